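"""Synthetic growth-cycle generator.

Generates a circular genome with a G/C (melting-energy) gradient declining
from OriC to Ter on both replichores, a strand-aware gene annotation, and
a 0-420 min expression time course driven by a global superhelical density
sigma(t) that plunges after nutritional shift-up and relaxes toward
stationary phase.

The generative model is the timing chain: each gene has an optimal
superhelical density sigma* for transcription, tied to the local duplex
stability (more stable, G/C-rich, OriC-proximal DNA -> more negative
sigma*), and its expression follows a Gaussian response around sigma* as
the global sigma(t) sweeps from the stationary level (~ -0.03) to the
shift-up peak (~ -0.075) and back.  Genes therefore reach maximal
expression in order of distance from OriC as the chromosome relaxes.

Genes with sigma* below ``hyp_threshold`` are labeled ``hyp`` (activated
by hyper-negative supercoiling), those above ``rel_threshold`` are ``rel``
(activated by relaxation); a buffer zone stays unlabeled.  Strand
orientation couples to the labels: with probability ``orientation_bias`` a
hyp gene is placed divergently with its nearest neighbor (so it receives
negative TCDS) and a rel gene convergently (positive TCDS).

Every operation is deterministic under a fixed seed; independent random
streams are derived per stage so the stages can be re-run in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .core import CircularGenome, ExpressionMatrix, GeneRecord, GeneTable
from .thermo import ThermoProfile, default_window, window_fme

logger = logging.getLogger(__name__)

# stream ids for per-stage child RNGs
_STREAM_GENOME = 1
_STREAM_PLACE = 2
_STREAM_EXPR = 3


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic growth cycle.

    Defaults encode a scaled-down bacterial chromosome (1 Mb, 400 genes)
    with the batch-culture supercoiling schedule: stationary sigma -0.03,
    shift-up peak -0.075 at 60 min, samples every 10 min out to 420 min.
    """

    length: int = 1_000_000
    n_genes: int = 400
    gc_ori: float = 0.60
    gc_ter: float = 0.40
    sigma_stat: float = -0.03
    sigma_peak: float = -0.075
    t_peak: float = 60.0
    t_end: float = 420.0
    grid_step: float = 10.0
    response_width: float = 0.012
    hyp_threshold: float = -0.060
    rel_threshold: float = -0.045
    orientation_bias: float = 0.8
    noise: float = 0.2
    baseline_sd: float = 0.5
    gene_length: int = 1000
    min_gap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.n_genes < 0:
            raise ValueError("length must be positive and n_genes nonnegative")
        if not (0.0 < self.gc_ter <= self.gc_ori < 1.0):
            raise ValueError("require 0 < gc_ter <= gc_ori < 1")
        if not (self.sigma_peak < self.sigma_stat <= 0.0):
            raise ValueError("require sigma_peak < sigma_stat <= 0")
        if self.t_peak >= self.t_end:
            raise ValueError("t_peak must precede t_end")
        if self.t_peak <= 0 or self.grid_step <= 0:
            raise ValueError("t_peak and grid_step must be positive")
        for t in (self.t_peak, self.t_end):
            if abs(t / self.grid_step - round(t / self.grid_step)) > 1e-9:
                raise ValueError("t_peak and t_end must lie on the time grid")
        if not (self.sigma_peak <= self.hyp_threshold
                < self.rel_threshold <= self.sigma_stat):
            raise ValueError("thresholds must be ordered within [sigma_peak, sigma_stat]")
        if not (0.0 <= self.orientation_bias <= 1.0):
            raise ValueError("orientation_bias must be in [0, 1]")
        if self.response_width <= 0:
            raise ValueError("response_width must be positive")
        if self.noise < 0 or self.baseline_sd < 0:
            raise ValueError("noise and baseline_sd must be nonnegative")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.grid_step)) + 1
        return np.arange(n) * self.grid_step

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class SigmaSchedule:
    """Global superhelical density over the growth cycle (minutes grid)."""

    timepoints: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", np.asarray(self.timepoints, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.timepoints.shape != self.sigma.shape:
            raise ValueError("timepoints and sigma must have equal length")
        if np.any(self.sigma > 0):
            raise ValueError("sigma must be nonpositive")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.timepoints, "sigma": self.sigma})


@dataclass
class SimTruth:
    """Ground truth of the generator: per-gene sigma*, label and (after
    simulation) the timepoint of maximal noiseless expression."""

    gene_ids: list[str]
    sigma_opt: np.ndarray
    labels: list[str]
    peak_time: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "gene_id": self.gene_ids,
            "sigma_opt": self.sigma_opt,
            "label": self.labels,
        })
        if self.peak_time is not None:
            df["peak_time"] = self.peak_time
        return df

    def label_set(self, label: str) -> list[str]:
        return [g for g, lab in zip(self.gene_ids, self.labels) if lab == label]


def sigma_schedule(config: SimConfig) -> SigmaSchedule:
    """Piecewise-linear sigma(t): stationary level at t=0, linear ramp to
    the shift-up peak at t_peak, linear return to the stationary level at
    t_end."""
    t = config.time_grid()
    sigma = np.where(
        t <= config.t_peak,
        config.sigma_stat + (config.sigma_peak - config.sigma_stat) * t / config.t_peak,
        config.sigma_peak + (config.sigma_stat - config.sigma_peak)
        * (t - config.t_peak) / (config.t_end - config.t_peak),
    )
    return SigmaSchedule(t, sigma)


def make_genome(config: SimConfig) -> CircularGenome:
    """Random genome whose per-position G/C probability declines linearly
    from ``gc_ori`` at OriC (position 0) to ``gc_ter`` at Ter (L/2) along
    both replichores."""
    rng = config.rng(_STREAM_GENOME)
    L = config.length
    pos = np.arange(L)
    dist = np.minimum(pos, L - pos)  # circular distance to ori at 0
    frac = dist / (L / 2.0)
    p_gc = config.gc_ori + (config.gc_ter - config.gc_ori) * frac
    is_gc = rng.random(L) < p_gc
    which = rng.integers(0, 2, L)  # G vs C, A vs T
    alphabet = np.frombuffer(b"ATGC", dtype=np.uint8)
    codes = np.where(is_gc, 2 + which, which)
    seq = alphabet[codes].tobytes().decode()
    return CircularGenome(sequence=seq, ori_pos=0, ter_pos=L // 2)


def _optima_from_fme(fme: np.ndarray, config: SimConfig) -> tuple[np.ndarray, list[str]]:
    """Map per-gene fME to sigma* affinely: the most stable (most negative
    fME) gene gets sigma_peak, the least stable gets sigma_stat."""
    fme = np.asarray(fme, dtype=float)
    lo, hi = fme.min(), fme.max()
    if hi - lo < 1e-12:
        logger.warning("degenerate (constant) fME profile: all sigma* equal, "
                       "no hyp/rel labels assigned")
        sigma_opt = np.full(fme.shape, (config.sigma_peak + config.sigma_stat) / 2.0)
        return sigma_opt, ["none"] * fme.size
    sigma_opt = config.sigma_peak + (config.sigma_stat - config.sigma_peak) \
        * (fme - lo) / (hi - lo)
    labels = [
        "hyp" if s <= config.hyp_threshold
        else "rel" if s >= config.rel_threshold
        else "none"
        for s in sigma_opt
    ]
    return sigma_opt, labels


def _gene_midpoint_fme(starts: np.ndarray, config: SimConfig,
                       profile: ThermoProfile) -> np.ndarray:
    """fME at each gene's interval midpoint (strand-independent, so label
    assignment cannot depend on the orientation choice it drives)."""
    mids = (starts + config.gene_length // 2) % config.length
    return np.array([profile.value_at(int(m)) for m in mids])


def place_genes(config: SimConfig, genome: CircularGenome,
                profile: ThermoProfile | None = None) -> GeneTable:
    """Place non-overlapping gene bodies around the circle and orient them.

    Genes are laid out in adjacent pairs separated by ``min_gap`` within a
    pair and by at least ``2 * min_gap + 1`` between pairs (the slack left
    over from packing is spread randomly over the inter-pair gaps), so each
    gene's nearest neighbor is its pair partner.  Strands are then chosen
    from provisional hyp/rel labels (from the melting-energy profile): with
    probability ``orientation_bias`` a hyp gene's pair is made divergent
    and a rel gene's pair convergent; conflicting desires within a mixed
    pair resolve in favor of the hyp member, and undecided pairs get
    independent random strands.
    """
    if config.n_genes == 0:
        return GeneTable([], genome.length)
    rng = config.rng(_STREAM_PLACE)
    L = genome.length
    glen, gap = config.gene_length, config.min_gap
    inter_min = 2 * config.min_gap + 1

    n_pairs, solo = divmod(config.n_genes, 2)
    units = n_pairs + solo
    pair_footprint = 2 * glen + gap
    footprints = [pair_footprint] * n_pairs + [glen] * solo
    needed = sum(footprints) + units * inter_min
    if needed > L:
        raise ValueError(
            f"infeasible packing: {config.n_genes} genes need {needed} bp "
            f"but genome is {L} bp"
        )
    extra = L - needed
    # split the slack over the inter-unit gaps, uniformly at random
    extras = rng.multinomial(extra, np.full(units, 1.0 / units)) if extra else np.zeros(units, dtype=int)

    starts: list[int] = []
    is_pair: list[bool] = []
    s = 0
    for u in range(units):
        starts.append(s)
        is_pair.append(u < n_pairs)
        s += footprints[u] + inter_min + int(extras[u])
    assert s == L

    if profile is None:
        profile = window_fme(genome, window=default_window(L), step=1000)

    # provisional labels from the melting-energy gradient (midpoint fME)
    gene_starts: list[int] = []
    for u, st in enumerate(starts):
        gene_starts.append(st)
        if is_pair[u]:
            gene_starts.append(st + glen + gap)
    gene_starts_arr = np.array(gene_starts)
    _, labels = _optima_from_fme(_gene_midpoint_fme(gene_starts_arr, config, profile), config)

    strands: list[str] = ["+"] * len(gene_starts)
    gi = 0
    for u in range(units):
        if not is_pair[u]:
            strands[gi] = "+" if rng.random() < 0.5 else "-"
            gi += 1
            continue
        i, j = gi, gi + 1
        desires = []
        for k in (i, j):
            if labels[k] == "hyp" and rng.random() < config.orientation_bias:
                desires.append("divergent")
            elif labels[k] == "rel" and rng.random() < config.orientation_bias:
                desires.append("convergent")
            else:
                desires.append(None)
        want = None
        if "divergent" in desires and "convergent" in desires:
            # mixed pair: the hyp member's configuration wins
            want = "divergent" if "hyp" in (labels[i], labels[j]) else desires[0]
        else:
            want = desires[0] or desires[1]
        if want == "divergent":
            strands[i], strands[j] = "-", "+"
        elif want == "convergent":
            strands[i], strands[j] = "+", "-"
        else:
            strands[i] = "+" if rng.random() < 0.5 else "-"
            strands[j] = "+" if rng.random() < 0.5 else "-"
        gi += 2

    width = len(str(len(gene_starts)))
    records = [
        GeneRecord(
            gene_id=f"g{k + 1:0{width}d}", start=int(st), end=int(st) + glen,
            strand=strands[k], label=labels[k],
        )
        for k, st in enumerate(gene_starts)
    ]
    return GeneTable(records, L)


def assign_optima(genes: GeneTable, thermo: ThermoProfile,
                  config: SimConfig) -> SimTruth:
    """Per-gene optimal superhelical density and hyp/rel label.

    sigma* is an affine function of the gene's midpoint fME: the most
    stable gene maps to ``sigma_peak``, the least stable to ``sigma_stat``.
    """
    starts = np.array([g.start for g in genes])
    fme = _gene_midpoint_fme(starts, config, thermo)
    sigma_opt, labels = _optima_from_fme(fme, config)
    return SimTruth(gene_ids=genes.gene_ids, sigma_opt=sigma_opt, labels=labels)


def simulate_expression(genes: GeneTable, truth: SimTruth,
                        schedule: SigmaSchedule, config: SimConfig) -> ExpressionMatrix:
    """Gaussian response of each gene to the sigma(t) sweep.

    mean_g(t) = B_g * exp(-(sigma(t) - sigma*_g)^2 / (2 w^2)) with a
    lognormal per-gene baseline B_g; observed values multiply the mean by
    lognormal noise with log-sd ``config.noise``.  The noiseless argmax
    per gene is recorded as ``truth.peak_time`` (ties resolve to the
    latest timepoint, so a gene tuned to the stationary level peaks at the
    end of the cycle rather than at inoculation).
    """
    if truth.gene_ids != genes.gene_ids:
        raise ValueError("truth and gene table are out of register")
    rng = config.rng(_STREAM_EXPR)
    G = len(genes)
    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sd, size=G)
    dev = schedule.sigma[None, :] - truth.sigma_opt[:, None]
    mean = baseline[:, None] * np.exp(-dev ** 2 / (2 * config.response_width ** 2))
    if config.noise > 0:
        values = mean * rng.lognormal(mean=0.0, sigma=config.noise, size=mean.shape)
    else:
        values = mean
    # latest argmax: reverse, take argmax, map back
    rev = np.argmax(mean[:, ::-1], axis=1)
    peak_idx = mean.shape[1] - 1 - rev
    truth.peak_time = schedule.timepoints[peak_idx]
    return ExpressionMatrix(genes.gene_ids, schedule.timepoints, values)


@dataclass
class SimBundle:
    """Everything one simulated growth cycle produces."""

    config: SimConfig
    genome: CircularGenome
    profile: ThermoProfile
    genes: GeneTable
    truth: SimTruth
    schedule: SigmaSchedule
    expression: ExpressionMatrix


def simulate(config: SimConfig = SimConfig()) -> SimBundle:
    """Run the full generator: genome, thermo profile, genes, truth,
    sigma schedule, expression."""
    genome = make_genome(config)
    profile = window_fme(genome, window=default_window(genome.length), step=1000)
    genes = place_genes(config, genome, profile)
    truth = assign_optima(genes, profile, config)
    schedule = sigma_schedule(config)
    expression = simulate_expression(genes, truth, schedule, config)
    return SimBundle(config, genome, profile, genes, truth, schedule, expression)


def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Write genome.fasta, genes.gff3, expr.tsv, truth.tsv, sigma.tsv and
    config.yaml into ``outdir``; returns the path manifest."""
    import yaml

    from .io import (_write_tsv, provenance_header, write_expression,
                     write_genes_gff3, write_genome)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(seed=bundle.config.seed)
    paths = {
        "genome": outdir / "genome.fasta",
        "genes": outdir / "genes.gff3",
        "expression": outdir / "expr.tsv",
        "truth": outdir / "truth.tsv",
        "sigma": outdir / "sigma.tsv",
        "config": outdir / "config.yaml",
    }
    write_genome(bundle.genome, paths["genome"])
    write_genes_gff3(bundle.genes, paths["genes"], header_lines=header)
    write_expression(bundle.expression, paths["expression"], header_lines=header)
    _write_tsv(bundle.truth.to_dataframe(), paths["truth"], header)
    _write_tsv(bundle.schedule.to_dataframe(), paths["sigma"], header)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(bundle.config), fh, sort_keys=False)
    return paths
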