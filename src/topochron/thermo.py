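"""Nearest-neighbor DNA melting thermodynamics along a circular genome.

The free melting energy (fME) of a window is the mean stacked-pair free
energy of its base steps, computed from the unified nearest-neighbor
Delta-G(37 C) duplex parameters (SantaLucia 1998).  Duplex initiation and
symmetry corrections are omitted: they are O(1) per duplex and vanish
against the hundreds of kilobases summed per window.  More negative fME
means a more stable (more G/C-rich) window.

Sliding windows wrap around the circle; values are normalized per step so
different window sizes remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CircularGenome, GeneRecord, circular_distance

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Unified nearest-neighbor Delta-G(37) stacking parameters, kcal/mol per
#: base step (10 unique values; the remaining 6 follow from
#: reverse-complement symmetry).
_DG37_UNIQUE: dict[str, float] = {
    "AA": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45,
    "GT": -1.44,
    "CT": -1.28,
    "GA": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84,
}


def _reverse_complement(step: str) -> str:
    return step.translate(_COMPLEMENT)[::-1]


def _expand_steps(unique: Mapping[str, float]) -> dict[str, float]:
    full: dict[str, float] = {}
    for step, dg in unique.items():
        full[step] = dg
        full[_reverse_complement(step)] = dg
    return full


@dataclass(frozen=True)
class NNParameterSet:
    """Dinucleotide-step free energies plus the helical repeat.

    ``delta_g`` maps all 16 steps to Delta-G(37) in kcal/mol (negative =
    more stable) and must satisfy reverse-complement symmetry.
    ``helical_repeat`` is the B-DNA repeat in bp/turn used when converting
    superhelical density to turns.
    """

    delta_g: Mapping[str, float] = field(
        default_factory=lambda: _expand_steps(_DG37_UNIQUE)
    )
    helical_repeat: float = 10.5

    def __post_init__(self) -> None:
        steps = {a + b for a in "ACGT" for b in "ACGT"}
        if set(self.delta_g) != steps:
            missing = sorted(steps - set(self.delta_g))
            raise ValueError(f"parameter table missing steps: {missing}")
        for step, dg in self.delta_g.items():
            if dg >= 0:
                raise ValueError(f"Delta-G for step {step} must be negative")
            rc = _reverse_complement(step)
            if abs(dg - self.delta_g[rc]) > 1e-12:
                raise ValueError(
                    f"reverse-complement symmetry violated: {step} vs {rc}"
                )
        if self.helical_repeat <= 0:
            raise ValueError("helical_repeat must be positive")


SANTALUCIA_UNIFIED = NNParameterSet()


def step_free_energy(dinucleotide: str, params: NNParameterSet = SANTALUCIA_UNIFIED) -> float:
    """Delta-G(37) of a single base step in kcal/mol."""
    try:
        return params.delta_g[dinucleotide.upper()]
    except KeyError:
        raise ValueError(f"unknown dinucleotide step {dinucleotide!r}") from None


@dataclass(frozen=True)
class ThermoProfile:
    """Windowed fME profile around the circle.

    ``centers`` are the bp coordinates of window centers (ascending,
    evenly spaced by ``step``); ``fme`` is kcal/mol per base step
    (negative; lower = more stable = more G/C-rich).
    """

    window: int
    step: int
    genome_length: int
    centers: np.ndarray
    fme: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=np.int64))
        object.__setattr__(self, "fme", np.asarray(self.fme, dtype=float))
        if self.centers.size == 0:
            raise ValueError("profile must contain at least one window")
        if self.centers.shape != self.fme.shape:
            raise ValueError("centers and fme must have equal length")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly ascending")

    def nearest_center_index(self, pos: int) -> int:
        """Index of the window center circularly nearest to ``pos``.

        Ties between two equidistant centers resolve to the lower
        coordinate (deterministic)."""
        L = self.genome_length
        d = np.abs(self.centers - (pos % L))
        d = np.minimum(d, L - d)
        return int(np.argmin(d))

    def value_at(self, pos: int) -> float:
        return float(self.fme[self.nearest_center_index(pos)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"center": self.centers, "fme": self.fme})


def default_window(genome_length: int) -> int:
    """Default scanning-window width.

    Full-size bacterial genomes use 500 kb; smaller (synthetic) genomes
    keep the same window:genome ratio (500 kb : 4.5 Mb = 1/9), rounded to
    1 kb.
    """
    w = min(500_000, max(1000, round(genome_length / 9 / 1000) * 1000))
    return min(w, genome_length)


def window_fme(
    genome: CircularGenome,
    window: int | None = None,
    step: int = 1000,
    params: NNParameterSet = SANTALUCIA_UNIFIED,
) -> ThermoProfile:
    """Sliding-window fME profile of the circular genome.

    Each window of ``window`` bp (centered every ``step`` bp, wrapping)
    contributes the mean Delta-G of its ``window - 1`` consecutive base
    steps.
    """
    L = genome.length
    if window is None:
        window = default_window(L)
    if not (2 <= window <= L):
        raise ValueError(f"window must be in [2, {L}], got {window}")
    if step < 1:
        raise ValueError("step must be >= 1")

    idx = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    code = np.zeros(256, dtype=np.int64)
    for i, base in enumerate(b"ACGT"):
        code[base] = i
    bases = code[idx]
    table = np.empty((4, 4), dtype=float)
    for a, ba in enumerate("ACGT"):
        for b, bb in enumerate("ACGT"):
            table[a, b] = params.delta_g[ba + bb]
    # per-position step energy on the circle: e[i] = dG(seq[i], seq[i+1 mod L])
    energies = table[bases, np.roll(bases, -1)]

    centers = np.arange(0, L, step, dtype=np.int64)
    starts = (centers - window // 2) % L
    ext = np.concatenate([energies, energies[: window]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    sums = csum[starts + window - 1] - csum[starts]
    return ThermoProfile(
        window=window, step=step, genome_length=L,
        centers=centers, fme=sums / (window - 1),
    )


def gene_fme(gene: GeneRecord, profile: ThermoProfile) -> float:
    """Profile fME at the window center nearest the gene's promoter proxy
    (strand-aware start)."""
    return profile.value_at(gene.promoter_pos)


def gene_ori_distance(gene: GeneRecord, genome: CircularGenome) -> int:
    """Circular distance from the gene's promoter proxy to OriC, in bp."""
    return circular_distance(gene.promoter_pos, genome.ori_pos, genome.length)


def sigma_to_turns_per_kb(sigma: float, helical_repeat: float = 10.5) -> float:
    """Convert superhelical density to total superhelical turns per kb.

    Only negatively supercoiled (or relaxed) DNA is modeled; sigma must be
    <= 0.  At sigma = -0.08 and h = 10.5 this gives ~8 turns/kb, declining
    to ~3 at sigma = -0.03 — the drop seen between exponential and
    stationary phase.
    """
    if sigma > 0:
        raise ValueError("only negative supercoiling is modeled (sigma <= 0)")
    if helical_repeat <= 0:
        raise ValueError("helical_repeat must be positive")
    return abs(sigma) * 1000.0 / helical_repeat


def write_profile(profile: ThermoProfile, path,
                  header_lines: Sequence[str] | None = None) -> None:
    from .io import _write_tsv

    _write_tsv(profile.to_dataframe(), path, header_lines)


def read_profile(path, window: int, step: int, genome_length: int) -> ThermoProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ThermoProfile(
        window=window, step=step, genome_length=genome_length,
        centers=df["center"].to_numpy(), fme=df["fme"].to_numpy(),
    )
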