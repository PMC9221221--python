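"""Growth-cycle expression trajectories and resampling envelopes.

Summarizes a time-resolved expression matrix into group-relative
expression curves (hyp / rel gene classes against the all-gene mean),
expression-weighted means of per-gene properties (windowed melting energy,
distance to OriC), (0;1) min-max normalization for joint plotting, and a
random-remapping envelope: the per-timepoint standard deviation of a curve
when the expression profiles of a random subset of genes are permuted
among themselves.

Also provides the promoter-optimum trend statistic: the Spearman rank
correlation between a promoter's distance from OriC and its optimal
superhelical density for transcription, computed on a table of
experimentally characterized promoters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Curve, ExpressionMatrix

logger = logging.getLogger(__name__)


def group_relative_expression(gene_set: Sequence[str], expr: ExpressionMatrix) -> Curve:
    """Mean expression of a gene set divided by the mean over all genes,
    per timepoint."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    missing = [g for g in gene_set if g not in expr._index]
    if missing:
        raise ValueError(f"gene set members missing from expression: {missing}")
    all_mean = expr.values.mean(axis=0)
    if np.any(all_mean == 0):
        t = expr.timepoints[np.nonzero(all_mean == 0)[0][0]]
        raise ValueError(f"all-genes mean expression is zero at t={t:g}")
    set_mean = expr.rows(gene_set).mean(axis=0)
    return Curve(expr.timepoints, set_mean / all_mean)


def weighted_mean_property(property_per_gene: np.ndarray, expr_col: np.ndarray) -> float:
    """Expression-weighted mean of a per-gene property.

    Invariant to rescaling the expression column by any positive constant.
    """
    prop = np.asarray(property_per_gene, dtype=float)
    w = np.asarray(expr_col, dtype=float)
    if prop.shape != w.shape:
        raise ValueError("property and expression column lengths differ")
    total = w.sum()
    if total <= 0:
        raise ValueError("total expression weight must be positive")
    return float(np.dot(prop, w) / total)


def weighted_property_curve(property_per_gene: np.ndarray, expr: ExpressionMatrix) -> Curve:
    """``weighted_mean_property`` evaluated at every timepoint."""
    vals = np.array([
        weighted_mean_property(property_per_gene, expr.values[:, j])
        for j in range(expr.timepoints.size)
    ])
    return Curve(expr.timepoints, vals)


def minmax01(curve: Curve) -> Curve:
    """Rescale a curve affinely onto [0, 1].

    A constant curve has no dynamic range; it maps to 0.5 everywhere and a
    warning is logged.
    """
    v = curve.values
    if v.size == 0:
        raise ValueError("curve is empty")
    lo, hi = v.min(), v.max()
    if hi == lo:
        logger.warning("minmax01: constant curve, mapping to 0.5")
        return Curve(curve.timepoints, np.full_like(v, 0.5), curve.envelope_sd)
    scaled = (v - lo) / (hi - lo)
    sd = curve.envelope_sd / (hi - lo) if curve.envelope_sd is not None else None
    return Curve(curve.timepoints, scaled, sd)


def remapping_envelope(
    statistic_fn: Callable[[ExpressionMatrix], np.ndarray],
    expr: ExpressionMatrix,
    fraction: float = 0.10,
    n_reps: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Per-timepoint SD of a curve under random remapping of expression.

    Each replicate selects ceil(fraction * G) genes uniformly without
    replacement and permutes their expression rows among themselves (a
    derangement is not enforced), then recomputes the statistic.
    Deterministic for a fixed seed.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    G = len(expr.gene_ids)
    k = math.ceil(fraction * G)
    if k == 0:
        # no genes remapped: every replicate is the unperturbed curve
        return np.zeros(expr.timepoints.size)
    curves = np.empty((n_reps, expr.timepoints.size), dtype=float)
    for r in range(n_reps):
        values = expr.values.copy()
        if k > 0:
            chosen = rng.choice(G, size=k, replace=False)
            values[chosen] = values[rng.permutation(chosen)]
        perturbed = ExpressionMatrix(expr.gene_ids, expr.timepoints, values)
        curves[r] = np.asarray(statistic_fn(perturbed), dtype=float)
    return curves.std(axis=0, ddof=1)


@dataclass(frozen=True)
class PromoterOptimumTable:
    """Experimentally characterized promoters with their optimal
    superhelical density (as a [low, high] sigma range) and distance from
    OriC."""

    promoter_ids: tuple[str, ...]
    distance_bp: np.ndarray
    sigma_low: np.ndarray
    sigma_high: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "distance_bp", np.asarray(self.distance_bp, dtype=float))
        object.__setattr__(self, "sigma_low", np.asarray(self.sigma_low, dtype=float))
        object.__setattr__(self, "sigma_high", np.asarray(self.sigma_high, dtype=float))
        n = len(self.promoter_ids)
        if not (self.distance_bp.size == self.sigma_low.size == self.sigma_high.size == n):
            raise ValueError("column lengths differ")
        if np.any(self.distance_bp < 0):
            raise ValueError("distances must be nonnegative")
        if np.any(self.sigma_low > self.sigma_high) or np.any(self.sigma_high > 0):
            raise ValueError("require sigma_low <= sigma_high <= 0")

    @property
    def sigma_midpoint(self) -> np.ndarray:
        return (self.sigma_low + self.sigma_high) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "promoter_id": list(self.promoter_ids),
            "distance_bp": self.distance_bp,
            "sigma_low": self.sigma_low,
            "sigma_high": self.sigma_high,
        })

    @classmethod
    def from_tsv(cls, path) -> "PromoterOptimumTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            promoter_ids=tuple(df["promoter_id"].astype(str)),
            distance_bp=df["distance_bp"].to_numpy(),
            sigma_low=df["sigma_low"].to_numpy(),
            sigma_high=df["sigma_high"].to_numpy(),
        )


#: In-vitro / in-vivo optimal superhelical densities of five characterized
#: E. coli promoters, with promoter distance from OriC (literature survey;
#: sigma optima are approximate ranges, activity declines on both sides).
REFERENCE_PROMOTER_OPTIMA = PromoterOptimumTable(
    promoter_ids=("hisR", "rrnAP1", "fis", "tyrT", "osmE"),
    distance_bp=np.array([62_500, 120_000, 508_500, 1_967_600, 2_097_900], dtype=float),
    sigma_low=np.array([-0.10, -0.076, -0.08, -0.06, -0.04]),
    sigma_high=np.array([-0.08, -0.076, -0.07, -0.05, -0.03]),
)


def optimum_trend(table: PromoterOptimumTable) -> float:
    """Spearman rank correlation between promoter distance from OriC and
    the signed midpoint of its optimal superhelical density range.

    A value of +1 means the optimum rises monotonically (toward relaxed
    DNA) with distance from the origin.
    """
    if len(table.promoter_ids) < 3:
        raise ValueError("need at least 3 promoters for a trend statistic")
    rho, _ = stats.spearmanr(table.distance_bp, table.sigma_midpoint)
    return float(rho)
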