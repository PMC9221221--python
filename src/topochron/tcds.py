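"""Transcription-coupled supercoil-diffusion (TCDS) scores at gene promoters.

A translocating RNA polymerase generates negative supercoils upstream and
positive supercoils downstream of itself (the twin-domain picture).  The
supercoils diffuse outward from the transcribed unit, so a promoter flanked
by divergently oriented neighbors accumulates negative superhelicity
(negative TCDS) while convergent flanks deliver positive superhelicity.

Each neighbor within ``range_bp`` of a focal promoter contributes its
abundance, weighted by exponential decay with the circular distance to the
neighbor's facing end, and signed by which end faces the promoter:
the 5' (start-of-transcription) end contributes -1, the 3' end +1.
Contributions sum linearly over neighbors and timepoints are independent,
so the whole matrix is one signed-weight matrix times the expression
matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    CircularGenome,
    Curve,
    ExpressionMatrix,
    GeneRecord,
    GeneTable,
    circular_distance,
)
from .thermo import gene_ori_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TCDSParams:
    """Range cutoff and decay constant of the supercoil-diffusion kernel.

    ``range_bp`` is the hard interaction cutoff (10 kb); ``decay_bp`` the
    exponential decay length of the diffusing supercoils (2.5 kb by
    default, so the weight at the cutoff is exp(-4) ~ 0.018).
    """

    range_bp: int = 10_000
    decay_bp: float = 2_500.0
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if self.range_bp <= 0:
            raise ValueError("range_bp must be positive")
        if self.decay_bp <= 0:
            raise ValueError("decay_bp must be positive")


def _facing_end(promoter_pos: int, neighbor: GeneRecord, L: int) -> tuple[int, int]:
    """(position, distance) of the neighbor end facing the promoter along
    the shorter circular arc.  Equidistant ends resolve to the start edge."""
    left, right = neighbor.start, neighbor.end - 1
    d_left = circular_distance(promoter_pos, left, L)
    d_right = circular_distance(promoter_pos, right, L)
    if d_left <= d_right:
        return left, d_left
    return right, d_right


def contribution_sign(promoter_pos: int, neighbor: GeneRecord, L: int) -> int:
    """Twin-domain sign of a neighbor's supercoil flux at a promoter.

    -1 if the neighbor's 5' end faces the promoter (the promoter sits
    upstream of the unit and receives negative supercoils), +1 if the 3'
    end faces it.
    """
    if neighbor.contains(promoter_pos):
        raise ValueError(
            f"promoter at {promoter_pos} lies inside neighbor "
            f"{neighbor.gene_id}; sign undefined"
        )
    end, _ = _facing_end(promoter_pos, neighbor, L)
    return -1 if end == neighbor.five_prime else +1


def tcds_at_gene(
    focal: GeneRecord,
    genes: GeneTable,
    expr_col: Mapping[str, float],
    params: TCDSParams = TCDSParams(),
    L: int | None = None,
) -> float:
    """Signed TCDS score at one promoter for one expression column.

    score = sum over neighbors n of sign(p, n) * E_n * exp(-d_n / decay),
    restricted to facing-end distances d_n <= range_bp.  Neighbors that
    contain the promoter are skipped (their sign is undefined).
    """
    L = L if L is not None else genes.genome_length
    p = focal.promoter_pos
    score = 0.0
    for n in genes:
        if params.exclude_self and n.gene_id == focal.gene_id:
            continue
        if n.contains(p):
            logger.debug(
                "promoter of %s inside %s: neighbor skipped",
                focal.gene_id, n.gene_id,
            )
            continue
        end, d = _facing_end(p, n, L)
        if d > params.range_bp:
            continue
        sign = -1 if end == n.five_prime else +1
        score += sign * expr_col.get(n.gene_id, 0.0) * math.exp(-d / params.decay_bp)
    return score


def tcds_weights(
    genes: GeneTable,
    expr_gene_ids: Sequence[str],
    params: TCDSParams = TCDSParams(),
) -> np.ndarray:
    """Signed weight matrix Wmat[f, n] so that TCDS = Wmat @ expression.

    Rows are focal genes, columns emitting neighbors, both in
    ``expr_gene_ids`` order.
    """
    L = genes.genome_length
    records = [genes.get(g) for g in expr_gene_ids]
    G = len(records)
    W = np.zeros((G, G), dtype=float)
    for i, focal in enumerate(records):
        p = focal.promoter_pos
        for j, n in enumerate(records):
            if params.exclude_self and i == j:
                continue
            if n.contains(p):
                continue
            end, d = _facing_end(p, n, L)
            if d > params.range_bp:
                continue
            sign = -1 if end == n.five_prime else +1
            W[i, j] = sign * math.exp(-d / params.decay_bp)
    return W


class TCDSMatrix:
    """Signed TCDS scores for every gene at every timepoint.

    Positive values indicate a net positive-superhelicity impact from the
    neighborhood, negative values a net negative-superhelicity impact.
    """

    def __init__(self, gene_ids: Sequence[str], timepoints: np.ndarray,
                 values: np.ndarray):
        self.gene_ids = list(gene_ids)
        self.timepoints = np.asarray(timepoints, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.gene_ids), self.timepoints.size):
            raise ValueError("TCDS matrix shape inconsistent with inputs")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index[gene_id]]

    def to_dataframe(self):
        import pandas as pd

        from .core import _fmt_time

        df = pd.DataFrame(self.values,
                          columns=[_fmt_time(t) for t in self.timepoints])
        df.insert(0, "gene_id", self.gene_ids)
        return df


def tcds_matrix(
    genes: GeneTable,
    expr: ExpressionMatrix,
    params: TCDSParams = TCDSParams(),
) -> TCDSMatrix:
    """TCDS score of every expressed gene at every timepoint."""
    missing = [g for g in expr.gene_ids if g not in genes]
    if missing:
        raise ValueError(
            f"genes in expression matrix missing from annotation: {missing}"
        )
    W = tcds_weights(genes, expr.gene_ids, params)
    return TCDSMatrix(expr.gene_ids, expr.timepoints, W @ expr.values)


def partition_thirds(genes: GeneTable, genome: CircularGenome) -> dict[str, list[str]]:
    """Split genes into OriC-proximal / intermediate / Ter-proximal thirds.

    Genes are ranked by circular promoter distance to OriC and cut into
    three contiguous rank blocks; remainders go to ori, then mid.
    """
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to partition into thirds")
    dist = np.array([gene_ori_distance(g, genome) for g in genes])
    order = np.argsort(dist, kind="stable")
    n = len(genes)
    q, r = divmod(n, 3)
    sizes = [q + (1 if r >= 1 else 0), q + (1 if r >= 2 else 0), q]
    ids = [genes[i].gene_id for i in order]
    out = {}
    pos = 0
    for name, size in zip(("ori", "mid", "ter"), sizes):
        out[name] = ids[pos: pos + size]
        pos += size
    return out


def group_mean_tcds(tcds: TCDSMatrix, gene_set: Sequence[str]) -> Curve:
    """Per-timepoint arithmetic mean TCDS over a gene set."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    missing = [g for g in gene_set if g not in tcds._index]
    if missing:
        raise ValueError(f"gene set members missing from TCDS matrix: {missing}")
    rows = tcds.values[[tcds._index[g] for g in gene_set]]
    return Curve(tcds.timepoints, rows.mean(axis=0))


def write_tcds(tcds: TCDSMatrix, path, header_lines=None) -> None:
    from .io import _write_tsv

    _write_tsv(tcds.to_dataframe(), path, header_lines)
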