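"""Shared domain types for circular-chromosome analyses.

All coordinates are 0-based, half-open, on a single circular replicon.
Genes spanning the linearization point (coordinate 0) are rejected on
input; circular arithmetic is confined to distance and window code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

_VALID_SEQ = re.compile(r"[ACGT]+\Z")
_STRANDS = ("+", "-")
_LABELS = ("hyp", "rel", "none")


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest arc length between two positions on a circle of ``length`` bp.

    Symmetric, bounded by ``length // 2``, and satisfies the triangle
    inequality on the circle.
    """
    if length <= 0:
        raise ValueError("circle length must be positive")
    if not (0 <= a < length and 0 <= b < length):
        raise ValueError(
            f"coordinates must lie in [0, {length}): got a={a}, b={b}"
        )
    d = (a - b) % length
    return int(min(d, length - d))


@dataclass(frozen=True)
class CircularGenome:
    """A single circular chromosome with replication origin/terminus landmarks.

    Parameters
    ----------
    sequence : str
        Uppercase DNA over {A, C, G, T}.
    ori_pos, ter_pos : int
        0-based coordinates of OriC and Ter.
    """

    sequence: str
    ori_pos: int
    ter_pos: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        bad = re.search(r"[^ACGT]", self.sequence)
        if bad:
            raise ValueError(
                f"invalid character {self.sequence[bad.start()]!r} "
                f"at position {bad.start()}"
            )
        L = len(self.sequence)
        for name, pos in (("ori_pos", self.ori_pos), ("ter_pos", self.ter_pos)):
            if not (0 <= pos < L):
                raise ValueError(f"{name}={pos} outside [0, {L})")
        if self.ori_pos == self.ter_pos:
            raise ValueError("ori_pos and ter_pos must differ")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """A strand-aware gene interval, 0-based half-open."""

    gene_id: str
    start: int
    end: int
    strand: str
    label: str = "none"

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def promoter_pos(self) -> int:
        """Strand-aware transcription start used as the promoter proxy."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def five_prime(self) -> int:
        return self.promoter_pos

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class GeneTable:
    """Ordered, strand-aware gene annotation for one circular chromosome.

    Records are kept sorted by start coordinate; gene IDs are unique.
    Genes crossing coordinate 0 are rejected (rotate the sequence first).
    """

    def __init__(self, records: Iterable[GeneRecord], genome_length: int):
        records = sorted(records, key=lambda r: (r.start, r.gene_id))
        if genome_length <= 0:
            raise ValueError("genome_length must be positive")
        seen: set[str] = set()
        for rec in records:
            if rec.end > genome_length:
                raise ValueError(
                    f"gene {rec.gene_id} ends at {rec.end} beyond genome "
                    f"length {genome_length}"
                )
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
            seen.add(rec.gene_id)
        self._records: tuple[GeneRecord, ...] = tuple(records)
        self.genome_length = genome_length
        self._by_id: dict[str, GeneRecord] = {r.gene_id: r for r in records}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> GeneRecord:
        return self._records[i]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GeneTable)
            and self.genome_length == other.genome_length
            and self._records == other._records
        )

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self._records]

    def get(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def promoter_positions(self) -> np.ndarray:
        return np.array([r.promoter_pos for r in self._records], dtype=np.int64)

    def labels(self) -> list[str]:
        return [r.label for r in self._records]

    def with_labels(self, labels: Mapping[str, str]) -> "GeneTable":
        new = [
            GeneRecord(r.gene_id, r.start, r.end, r.strand,
                       labels.get(r.gene_id, r.label))
            for r in self._records
        ]
        return GeneTable(new, self.genome_length)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self._records],
                "start": [r.start for r in self._records],
                "end": [r.end for r in self._records],
                "strand": [r.strand for r in self._records],
                "label": [r.label for r in self._records],
            }
        )


class ExpressionMatrix:
    """Nonnegative gene x timepoint abundances on a minutes grid."""

    def __init__(
        self,
        gene_ids: Sequence[str],
        timepoints: Sequence[float],
        values: np.ndarray,
    ):
        gene_ids = list(gene_ids)
        timepoints = np.asarray(timepoints, dtype=float)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(timepoints)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(gene_ids)} genes, {len(timepoints)} timepoints)"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene_ids in expression matrix")
        if timepoints.size and np.any(np.diff(timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(values < 0) or np.any(~np.isfinite(values)):
            g, t = np.argwhere((values < 0) | ~np.isfinite(values))[0]
            raise ValueError(
                f"invalid expression value {values[g, t]} for gene "
                f"{gene_ids[g]!r} at t={timepoints[t]:g}"
            )
        self.gene_ids = gene_ids
        self.timepoints = timepoints
        self.values = values
        self._index = {g: i for i, g in enumerate(gene_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index[gene_id]]

    def rows(self, gene_ids: Sequence[str]) -> np.ndarray:
        idx = [self._index[g] for g in gene_ids]
        return self.values[idx]

    def column(self, timepoint: float) -> np.ndarray:
        (j,) = np.nonzero(self.timepoints == timepoint)
        if j.size != 1:
            raise KeyError(f"timepoint {timepoint} not on the grid")
        return self.values[:, j[0]]

    def normalized_columns(self) -> "ExpressionMatrix":
        """Rescale each timepoint column to unit sum (optional, off by default
        elsewhere); columns summing to zero are left unchanged."""
        sums = self.values.sum(axis=0)
        scaled = np.where(sums > 0, self.values / np.where(sums > 0, sums, 1.0), self.values)
        return ExpressionMatrix(self.gene_ids, self.timepoints, scaled)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[_fmt_time(t) for t in self.timepoints])
        df.insert(0, "gene_id", self.gene_ids)
        return df

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.timepoints, other.timepoints)
            and np.array_equal(self.values, other.values)
        )


def _fmt_time(t: float) -> str:
    return f"{int(t)}" if float(t).is_integer() else f"{t:g}"


@dataclass
class Curve:
    """A time series (minutes grid), optionally with a resampling-SD envelope."""

    timepoints: np.ndarray
    values: np.ndarray
    envelope_sd: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.shape != self.values.shape:
            raise ValueError("timepoints and values must have equal length")
        if self.envelope_sd is not None:
            self.envelope_sd = np.asarray(self.envelope_sd, dtype=float)
            if self.envelope_sd.shape != self.values.shape:
                raise ValueError("envelope_sd length mismatch")
            if np.any(self.envelope_sd < 0):
                raise ValueError("envelope_sd must be nonnegative")

    def value_at(self, t: float) -> float:
        (j,) = np.nonzero(self.timepoints == t)
        if j.size != 1:
            raise KeyError(f"timepoint {t} not on the grid")
        return float(self.values[j[0]])

    def argmax_time(self, min_time: float | None = None) -> float:
        """Timepoint of the maximum value.

        ``min_time`` restricts the search to later timepoints — useful for
        growth-cycle curves where t=0 carries the expression pattern of the
        stationary inoculum rather than the post-shift-up response.
        """
        if min_time is None:
            return float(self.timepoints[int(np.argmax(self.values))])
        mask = self.timepoints >= min_time
        if not mask.any():
            raise ValueError(f"no timepoints at or after {min_time}")
        sub = np.flatnonzero(mask)
        return float(self.timepoints[sub[int(np.argmax(self.values[sub]))]])

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time": self.timepoints, "value": self.values}
        if self.envelope_sd is not None:
            data["sd"] = self.envelope_sd
        return pd.DataFrame(data)
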