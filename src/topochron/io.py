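"""Readers and writers for the on-disk formats.

FASTA via Biopython; GFF3 via gffutils (feature type ``gene``, ``ID``
attribute); BED6 and TSV matrices via pandas.  All TSV writers accept
provenance comment lines (``# key=value``) that every reader skips.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CircularGenome, Curve, ExpressionMatrix, GeneRecord, GeneTable


def provenance_header(**params) -> list[str]:
    """Comment lines recording tool version and run parameters."""
    from . import __version__

    lines = [f"# topochron v{__version__}"]
    for key, val in params.items():
        lines.append(f"# {key}={val}")
    return lines


def _write_tsv(df: pd.DataFrame, path, header_lines: Sequence[str] | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome


def read_genome(fasta_path, ori_pos: int, ter_pos: int) -> CircularGenome:
    """Load a single circular chromosome from FASTA.

    Exactly one record is required; ambiguity codes (including N) are
    rejected with the offending position.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected single circular chromosome, found {len(records)} "
            f"records in {fasta_path}"
        )
    seq = str(records[0].seq).upper()
    bad = re.search(r"[^ACGT]", seq)
    if bad:
        raise ValueError(
            f"non-ACGT character {seq[bad.start()]!r} at position {bad.start()}"
        )
    return CircularGenome(sequence=seq, ori_pos=ori_pos, ter_pos=ter_pos)


def write_genome(genome: CircularGenome, path, record_id: str = "chr") -> None:
    rec = SeqRecord(Seq(genome.sequence), id=record_id,
                    description=f"circular ori={genome.ori_pos} ter={genome.ter_pos}")
    SeqIO.write([rec], str(path), "fasta")


# ---------------------------------------------------------------------------
# genes


def read_genes(path, format: str, genome_length: int) -> GeneTable:
    """Read gene annotation as GFF3 (1-based inclusive, converted) or BED6
    (0-based half-open, taken as-is)."""
    if format == "gff3":
        return _read_gff3(path, genome_length)
    if format == "bed6":
        return _read_bed6(path, genome_length)
    raise ValueError(f"format must be 'gff3' or 'bed6', got {format!r}")


def _read_gff3(path, genome_length: int) -> GeneTable:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    records = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {feat.id}: missing or invalid strand")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        # GFF3 start is 1-based inclusive; end inclusive.
        records.append(
            GeneRecord(gene_id=gene_id, start=feat.start - 1, end=feat.end,
                       strand=feat.strand)
        )
    return GeneTable(records, genome_length)


def _read_bed6(path, genome_length: int) -> GeneTable:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"start": int, "end": int, "name": str, "strand": str},
    )
    if df["strand"].isna().any():
        raise ValueError("BED6 input is missing the strand column")
    records = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"gene {row.name}: missing or invalid strand")
        records.append(
            GeneRecord(gene_id=str(row.name), start=int(row.start),
                       end=int(row.end), strand=row.strand)
        )
    return GeneTable(records, genome_length)


def write_genes_gff3(table: GeneTable, path, seqid: str = "chr",
                     header_lines: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        for rec in table:
            attrs = f"ID={rec.gene_id}"
            if rec.label != "none":
                attrs += f";label={rec.label}"
            fh.write(
                f"{seqid}\ttopochron\tgene\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\t{attrs}\n"
            )


def write_genes_bed6(table: GeneTable, path, seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        for rec in table:
            fh.write(f"{seqid}\t{rec.start}\t{rec.end}\t{rec.gene_id}\t0\t{rec.strand}\n")


# ---------------------------------------------------------------------------
# expression


def read_expression(tsv_path) -> ExpressionMatrix:
    """Read a genes x timepoints abundance matrix.

    First column holds gene IDs; remaining column headers are timepoints
    in minutes.  Negative entries are rejected with their cell location.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    gene_col = df.columns[0]
    try:
        timepoints = [float(c) for c in df.columns[1:]]
    except ValueError as exc:
        raise ValueError(f"non-numeric timepoint header: {exc}") from None
    gene_ids = df[gene_col].astype(str).tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        g, t = neg[0]
        raise ValueError(
            f"negative expression value {values[g, t]} for gene "
            f"{gene_ids[g]!r} at t={timepoints[t]:g}"
        )
    return ExpressionMatrix(gene_ids, timepoints, values)


def write_expression(expr: ExpressionMatrix, path,
                     header_lines: Sequence[str] | None = None) -> None:
    _write_tsv(expr.to_dataframe(), path, header_lines)


# ---------------------------------------------------------------------------
# gene sets and curves


def read_gene_set(path) -> list[str]:
    """One gene ID per line; '#' comments and blank lines ignored."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return ids


def write_gene_set(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


def write_curve(curve: Curve, path,
                header_lines: Sequence[str] | None = None) -> None:
    _write_tsv(curve.to_dataframe(), path, header_lines)


def read_curve(path) -> Curve:
    df = pd.read_csv(path, sep="\t", comment="#")
    sd = df["sd"].to_numpy() if "sd" in df.columns else None
    return Curve(df["time"].to_numpy(), df["value"].to_numpy(), sd)
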