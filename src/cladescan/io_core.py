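"""Readers/writers for the formats the pipeline touches, plus coordinate rules.

All internal interval arithmetic is 0-based half-open ``[start, end)`` on the
forward strand.  GFF3 uses 1-based inclusive coordinates; conversion happens
only at the I/O boundary (:func:`gff3_to_internal`, :func:`internal_to_gff3`)
and is a bijection.

Sequences are case-normalized to upper on read.  Nucleotide records may
contain ``N`` and protein records may contain ``X``; anything else outside the
stated alphabet is a hard error naming the record and position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "GeneAnnotation",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_matrix",
    "write_matrix",
    "gff3_to_internal",
    "internal_to_gff3",
    "reverse_complement",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene feature: 0-based half-open interval on the forward strand."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


def gff3_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert a GFF3 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_inclusive


def internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to GFF3 1-based inclusive."""
    return start + 1, end


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_sequence(rec_id: str, seq: str, alphabet: str, allow_gaps: bool) -> None:
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    if allow_gaps:
        allowed = allowed | {"-"}
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"record {rec_id!r}: character {ch!r} at position {pos + 1} "
                f"is outside the {alphabet} alphabet"
            )


def read_fasta(
    path: str | Path, alphabet: str = "nucleotide", allow_gaps: bool = False
) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Parameters
    ----------
    path:
        FASTA file (multi-record).
    alphabet:
        ``"nucleotide"`` (A/C/G/T plus N) or ``"protein"`` (20 residues plus X).

    Ids are the first whitespace-delimited token of the header.  Sequences are
    upper-cased.  Duplicate ids and out-of-alphabet characters are hard errors.
    """
    if alphabet not in {"nucleotide", "protein"}:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} is empty")
        _validate_sequence(rec.id, seq, alphabet, allow_gaps)
        records[rec.id] = seq
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write an id -> sequence mapping as multi-record FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | Path, feature_types: frozenset[str] = frozenset({"gene"})) -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file.

    Only features whose type is in ``feature_types`` are returned; each must
    carry an ``ID`` attribute.  Coordinates are converted to the internal
    0-based half-open convention.  ``start > end`` or a missing ID is an error.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype not in feature_types:
                continue
            start_1, end_1 = int(start_s), int(end_s)
            if start_1 > end_1:
                raise ValueError(f"{path}:{lineno}: start {start_1} > end {end_1}")
            attrs = _parse_gff3_attributes(attr_s)
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: gene feature without ID attribute")
            gene_id = attrs["ID"]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            start, end = gff3_to_internal(start_1, end_1)
            genes.append(GeneAnnotation(gene_id, seq_id, start, end, strand))
    return genes


def write_gff3(
    genes: Iterable[GeneAnnotation],
    path: str | Path,
    source: str = "cladescan",
    extra_attributes: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write gene features as GFF3 (``type=gene``), converting coordinates back."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            start_1, end_1 = internal_to_gff3(gene.start, gene.end)
            attrs = {"ID": gene.gene_id}
            if extra_attributes and gene.gene_id in extra_attributes:
                attrs.update(extra_attributes[gene.gene_id])
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            handle.write(
                f"{gene.seq_id}\t{source}\tgene\t{start_1}\t{end_1}\t.\t{gene.strand}\t.\t{attr_s}\n"
            )


def read_matrix(path: str | Path | io.StringIO) -> pd.DataFrame:
    """Read a gene x sample TSV (first column = gene ids, header = sample ids).

    The table must be rectangular with unique row/column ids and non-negative
    numeric values.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r}")
    if frame.isna().any().any():
        raise ValueError("matrix is ragged or contains missing values")
    values = frame.to_numpy()
    if not pd.api.types.is_numeric_dtype(frame.values):
        raise ValueError("matrix contains non-numeric values")
    if (values < 0).any():
        raise ValueError("matrix contains negative values")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x sample table as TSV with full float precision."""
    frame.to_csv(path, sep="\t", float_format="%.17g")
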