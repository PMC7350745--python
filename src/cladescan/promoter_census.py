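"""Upstream-region extraction and IUPAC cis-element census.

Promoters are the ``length`` (default 3000) bases immediately upstream of
the annotated gene start in transcription orientation; position −1 is the
base adjacent to the TSS and positions run back to −3000.  Minus-strand
regions are reverse-complemented so every promoter reads 5′→3′ toward its
gene.

Element patterns are IUPAC degenerate nucleotide strings (e.g. ``CAAT``,
``WAACCA``).  Scanning counts all, possibly overlapping, matches; by default
both the promoter strand and its reverse complement are scanned (hits of a
palindromic pattern are counted once per position).  Occurrence positions
are reported relative to the TSS as negative integers (the position of the
match's 5′-most promoter base).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .conservation import (
    Alignment,
    IdentityMatrix,
    dna_scoring,
    identity_matrix,
    progressive_msa,
)
from .io_core import GeneAnnotation, reverse_complement

__all__ = [
    "IUPAC_CODES",
    "ElementPattern",
    "PromoterRegion",
    "ElementCountTable",
    "iupac_regex",
    "extract_promoters",
    "scan_elements",
    "elements_in_all",
    "unique_elements",
    "promoter_identity",
    "read_patterns",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B",
    "N": "N",
}


@dataclass(frozen=True)
class ElementPattern:
    """A named cis-element written as an IUPAC degenerate string."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"pattern {self.name!r} is empty")
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"pattern {self.name!r} contains invalid IUPAC code(s) {sorted(bad)}"
            )

    @property
    def width(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "ElementPattern":
        rc = "".join(_IUPAC_COMPLEMENT[c] for c in self.iupac.upper()[::-1])
        return ElementPattern(self.name, rc)

    def is_palindromic(self) -> bool:
        return self.iupac.upper() == self.reverse_complement().iupac


def iupac_regex(iupac: str) -> re.Pattern:
    """Compiled regex finding all (overlapping) matches of an IUPAC pattern.

    Overlaps are captured with a lookahead group, so match positions are
    ``m.start(1)`` over ``finditer``.
    """
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]"
        for c in iupac.upper()
    )
    return re.compile(f"(?=({body}))")


@dataclass
class PromoterRegion:
    """One gene's upstream region, oriented 5'->3' toward the gene."""

    gene_id: str
    seq_id: str
    strand: str
    start: int  # genomic forward-strand interval, 0-based half-open
    end: int
    sequence: str
    clipped: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_promoters(
    annotations: Sequence[GeneAnnotation],
    genome: Mapping[str, str],
    length: int = 3000,
) -> list[PromoterRegion]:
    """The ``length`` bases upstream of each gene's TSS, in transcription
    orientation.

    For a plus-strand gene the region is the forward-strand window ending at
    the base before the gene start; for a minus-strand gene it is the window
    after the gene end, reverse-complemented.  Regions shorter than
    ``length`` at a chromosome edge are clipped and flagged (with a warning).
    A gene on an unknown sequence is an error.
    """
    regions = []
    for gene in annotations:
        if gene.seq_id not in genome:
            raise KeyError(f"gene {gene.gene_id!r}: sequence {gene.seq_id!r} not in genome")
        chrom = genome[gene.seq_id]
        if gene.strand == "+":
            start = max(gene.start - length, 0)
            end = gene.start
            seq = chrom[start:end]
        else:
            start = gene.end
            end = min(gene.end + length, len(chrom))
            seq = reverse_complement(chrom[start:end])
        clipped = len(seq) < length
        if clipped:
            warnings.warn(
                f"promoter of {gene.gene_id} clipped to {len(seq)} bp at a sequence edge"
            )
        regions.append(
            PromoterRegion(gene.gene_id, gene.seq_id, gene.strand, start, end, seq, clipped)
        )
    return regions


@dataclass
class ElementCountTable:
    """Per-promoter element counts plus every occurrence's TSS-relative
    position and strand."""

    counts: pd.DataFrame  # promoter x element
    occurrences: pd.DataFrame  # promoter, element, position, strand

    def count(self, promoter: str, element: str) -> int:
        return int(self.counts.loc[promoter, element])

    @property
    def promoters(self) -> list[str]:
        return list(self.counts.index)

    @property
    def elements(self) -> list[str]:
        return list(self.counts.columns)


def scan_elements(
    regions: Sequence[PromoterRegion],
    patterns: Sequence[ElementPattern],
    strands: str = "both",
) -> ElementCountTable:
    """Census of every pattern over every promoter.

    ``strands`` is ``"both"`` (promoter strand plus its reverse complement;
    the convention of classic plant cis-element catalogues) or ``"forward"``.
    All overlapping matches are counted.  Positions are relative to the TSS:
    the last promoter base is −1.  For a palindromic pattern, a reverse-
    strand hit at an interval that already matched forward is suppressed.
    """
    if strands not in {"both", "forward"}:
        raise ValueError("strands must be 'both' or 'forward'")
    names = [p.name for p in patterns]
    if len(set(names)) != len(names):
        raise ValueError("element pattern names must be unique")
    rows = []
    for region in regions:
        seq = region.sequence.upper()
        offset = -len(seq)  # promoter index i -> TSS-relative i + offset
        for pat in patterns:
            fwd = iupac_regex(pat.iupac)
            fwd_positions = [m.start(1) for m in fwd.finditer(seq)]
            for pos in fwd_positions:
                rows.append((region.gene_id, pat.name, pos + offset, "+"))
            if strands == "both":
                rc_pat = pat.reverse_complement()
                rc_regex = iupac_regex(rc_pat.iupac)
                fwd_set = set(fwd_positions)
                for m in rc_regex.finditer(seq):
                    pos = m.start(1)
                    if pos in fwd_set and pat.is_palindromic():
                        continue
                    rows.append((region.gene_id, pat.name, pos + offset, "-"))
    occurrences = pd.DataFrame(rows, columns=["promoter", "element", "position", "strand"])
    promoter_ids = [r.gene_id for r in regions]
    counts = (
        occurrences.pivot_table(
            index="promoter", columns="element", values="position", aggfunc="count"
        )
        .reindex(index=promoter_ids, columns=names)
        .fillna(0)
        .astype(int)
    )
    counts.index.name = "promoter"
    counts.columns.name = "element"
    return ElementCountTable(counts, occurrences)


def elements_in_all(table: ElementCountTable) -> set[str]:
    """Elements present (count >= 1) in every promoter of the table."""
    if table.counts.empty:
        return set()
    return set(table.counts.columns[(table.counts >= 1).all(axis=0)])


def unique_elements(table: ElementCountTable, focal: str) -> set[str]:
    """Elements present in the focal promoter and absent from all others."""
    if focal not in table.counts.index:
        raise KeyError(f"unknown promoter {focal!r}")
    present_focal = table.counts.loc[focal] >= 1
    others = table.counts.drop(index=focal)
    absent_elsewhere = (others == 0).all(axis=0) if len(others) else pd.Series(
        True, index=table.counts.columns
    )
    return set(table.counts.columns[present_focal & absent_elsewhere])


def promoter_identity(
    regions: Sequence[PromoterRegion], convention: str = "pair_columns"
) -> IdentityMatrix:
    """Percent-identity matrix of the promoter set (progressive DNA MSA)."""
    if len(regions) < 2:
        raise ValueError("need at least 2 promoter regions")
    seqs = {r.gene_id: r.sequence for r in regions}
    aln = progressive_msa(seqs, dna_scoring())
    return identity_matrix(aln, convention)


def read_patterns(path) -> list[ElementPattern]:
    """Read a 2-column TSV (name, IUPAC) of element patterns."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["name", "iupac"], comment="#")
    return [ElementPattern(str(r["name"]), str(r["iupac"])) for _, r in frame.iterrows()]
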