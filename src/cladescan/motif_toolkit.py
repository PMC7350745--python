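"""Protein motif models: discovery from a seed alignment, scanning, comparison.

A motif is a short conserved amino-acid block (width 7-50 residues by
default) summarized as a position frequency matrix (PFM) with a consensus
string.  Discovery does not run expectation-maximization over unaligned
sequences; conserved blocks are extracted directly from a seed alignment by
per-column information content, which is what the downstream stages need:
models to scan with and consensus strings to compare.

Scanning is sliding-window log-odds: for a window w of the protein,
``score = sum_i log2(pfm[i][w_i] / background[w_i])`` in bits.  A hit is
"present" when its fraction of consensus-identical positions reaches the
identity threshold (default 0.6 — comfortably below the ~0.71 identity at
which two motif variants are still treated as the same motif) and its
log-odds is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import Alignment, pairwise_align, protein_scoring

__all__ = [
    "MotifModel",
    "MotifHit",
    "MotifArchitecture",
    "build_motif_model",
    "discover_motifs",
    "scan_protein",
    "call_presence",
    "architecture",
    "architecture_table",
    "compare_motifs",
    "write_motif_models",
    "read_motif_models",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_INDEX = {c: i for i, c in enumerate(RESIDUES)}

MIN_WIDTH = 7
MAX_WIDTH = 50
PSEUDOCOUNT = 0.01


@dataclass
class MotifModel:
    """A position frequency model for one conserved amino-acid block."""

    motif_id: str
    pfm: np.ndarray  # (width, 20) frequencies; columns sum to 1
    background: np.ndarray  # (20,) background residue frequencies
    total_ic: float = 0.0  # summed per-column information content, bits

    def __post_init__(self) -> None:
        if self.pfm.ndim != 2 or self.pfm.shape[1] != len(RESIDUES):
            raise ValueError("pfm must be (width, 20)")
        colsums = self.pfm.sum(axis=1)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("pfm rows must each sum to 1")
        if not len(self.background) == len(RESIDUES):
            raise ValueError("background must cover the 20 residues")

    @property
    def width(self) -> int:
        return self.pfm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(RESIDUES[i] for i in self.pfm.argmax(axis=1))

    def logodds(self) -> np.ndarray:
        """(width, 20) log2(pfm / background) score matrix, X scores 0."""
        return np.log2(self.pfm / self.background[None, :])

    def max_score(self) -> float:
        """Best attainable log-odds score (per-column maxima summed)."""
        return float(self.logodds().max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring placement of a motif in a protein (1-based residue coords)."""

    protein_id: str
    motif_id: str
    start: int  # 1-based
    end: int  # inclusive
    logodds: float
    consensus_identity: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class MotifArchitecture:
    """Present, overlap-resolved motif hits of one protein, ordered by start."""

    protein_id: str
    hits: list[MotifHit] = field(default_factory=list)

    @property
    def motif_order(self) -> list[str]:
        return [h.motif_id for h in self.hits]

    def presence_vector(self, motif_ids: Sequence[str]) -> dict[str, bool]:
        present = {h.motif_id for h in self.hits}
        return {m: m in present for m in motif_ids}


def _encode(protein: str) -> np.ndarray:
    """Residue indices; X (or any unknown) becomes -1 and scores 0."""
    return np.array([_RESIDUE_INDEX.get(c, -1) for c in protein], dtype=np.intp)


def residue_frequencies(seqs: Iterable[str], pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    counts = np.full(len(RESIDUES), pseudocount)
    for seq in seqs:
        for c in seq:
            if c in _RESIDUE_INDEX:
                counts[_RESIDUE_INDEX[c]] += 1.0
    return counts / counts.sum()


def build_motif_model(
    motif_id: str,
    aligned_block: Sequence[str],
    background: np.ndarray,
    pseudocount: float = PSEUDOCOUNT,
) -> MotifModel:
    """PFM from the rows of one aligned block (gaps ignored per column)."""
    width = len(aligned_block[0])
    pfm = np.full((width, len(RESIDUES)), pseudocount)
    for row in aligned_block:
        for j, c in enumerate(row):
            if c in _RESIDUE_INDEX:
                pfm[j, _RESIDUE_INDEX[c]] += 1.0
    pfm /= pfm.sum(axis=1, keepdims=True)
    ic = float((pfm * np.log2(pfm / background[None, :])).sum())
    return MotifModel(motif_id, pfm, background, total_ic=ic)


def column_information(aln: Alignment, background: np.ndarray) -> np.ndarray:
    """Per-column information content (bits) of the non-gap residues."""
    out = np.zeros(aln.n_cols)
    for j in range(aln.n_cols):
        col = [c for c in aln.column(j) if c in _RESIDUE_INDEX]
        if not col:
            continue
        freq = np.full(len(RESIDUES), PSEUDOCOUNT)
        for c in col:
            freq[_RESIDUE_INDEX[c]] += 1.0
        freq /= freq.sum()
        out[j] = (freq * np.log2(freq / background)).sum()
    return out


def discover_motifs(
    seed_alignment: Alignment,
    min_width: int = MIN_WIDTH,
    max_width: int = MAX_WIDTH,
    max_motifs: int = 13,
    ic_threshold: float = 2.0,
    max_gap_fraction: float = 0.2,
) -> list[MotifModel]:
    """Extract conserved blocks from a seed alignment as motif models.

    Columns are scored by information content against the seed-set residue
    background; maximal runs of columns with IC >= ``ic_threshold`` and gap
    fraction <= ``max_gap_fraction``, at least ``min_width`` long, become
    motifs (runs longer than ``max_width`` are split into near-equal pieces).
    Motifs are numbered M1, M2, ... by decreasing total information content;
    at most ``max_motifs`` are kept.

    Raises ``ValueError`` for fewer than 3 sequences; returns an empty list
    (with a warning) when no column passes the threshold.
    """
    if seed_alignment.n_rows < 3:
        raise ValueError("motif discovery needs an alignment of >= 3 sequences")
    background = residue_frequencies(
        row.replace("-", "") for row in seed_alignment.rows
    )
    ic = column_information(seed_alignment, background)
    n_rows = seed_alignment.n_rows
    gap_frac = np.array(
        [seed_alignment.column(j).count("-") / n_rows for j in range(seed_alignment.n_cols)]
    )
    passing = (ic >= ic_threshold) & (gap_frac <= max_gap_fraction)
    if not passing.any():
        warnings.warn("no alignment column passes the conservation threshold")
        return []

    # maximal runs of passing columns
    runs: list[tuple[int, int]] = []
    j = 0
    while j < len(passing):
        if passing[j]:
            k = j
            while k < len(passing) and passing[k]:
                k += 1
            runs.append((j, k))
            j = k
        else:
            j += 1

    blocks: list[tuple[int, int]] = []
    for start, end in runs:
        length = end - start
        if length < min_width:
            continue
        if length <= max_width:
            blocks.append((start, end))
        else:
            n_pieces = int(np.ceil(length / max_width))
            bounds = np.linspace(start, end, n_pieces + 1).round().astype(int)
            blocks.extend(zip(bounds[:-1], bounds[1:]))

    models = []
    for start, end in blocks:
        rows = [row[start:end] for row in seed_alignment.rows]
        models.append(build_motif_model(f"block{start}", rows, background))
    models.sort(key=lambda m: (-m.total_ic, m.motif_id))
    models = models[:max_motifs]
    for rank, model in enumerate(models, start=1):
        model.motif_id = f"M{rank}"
    return models


def scan_protein(protein: str, motif: MotifModel, protein_id: str = "") -> MotifHit | None:
    """Best log-odds window of ``motif`` in ``protein``; None if too short.

    Ties are broken by the smallest start position.
    """
    width = motif.width
    if len(protein) < width:
        return None
    encoded = _encode(protein)
    lo = motif.logodds()
    n_windows = len(protein) - width + 1
    cons = np.array([_RESIDUE_INDEX[c] for c in motif.consensus], dtype=np.intp)
    # windows x width index matrix; X (index -1) scores 0 and never matches
    idx = encoded[np.arange(n_windows)[:, None] + np.arange(width)[None, :]]
    valid = idx >= 0
    scores = np.where(valid, lo[np.arange(width)[None, :], idx], 0.0).sum(axis=1)
    best = int(np.argmax(scores))  # argmax returns the first (smallest start)
    ident = float((idx[best] == cons).mean())
    return MotifHit(
        protein_id=protein_id,
        motif_id=motif.motif_id,
        start=best + 1,
        end=best + width,
        logodds=float(scores[best]),
        consensus_identity=ident,
    )


def call_presence(hit: MotifHit | None, identity_threshold: float = 0.6) -> bool:
    """Presence call: consensus identity >= threshold and positive log-odds."""
    if hit is None:
        return False
    return hit.consensus_identity >= identity_threshold and hit.logodds > 0


def architecture(
    protein: str,
    motifs: Sequence[MotifModel],
    protein_id: str = "",
    identity_threshold: float = 0.6,
) -> MotifArchitecture:
    """All present hits of ``motifs`` in one protein, overlap-resolved.

    Overlaps keep the higher log-odds hit (tie: smaller motif id); the result
    is sorted by start position.
    """
    hits = []
    for motif in motifs:
        hit = scan_protein(protein, motif, protein_id)
        if call_presence(hit, identity_threshold):
            hits.append(hit)
    # overlap resolution: scan hits in priority order, keep non-overlapping
    hits.sort(key=lambda h: (-h.logodds, h.motif_id))
    kept: list[MotifHit] = []
    for hit in hits:
        if all(hit.end < k.start or hit.start > k.end for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return MotifArchitecture(protein_id, kept)


def architecture_table(
    proteins: Mapping[str, str],
    motifs: Sequence[MotifModel],
    identity_threshold: float = 0.6,
) -> pd.DataFrame:
    """Presence matrix (protein x motif, boolean) over a protein set."""
    motif_ids = [m.motif_id for m in motifs]
    rows = {}
    for pid, seq in proteins.items():
        arch = architecture(seq, motifs, pid, identity_threshold)
        rows[pid] = arch.presence_vector(motif_ids)
    return pd.DataFrame.from_dict(rows, orient="index", columns=motif_ids).fillna(False)


def compare_motifs(a: MotifModel, b: MotifModel) -> float:
    """Percent identity of two motif consensus strings under global alignment.

    Identity = identical columns / total alignment columns, x 100.
    """
    res = pairwise_align(a.consensus, b.consensus, protein_scoring())
    row_a, row_b = res.alignment.rows
    ident = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return 100.0 * ident / len(row_a)


# ---------------------------------------------------------------------------
# Serialization: summary TSV + companion PFM table


def write_motif_models(models: Sequence[MotifModel], prefix: str | Path) -> None:
    """Write ``<prefix>.tsv`` (id, width, total IC, consensus) and
    ``<prefix>.pfm.tsv`` (long-form per-position frequencies)."""
    prefix = Path(prefix)
    summary = pd.DataFrame(
        {
            "motif_id": [m.motif_id for m in models],
            "width": [m.width for m in models],
            "total_ic": [m.total_ic for m in models],
            "consensus": [m.consensus for m in models],
        }
    )
    summary.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    rows = []
    for m in models:
        for pos in range(m.width):
            rows.append([m.motif_id, pos] + list(m.pfm[pos]))
        rows.append([m.motif_id, -1] + list(m.background))
    pfm = pd.DataFrame(rows, columns=["motif_id", "position"] + list(RESIDUES))
    pfm.to_csv(prefix.parent / (prefix.name + ".pfm.tsv"), sep="\t", index=False)


def read_motif_models(prefix: str | Path) -> list[MotifModel]:
    prefix = Path(prefix)
    summary = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    pfm_long = pd.read_csv(prefix.parent / (prefix.name + ".pfm.tsv"), sep="\t")
    models = []
    for _, row in summary.iterrows():
        sub = pfm_long[pfm_long["motif_id"] == row["motif_id"]]
        background = sub[sub["position"] == -1][list(RESIDUES)].to_numpy()[0]
        body = sub[sub["position"] >= 0].sort_values("position")
        pfm = body[list(RESIDUES)].to_numpy()
        models.append(
            MotifModel(row["motif_id"], pfm, background, total_ic=float(row["total_ic"]))
        )
    return models
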