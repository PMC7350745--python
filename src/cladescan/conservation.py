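"""Alignment, percent-identity matrices and a bootstrap neighbor-joining tree.

Pairwise global alignment uses an affine gap model (Gotoh): a gap run of
length L costs ``-(open + (L-1) * extend)`` in score terms, matching the
convention of Biopython's ``PairwiseAligner``, which provides the pairwise
implementation.  The progressive multiple aligner builds a UPGMA guide tree
on ``1 - identity/100`` distances and aligns profiles along it with
sum-of-pairs column scoring under the same gap model.

Percent identity between two rows of an alignment is, by default, the number
of columns where both carry the same residue divided by the number of columns
where at least one of the pair is non-gap, as a percentage ("pair_columns"
convention).  A "shorter" convention (denominator = length of the shorter
de-gapped sequence) is available because published identity figures do not
always state their denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "Alignment",
    "AlignmentScoring",
    "protein_scoring",
    "dna_scoring",
    "PairwiseResult",
    "pairwise_align",
    "progressive_msa",
    "IdentityMatrix",
    "identity_matrix",
    "Phylogeny",
    "nj_tree",
    "distance_from_identity",
]

_NEG = -1.0e30

PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWYX"
DNA_LETTERS = "ACGTN"


# ---------------------------------------------------------------------------
# Scoring


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus affine gap scores (both negative)."""

    alphabet: str
    matrix: np.ndarray  # square, indexed by alphabet position
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        if self.matrix.shape != (k, k):
            raise ValueError("substitution matrix does not match alphabet")

    def index(self, seq: str) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.alphabet)}
        try:
            return np.array([lut[c] for c in seq], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - guarded by io validation
            raise ValueError(f"character {exc.args[0]!r} not in scoring alphabet")


def protein_scoring(gap_open: float = -10.0, gap_extend: float = -1.0) -> AlignmentScoring:
    """BLOSUM62 over the 20 residues plus X, affine gaps (default 10/1)."""
    blosum = substitution_matrices.load("BLOSUM62")
    k = len(PROTEIN_LETTERS)
    mat = np.zeros((k, k))
    for i, a in enumerate(PROTEIN_LETTERS):
        for j, b in enumerate(PROTEIN_LETTERS):
            mat[i, j] = blosum[a, b]
    return AlignmentScoring(PROTEIN_LETTERS, mat, gap_open, gap_extend)


def dna_scoring(
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignmentScoring:
    """Match/mismatch DNA scoring; N is neutral (scores 0 against anything)."""
    k = len(DNA_LETTERS)
    mat = np.full((k, k), mismatch)
    np.fill_diagonal(mat, match)
    n_idx = DNA_LETTERS.index("N")
    mat[n_idx, :] = 0.0
    mat[:, n_idx] = 0.0
    return AlignmentScoring(DNA_LETTERS, mat, gap_open, gap_extend)


def _default_scoring(seqs: Sequence[str]) -> AlignmentScoring:
    letters = set("".join(seqs))
    if letters <= set(DNA_LETTERS):
        return dna_scoring()
    return protein_scoring()


# ---------------------------------------------------------------------------
# Alignment container


@dataclass
class Alignment:
    """An alignment: parallel ids and equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids are not unique")
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise ValueError("alignment rows differ in length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)].replace("-", "")

    def to_mapping(self) -> dict[str, str]:
        return dict(zip(self.ids, self.rows))

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def subsample_columns(self, cols: Sequence[int]) -> "Alignment":
        rows = ["".join(row[j] for j in cols) for row in self.rows]
        return Alignment(list(self.ids), rows)


def pair_identity(row_a: str, row_b: str, convention: str = "pair_columns") -> float:
    """Percent identity between two gapped rows of an alignment.

    Columns gapped in both rows are skipped.  ``convention`` picks the
    denominator: "pair_columns" (columns where at least one is non-gap) or
    "shorter" (length of the shorter de-gapped sequence).
    """
    ident = 0
    cols = 0
    for a, b in zip(row_a, row_b):
        if a == "-" and b == "-":
            continue
        cols += 1
        if a == b:
            ident += 1
    if convention == "pair_columns":
        denom = cols
    elif convention == "shorter":
        denom = min(len(row_a.replace("-", "")), len(row_b.replace("-", "")))
    else:
        raise ValueError(f"unknown identity convention {convention!r}")
    if denom == 0:
        return 0.0
    return 100.0 * ident / denom


# ---------------------------------------------------------------------------
# Pairwise alignment (Gotoh, via Biopython's C implementation)


@dataclass
class PairwiseResult:
    alignment: Alignment
    score: float
    identity: float


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    sub = substitution_matrices.Array(alphabet=scoring.alphabet, dims=2)
    for i, a in enumerate(scoring.alphabet):
        for j, b in enumerate(scoring.alphabet):
            sub[a, b] = scoring.matrix[i, j]
    aligner.substitution_matrix = sub
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def pairwise_align(
    a: str,
    b: str,
    scoring: AlignmentScoring | None = None,
    ids: tuple[str, str] = ("seq1", "seq2"),
    convention: str = "pair_columns",
) -> PairwiseResult:
    """Optimal global affine-gap alignment of two sequences with identity.

    Raises ``ValueError`` on an empty sequence.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if scoring is None:
        scoring = _default_scoring([a, b])
    aligner = _make_aligner(scoring)
    best = aligner.align(a, b)[0]
    row_a, row_b = str(best[0]), str(best[1])
    aln = Alignment(list(ids), [row_a, row_b])
    return PairwiseResult(aln, float(best.score), pair_identity(row_a, row_b, convention))


# ---------------------------------------------------------------------------
# Profile-profile Gotoh and progressive MSA


def _profile(rows: list[str], scoring: AlignmentScoring) -> np.ndarray:
    """Column frequency profile (L x K); gaps contribute zero mass."""
    k = len(scoring.alphabet)
    length = len(rows[0])
    prof = np.zeros((length, k))
    lut = {c: i for i, c in enumerate(scoring.alphabet)}
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                prof[j, lut[c]] += 1.0
    return prof / len(rows)


def _profile_gotoh(
    rows_a: list[str], rows_b: list[str], scoring: AlignmentScoring
) -> tuple[list[str], list[str], float]:
    """Globally align two profiles; returns gapped rows for each side + score."""
    prof_a = _profile(rows_a, scoring)
    prof_b = _profile(rows_b, scoring)
    n, m = prof_a.shape[0], prof_b.shape[0]
    score = (prof_a @ scoring.matrix) @ prof_b.T  # (n, m) expected pair score
    go, ge = scoring.gap_open, scoring.gap_extend

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in B (consumes A column)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in A (consumes B column)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = go + ge * np.arange(n)
    if m:
        Y[0, 1:] = go + ge * np.arange(m)

    js = np.arange(m)
    for i in range(1, n + 1):
        diag = np.maximum.reduce([M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
        M[i, 1:] = score[i - 1] + diag
        X[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] + go, X[i - 1, 1:] + ge, Y[i - 1, 1:] + go]
        )
        X[i, 0] = go + ge * (i - 1)
        # Y has an intra-row recurrence; solve it with a prefix max.
        best = np.maximum(M[i, :-1], X[i, :-1])  # candidates at k = 0..m-1
        t = np.maximum.accumulate(best - js * ge)
        Y[i, 1:] = t + js * ge + go

    # Traceback by predecessor recomputation.
    ops: list[tuple[str, int, int]] = []
    i, j = n, m
    state = max(("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m]), key=lambda t: t[1])[0]
    tol = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            ops.append(("match", i - 1, j - 1))
            prev = M[i, j] - score[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand in ("M", "X", "Y"):
                val = {"M": M, "X": X, "Y": Y}[cand][i, j]
                if abs(val - prev) <= tol:
                    state = cand
                    break
        elif state == "X":
            ops.append(("gap_b", i - 1, -1))
            val = X[i, j]
            i -= 1
            if abs(X[i, j] + ge - val) <= tol:
                state = "X"
            elif abs(M[i, j] + go - val) <= tol:
                state = "M"
            else:
                state = "Y"
        else:  # Y
            ops.append(("gap_a", -1, j - 1))
            val = Y[i, j]
            j -= 1
            if abs(Y[i, j] + ge - val) <= tol:
                state = "Y"
            elif abs(M[i, j] + go - val) <= tol:
                state = "M"
            else:
                state = "X"
    ops.reverse()

    out_a = []
    out_b = []
    for op, ia, jb in ops:
        if op == "match":
            out_a.append(ia)
            out_b.append(jb)
        elif op == "gap_b":
            out_a.append(ia)
            out_b.append(None)
        else:
            out_a.append(None)
            out_b.append(jb)
    new_a = ["".join(row[c] if c is not None else "-" for c in out_a) for row in rows_a]
    new_b = ["".join(row[c] if c is not None else "-" for c in out_b) for row in rows_b]
    total = max(M[n, m], X[n, m], Y[n, m])
    return new_a, new_b, float(total)


def _upgma_guide(ids: list[str], dist: np.ndarray):
    """UPGMA merge order on a distance matrix; ties broken lexicographically.

    Returns a nested tuple tree whose leaves are ids.
    """
    clusters: dict[str, tuple] = {i: i for i in ids}
    sizes = {i: 1 for i in ids}
    labels = list(ids)
    d = {
        tuple(sorted((a, b))): dist[ids.index(a), ids.index(b)]
        for a, b in itertools.combinations(ids, 2)
    }

    def get(a: str, b: str) -> float:
        return d[tuple(sorted((a, b)))]

    while len(labels) > 1:
        best_pair = None
        best_val = np.inf
        for a, b in itertools.combinations(sorted(labels), 2):
            val = get(a, b)
            if val < best_val - 1e-12:
                best_val = val
                best_pair = (a, b)
        a, b = best_pair
        merged = (clusters[a], clusters[b])
        new_label = min(a, b)
        new_dist = {}
        for c in labels:
            if c in (a, b):
                continue
            avg = (get(a, c) * sizes[a] + get(b, c) * sizes[b]) / (sizes[a] + sizes[b])
            new_dist[tuple(sorted((new_label, c)))] = avg
        labels = [c for c in labels if c not in (a, b)] + [new_label]
        new_size = sizes[a] + sizes[b]
        d.update(new_dist)
        clusters[new_label] = merged
        sizes[new_label] = new_size
    return clusters[labels[0]]


def progressive_msa(
    seqs: Mapping[str, str], scoring: AlignmentScoring | None = None
) -> Alignment:
    """Progressive multiple alignment: UPGMA guide tree, profile-profile Gotoh.

    With exactly two sequences this reduces to :func:`pairwise_align` so the
    two entry points agree by construction.  Raises on fewer than 2 sequences.
    """
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    sequences = [seqs[i] for i in ids]
    if scoring is None:
        scoring = _default_scoring(sequences)
    if len(ids) == 2:
        res = pairwise_align(sequences[0], sequences[1], scoring, ids=(ids[0], ids[1]))
        return res.alignment

    n = len(ids)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ident = pairwise_align(sequences[i], sequences[j], scoring).identity
        dist[i, j] = dist[j, i] = 1.0 - ident / 100.0
    guide = _upgma_guide(ids, dist)

    def align_node(node) -> tuple[list[str], list[str]]:
        if isinstance(node, str):
            return [node], [seqs[node]]
        left_ids, left_rows = align_node(node[0])
        right_ids, right_rows = align_node(node[1])
        new_l, new_r, _ = _profile_gotoh(left_rows, right_rows, scoring)
        return left_ids + right_ids, new_l + new_r

    out_ids, out_rows = align_node(guide)
    order = {name: k for k, name in enumerate(out_ids)}
    rows = [out_rows[order[name]] for name in ids]
    return Alignment(ids, rows)


def sum_of_pairs_score(aln: Alignment, scoring: AlignmentScoring) -> float:
    """Sum-of-pairs score of an alignment under the given scoring.

    Gap runs are charged per sequence pair with the affine model; a column
    where both rows are gapped contributes nothing.
    """
    total = 0.0
    for r1, r2 in itertools.combinations(range(aln.n_rows), 2):
        a, b = aln.rows[r1], aln.rows[r2]
        in_gap = False
        for ca, cb in zip(a, b):
            if ca == "-" and cb == "-":
                continue
            if ca == "-" or cb == "-":
                total += scoring.gap_extend if in_gap else scoring.gap_open
                in_gap = True
            else:
                ia = scoring.alphabet.index(ca)
                ib = scoring.alphabet.index(cb)
                total += scoring.matrix[ia, ib]
                in_gap = False
    return total


# ---------------------------------------------------------------------------
# Identity matrices


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix with diagonal 100."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("identity matrix shape does not match ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def mean_off_diagonal(self) -> float:
        n = len(self.ids)
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())

    def row_means(self) -> pd.Series:
        """Per-sequence mean identity to all other sequences."""
        n = len(self.ids)
        sums = self.values.sum(axis=1) - np.diag(self.values)
        return pd.Series(sums / (n - 1), index=self.ids)


def identity_matrix(aln: Alignment, convention: str = "pair_columns") -> IdentityMatrix:
    """Pairwise percent identity within an MSA (double-gap columns skipped)."""
    n = aln.n_rows
    values = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        ident = pair_identity(aln.rows[i], aln.rows[j], convention)
        values[i, j] = values[j, i] = ident
    return IdentityMatrix(list(aln.ids), values)


def distance_from_identity(im: IdentityMatrix) -> DistanceMatrix:
    d = 1.0 - im.values / 100.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=im.ids)


# ---------------------------------------------------------------------------
# Neighbor joining with bootstrap


@dataclass
class Phylogeny:
    """Unrooted NJ tree with per-internal-bipartition bootstrap support."""

    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.tree)

    def monophyletic(self, group: set[str]) -> bool:
        """True if `group` forms one side of some bipartition of the tree."""
        group = frozenset(group)
        comp = frozenset(self.leaf_names - group)
        return group in self.bipartitions() or comp in self.bipartitions()

    def support_for(self, group: set[str]) -> float | None:
        group = frozenset(group)
        comp = frozenset(self.leaf_names - group)
        for key in (group, comp):
            if key in self.supports:
                return self.supports[key]
        return None

    def newick(self) -> str:
        """Newick with bootstrap supports as internal node labels."""
        tree = self.tree.copy()
        leaves = frozenset(t.name for t in tree.tips())
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            support = self.supports.get(side, self.supports.get(leaves - side))
            if support is not None:
                node.name = f"{support:g}"
        return str(tree).strip()


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions (each as the set of tips under an edge)."""
    all_tips = frozenset(t.name for t in tree.tips())
    n = len(all_tips)
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < n - 1:
            # canonicalize: store the side not containing the smallest tip
            smallest = min(all_tips)
            parts.add(all_tips - side if smallest in side else side)
    return parts


def nj_tree(
    dist: DistanceMatrix | None = None,
    *,
    alignment: Alignment | None = None,
    convention: str = "pair_columns",
    bootstrap_n: int = 100,
    seed: int = 0,
) -> Phylogeny:
    """Neighbor-joining tree with column-resampling bootstrap supports.

    Either a precomputed distance matrix (no bootstrap possible) or an
    alignment (distances = 1 - identity/100, columns resampled with
    replacement for supports) must be given.
    """
    if alignment is None and dist is None:
        raise ValueError("provide a distance matrix or an alignment")
    if alignment is not None:
        dist = distance_from_identity(identity_matrix(alignment, convention))
    if len(dist.ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tree = nj(dist)
    supports: dict[frozenset, float] = {}
    if alignment is not None and bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        counts: dict[frozenset, int] = {part: 0 for part in _bipartitions(tree)}
        n_cols = alignment.n_cols
        for _ in range(bootstrap_n):
            cols = rng.integers(0, n_cols, size=n_cols)
            rep_aln = alignment.subsample_columns(list(cols))
            rep_dist = distance_from_identity(identity_matrix(rep_aln, convention))
            rep_parts = _bipartitions(nj(rep_dist))
            for part in counts:
                if part in rep_parts:
                    counts[part] += 1
        supports = {part: c / bootstrap_n for part, c in counts.items()}
    return Phylogeny(tree, supports)
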