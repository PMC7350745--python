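"""Soft-threshold co-expression networks, topological overlap, consensus.

Per expression series: Pearson correlation between gene expression profiles
is raised to a soft-thresholding power beta (unsigned network,
``a_ij = |cor|^beta``), the topological overlap matrix (TOM) is

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity ``k_i = sum_u a_iu`` and TOM_ii = 1, and the genes most
connected to a seed gene or to a whole clade (mean TOM to its members) form
a top-k neighborhood.  Neighborhoods from several series are intersected:
genes appearing in at least ``min_series`` of them are the cross-series
consensus, reported with their per-gene series counts (clade members
themselves excluded from the report).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "filter_genes",
    "adjacency",
    "tom",
    "TOMatrix",
    "NeighborhoodSet",
    "top_connected",
    "consensus",
    "series_neighborhoods",
]


def filter_genes(matrix: pd.DataFrame, min_mean: float = 0.1) -> pd.DataFrame:
    """Drop zero-variance genes and genes below a mean-expression floor.

    The floor is applied on the scale of the input matrix (the pipeline
    applies it after the log2(x+1) transform, default floor 0.1).
    """
    values = matrix.to_numpy()
    keep = (values.std(axis=1) > 0) & (values.mean(axis=1) >= min_mean)
    return matrix.loc[keep]


def adjacency(matrix: pd.DataFrame, beta: float = 6.0, mode: str = "unsigned") -> pd.DataFrame:
    """WGCNA-style soft-threshold adjacency from a gene x sample matrix.

    ``a_ij = |cor|^beta`` (unsigned) or ``((1+cor)/2)^beta`` (signed), with
    zero diagonal so downstream connectivity sums exclude self-edges.
    Zero-variance genes must be filtered beforehand (error otherwise).
    """
    if matrix.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    values = matrix.to_numpy()
    if (values.std(axis=1) == 0).any():
        bad = matrix.index[values.std(axis=1) == 0][0]
        raise ValueError(f"zero-variance gene {bad!r}; filter genes first")
    cor = np.corrcoef(values)
    if mode == "unsigned":
        adj = np.abs(cor) ** beta
    elif mode == "signed":
        adj = ((1.0 + cor) / 2.0) ** beta
    else:
        raise ValueError("mode must be 'unsigned' or 'signed'")
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=matrix.index, columns=matrix.index)


@dataclass
class TOMatrix:
    """Topological overlap matrix: symmetric, values in [0, 1], diagonal 1."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise ValueError("TOM must be square")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def tom(adj: pd.DataFrame) -> TOMatrix:
    """Topological overlap from an adjacency matrix (zero diagonal)."""
    a = adj.to_numpy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.diag(a).any():
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu * a_uj (u = i and u = j contribute 0)
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(t, 1.0)
    return TOMatrix(pd.DataFrame(t, index=adj.index, columns=adj.columns))


@dataclass
class NeighborhoodSet:
    """Top-k genes most connected to a seed in one series."""

    series_id: str
    seed: tuple[str, ...]
    ranked: pd.Series  # gene -> connectivity score, descending

    @property
    def genes(self) -> list[str]:
        return list(self.ranked.index)


def top_connected(
    t: TOMatrix,
    seed: str | Sequence[str],
    k: int = 100,
    include_seed_members: bool = True,
    series_id: str = "",
) -> NeighborhoodSet:
    """Rank genes by TOM connectivity to a seed gene or a clade.

    A single-gene seed ranks all other genes by that gene's TOM row; a clade
    seed scores each gene by its mean TOM to the clade members (the members
    themselves are eligible candidates when ``include_seed_members``, scored
    against the other members).  Returns at most ``k`` genes, ordered by
    descending score with ties broken by gene id.
    """
    genes = t.genes
    if isinstance(seed, str):
        seed_ids = [seed]
    else:
        seed_ids = list(seed)
    missing = [s for s in seed_ids if s not in t.values.index]
    if missing:
        raise KeyError(f"seed gene(s) not in TOM: {missing}")
    v = t.values
    if len(seed_ids) == 1:
        scores = v.loc[seed_ids[0]].drop(index=seed_ids[0])
    else:
        seed_set = set(seed_ids)
        score_map = {}
        for g in genes:
            members = [s for s in seed_ids if s != g]
            score_map[g] = float(v.loc[g, members].mean())
        scores = pd.Series(score_map)
        if not include_seed_members:
            scores = scores.drop(index=[g for g in genes if g in seed_set])
    # deterministic ordering: descending score, ties by gene id
    ranked = scores.sort_index().sort_values(ascending=False, kind="stable")
    ranked = ranked.iloc[:k]
    return NeighborhoodSet(series_id, tuple(seed_ids), ranked)


def consensus(
    neighborhoods: Sequence[NeighborhoodSet], min_series: int
) -> pd.DataFrame:
    """Genes present in at least ``min_series`` neighborhoods.

    Seed/clade members are excluded from the report.  Returns a DataFrame
    with columns ``gene`` and ``n_series``, sorted by descending count then
    gene id.
    """
    if len(neighborhoods) < 2:
        raise ValueError("consensus needs at least 2 series")
    seed_members = set()
    for nb in neighborhoods:
        seed_members.update(nb.seed)
    counts: dict[str, int] = {}
    for nb in neighborhoods:
        for g in nb.genes:
            if g in seed_members:
                continue
            counts[g] = counts.get(g, 0) + 1
    rows = [(g, c) for g, c in counts.items() if c >= min_series]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene", "n_series"])


def series_neighborhoods(
    series: Sequence[pd.DataFrame] | Mapping[str, pd.DataFrame],
    seed: str | Sequence[str],
    beta: float = 6.0,
    k: int = 100,
    min_mean: float = 0.1,
    include_seed_members: bool = True,
) -> list[NeighborhoodSet]:
    """Per-series pipeline: log2(x+1) -> filter -> adjacency -> TOM -> top-k."""
    from .expression_stats import log2p1

    if isinstance(series, Mapping):
        items = list(series.items())
    else:
        items = [(f"series{i + 1}", m) for i, m in enumerate(series)]
    out = []
    for name, matrix in items:
        logm = log2p1(matrix)
        filtered = filter_genes(logm, min_mean=min_mean)
        t = tom(adjacency(filtered, beta=beta))
        out.append(
            top_connected(
                t, seed, k=k, include_seed_members=include_seed_members, series_id=name
            )
        )
    return out
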