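"""Meta-analysis summary statistics over expression matrices and DEG tables.

- ``log2p1``: elementwise log2(x + 1), the transform used throughout the
  expression views.
- ``zscore_per_gene``: per-row standardization ((x - mean) / sd, sd with
  denominator n-1); constant rows are emitted as zeros and flagged.
- ``fold_dominance``: how much more a focal clade member is expressed than
  the average of the rest of its clade, computed per series on the raw
  (untransformed) scale and averaged across series.
- ``deg_frequency``: in how many differential-expression contrasts each gene
  of interest appears as a DEG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "log2p1",
    "zscore_per_gene",
    "FoldDominance",
    "fold_dominance",
    "DEGSetCollection",
    "deg_frequency",
]


def log2p1(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1).  Negative input is an error."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("log2p1 requires non-negative values")
    return pd.DataFrame(np.log2(values + 1.0), index=matrix.index, columns=matrix.columns)


def zscore_per_gene(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene Z-scores ((x - row mean) / row sd, sd denominator n-1).

    Returns the standardized matrix and the list of constant (zero-sd) genes,
    whose rows are emitted as zeros.
    """
    if matrix.shape[1] < 2:
        raise ValueError("Z-scores need at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    flat = sds[:, 0] == 0
    safe = np.where(sds == 0, 1.0, sds)
    z = (values - means) / safe
    z[flat, :] = 0.0
    flagged = list(matrix.index[flat])
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


@dataclass
class FoldDominance:
    """Per-series focal/clade-average expression ratios and their mean."""

    per_series: dict[str, float]  # may contain NaN for undefined series
    mean_ratio: float
    pooled_ratio: float


def fold_dominance(
    series: Sequence[pd.DataFrame] | Mapping[str, pd.DataFrame],
    focal: str,
    clade: Sequence[str],
) -> FoldDominance:
    """Expression dominance of one clade member over the rest of its clade.

    Per series (raw scale): ``ratio = mean_samples(focal) /
    mean_{samples, genes}(clade \\ focal)``.  The aggregate is the arithmetic
    mean of the per-series ratios; a pooled variant (total focal mean over
    total others mean across all series) is also reported.  A series with a
    zero denominator is flagged undefined (NaN) and excluded from the mean
    with a warning.
    """
    if focal not in clade:
        raise ValueError("focal gene must be a member of the clade")
    others = [g for g in clade if g != focal]
    if not others:
        raise ValueError("clade must contain more than the focal gene")
    if isinstance(series, Mapping):
        items = list(series.items())
    else:
        items = [(f"series{i + 1}", m) for i, m in enumerate(series)]

    per_series: dict[str, float] = {}
    focal_means, other_means = [], []
    for name, matrix in items:
        missing = [g for g in clade if g not in matrix.index]
        if missing:
            raise KeyError(f"series {name!r}: clade gene(s) missing: {missing}")
        focal_mean = float(matrix.loc[focal].mean())
        other_mean = float(matrix.loc[others].to_numpy().mean())
        focal_means.append(focal_mean)
        other_means.append(other_mean)
        if other_mean == 0:
            warnings.warn(f"series {name!r}: zero clade-average expression; ratio undefined")
            per_series[name] = float("nan")
        else:
            per_series[name] = focal_mean / other_mean
    defined = [v for v in per_series.values() if not np.isnan(v)]
    mean_ratio = float(np.mean(defined)) if defined else float("nan")
    total_others = float(np.mean(other_means))
    pooled = float(np.mean(focal_means)) / total_others if total_others else float("nan")
    return FoldDominance(per_series, mean_ratio, pooled)


@dataclass
class DEGSetCollection:
    """Labelled differential-expression contrasts with their DEG id sets."""

    contrasts: dict[str, set[str]]

    def __post_init__(self) -> None:
        # dict construction already enforces unique labels; validate types
        for label, genes in self.contrasts.items():
            if not isinstance(genes, set):
                self.contrasts[label] = set(genes)

    @classmethod
    def from_files(cls, paths: Mapping[str, str]) -> "DEGSetCollection":
        """Each file: one gene id per line (TSV gene lists)."""
        contrasts = {}
        for label, path in paths.items():
            with open(path) as handle:
                contrasts[label] = {
                    line.strip().split("\t")[0] for line in handle if line.strip()
                }
        return cls(contrasts)


def deg_frequency(degs: DEGSetCollection, genes: Sequence[str]) -> pd.Series:
    """For each gene of interest, the number of contrasts calling it a DEG.

    Sorted by descending count, ties by gene id.
    """
    counts = {
        g: sum(1 for deg_set in degs.contrasts.values() if g in deg_set) for g in genes
    }
    series = pd.Series(counts, name="n_contrasts")
    return series.sort_index().sort_values(ascending=False, kind="stable")
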