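"""Group-comparison statistics shared across the analyses.

The pipeline compares its own summary statistics (collinear-gene counts,
rank-normalized conservation scores, hom/het ratios, per-gene dS) between
groups with a Kruskal-Wallis test and, for three or more groups, Dunn's
post hoc z tests with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["kruskal_groups", "dunn_posthoc", "rank_normalize"]


@dataclass(frozen=True)
class KruskalResult:
    H: float
    p: float
    degenerate: bool = False


def kruskal_groups(groups: dict[str, np.ndarray]) -> KruskalResult:
    """Kruskal-Wallis H across named groups.

    All-identical data (zero rank variance) is degenerate for the test;
    it is reported as H=0, p=1 with a warning rather than an error.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, arr in zip(groups, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical; Kruskal-Wallis degenerate",
                      stacklevel=2)
        return KruskalResult(H=0.0, p=1.0, degenerate=True)
    H, p = sps.kruskal(*arrays)
    return KruskalResult(H=float(H), p=float(p))


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise post hoc z tests after Kruskal-Wallis.

    Uses the tie-corrected pooled rank variance; two-sided p values are
    Benjamini-Hochberg adjusted across all pairs.  Returns a table with
    columns group_a, group_b, z, p, p_adj.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    sizes = np.array([len(a) for a in arrays])
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # mean rank per group
    mean_ranks = []
    offset = 0
    for sz in sizes:
        mean_ranks.append(ranks[offset : offset + sz].mean())
        offset += sz
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            var = (n * (n + 1) / 12.0 - tie_term) * (
                1.0 / sizes[i] + 1.0 / sizes[j]
            )
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var) if var > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append((names[i], names[j], z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Map values to [0, 1] by (rank-1)/(n-1), ties getting their mean rank.

    A single observation maps to 0.5 (no ordering information).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return values.copy()
    if n == 1:
        return np.array([0.5])
    ranks = sps.rankdata(values, method="average")
    return (ranks - 1.0) / (n - 1.0)
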