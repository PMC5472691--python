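"""Alpha diversity on rarefied counts and exact Mann-Whitney comparisons.

Richness is the number of taxa observed; Chao1 (bias-corrected) adds
f1(f1-1)/(2(f2+1)) unseen taxa estimated from singletons and doubletons;
evenness is Pielou's J = H / ln S with Shannon H in natural log.  Group
comparisons use the exact Mann-Whitney U test: the two-sided p-value comes
from the full permutation distribution of the rank-sum over all
C(n1+n2, n1) group reassignments, computed by a shift algorithm
generalized to tied (average) ranks, which keeps p-values valid for small
samples and in the presence of ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .taxonomy import GenusTable

__all__ = [
    "chao1",
    "shannon_pielou",
    "diversity_frame",
    "exact_mann_whitney",
    "GroupTestResult",
    "compare_groups",
]


def chao1(counts: Sequence[int]) -> float:
    """Bias-corrected Chao1 richness: S + f1(f1-1) / (2(f2+1))."""
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("Chao1 needs integer (rarefied) counts")
        arr = np.round(arr).astype(int)
    arr = arr[arr > 0]
    s = len(arr)
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return float(s + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def shannon_pielou(counts: Sequence[float]) -> Tuple[float, float]:
    """Shannon entropy (natural log) and Pielou's evenness J = H / ln S.

    J is NaN when a single taxon is present (ln S = 0)."""
    arr = np.asarray(counts, dtype=float)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("all-zero abundance vector")
    p = arr / arr.sum()
    h = float(-(p * np.log(p)).sum())
    s = len(arr)
    j = h / np.log(s) if s >= 2 else np.nan
    return h, j


def diversity_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Chao1, Shannon H and Pielou J (columns=samples)."""
    rows = []
    for s in table.columns:
        v = table[s].to_numpy()
        present = v[v > 0]
        if present.size == 0:
            rows.append({"sample": s, "richness": 0, "chao1": 0.0,
                         "shannon": np.nan, "pielou_j": np.nan})
            continue
        h, j = shannon_pielou(v)
        rows.append(
            {
                "sample": s,
                "richness": int((v > 0).sum()),
                "chao1": chao1(v),
                "shannon": h,
                "pielou_j": j,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class GroupTestResult:
    measure: str
    scope: str
    U: float
    n1: int
    n2: int
    p: float


def _rank_sum_distribution(r2: np.ndarray, n1: int) -> np.ndarray:
    """Number of size-n1 subsets attaining each doubled-rank sum.

    The shift algorithm: one knapsack pass per observation over doubled
    average ranks (integers even under ties).  dist[j, s] counts subsets of
    size j summing to s; counts are exact in float64 for the group sizes
    used here.
    """
    total = int(r2.sum())
    dist = np.zeros((n1 + 1, total + 1))
    dist[0, 0] = 1.0
    for v in r2:
        v = int(v)
        for j in range(n1 - 1, -1, -1):
            row = dist[j]
            if row.any():
                dist[j + 1, v:] += row[: total + 1 - v]
    return dist[n1]


def exact_mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> GroupTestResult:
    """Exact two-sided Mann-Whitney U test with tie-averaged ranks.

    U is computed from average ranks; the p-value doubles the smaller tail
    of the exact permutation distribution of the rank-sum (capped at 1),
    matching brute-force enumeration of all group reassignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    r2 = np.round(ranks * 2).astype(np.int64)  # integers even with ties
    w_obs = int(r2[:n1].sum())
    u = float(r2[:n1].sum() / 2.0 - n1 * (n1 + 1) / 2.0)
    dist = _rank_sum_distribution(r2, n1)
    total = dist.sum()
    lower = dist[: w_obs + 1].sum() / total
    upper = dist[w_obs:].sum() / total
    p = min(1.0, 2.0 * min(lower, upper))
    return GroupTestResult("", "", u, n1, n2, float(p))


_FACTOR_COLUMNS = {"age": "age_class", "rank": "rank_class"}
_FACTOR_LEVELS = {"age": ("adult", "juvenile"), "rank": ("high", "low")}


def compare_groups(
    genus_table: GenusTable,
    metadata: pd.DataFrame,
    factor: str,
    scope: str = "all",
    measures: Sequence[str] = ("richness", "chao1", "pielou_j"),
) -> List[GroupTestResult]:
    """Exact Mann-Whitney comparisons of diversity between host groups.

    ``factor`` is "age" (adult vs juvenile) or "rank" (high vs low; hosts
    without a rank are excluded).  ``scope`` "all" tests the whole table;
    "per-phylum" restricts the table to each phylum's genera in turn.
    Counts are expected rarefied upstream.
    """
    if factor not in _FACTOR_COLUMNS:
        raise ValueError(f"unknown factor {factor!r}")
    col = _FACTOR_COLUMNS[factor]
    lev1, lev2 = _FACTOR_LEVELS[factor]
    meta = metadata.set_index("host_id")
    samples = [s for s in genus_table.counts.columns if s in meta.index]
    g1 = [s for s in samples if meta.loc[s, col] == lev1]
    g2 = [s for s in samples if meta.loc[s, col] == lev2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"factor {factor!r} needs at least 2 samples per level "
            f"(got {len(g1)} vs {len(g2)})"
        )
    scopes: List[Tuple[str, GenusTable]] = []
    if scope == "all":
        scopes.append(("all", genus_table))
    elif scope == "per-phylum":
        for phylum in sorted(genus_table.meta["phylum"].unique()):
            scopes.append((phylum, genus_table.subset_phylum(phylum)))
    else:
        raise ValueError(f"unknown scope {scope!r}")

    results: List[GroupTestResult] = []
    for scope_name, gt in scopes:
        div = diversity_frame(gt.counts)
        for measure in measures:
            v1 = div.loc[g1, measure].to_numpy(dtype=float)
            v2 = div.loc[g2, measure].to_numpy(dtype=float)
            keep1, keep2 = ~np.isnan(v1), ~np.isnan(v2)
            if keep1.sum() == 0 or keep2.sum() == 0:
                continue
            res = exact_mann_whitney(v1[keep1], v2[keep2])
            results.append(
                GroupTestResult(measure, scope_name, res.U, res.n1, res.n2,
                                res.p)
            )
    return results
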