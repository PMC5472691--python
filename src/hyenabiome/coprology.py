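"""McMaster egg counts, prevalence/intensity summaries and the
coprology-sequence correlation screen.

Egg or oocyst counts from four McMaster chambers convert to eggs per gram
via dilution / (chambers x chamber volume) = 25 at the defaults (1:15
dilution, 0.15 ml chambers).  The screen ranks Spearman correlations of a
morphotype's per-gram counts against sequence counts at every taxonomic
level (plus user-declared genus unions) and reports the strongest ones for
taxonomic-agreement checks; log-log linear models on (1+log10)-transformed
data serve as the predictive summary of the relationship.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import GenusTable, LEVELS

__all__ = [
    "fec_from_chambers",
    "combine_size_classes",
    "summarize_parasites",
    "spearman",
    "SpearmanResult",
    "hierarchical_counts",
    "correlation_screen",
    "ScreenResult",
    "fit_loglog",
    "LogLogModel",
]


def fec_from_chambers(
    counts: Sequence[int],
    dilution: float = 15.0,
    chamber_volume_ml: float = 0.15,
) -> float:
    """Eggs (or oocysts) per gram from chamber counts.

    epg = sum(counts) * dilution / (n_chambers * chamber_volume_ml); with
    the default 4 chambers of 0.15 ml at 1:15 dilution each counted egg is
    worth 25 epg.
    """
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("no chamber counts")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("chamber counts must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ValueError("negative chamber count")
    return float(arr.sum() * dilution / (len(arr) * chamber_volume_ml))


def combine_size_classes(table: pd.DataFrame, morphotype: str) -> pd.Series:
    """Per-sample epg totals summed over a morphotype's size classes."""
    sub = table[table["morphotype"] == morphotype]
    if sub.empty:
        raise ValueError(f"unknown morphotype {morphotype!r}")
    return sub.groupby("sample")["epg"].sum()


def _median_ci(values: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics.

    Returns (nan, nan) when the sample is too small for a two-sided
    interval at the requested level.
    """
    x = np.sort(values)
    m = len(x)
    if m < 2:
        return (np.nan, np.nan)
    alpha = 1.0 - level
    lo = int(stats.binom.ppf(alpha / 2, m, 0.5))
    hi = int(stats.binom.isf(alpha / 2, m, 0.5))
    # order-statistic indices: interval (x_(lo+1), x_(hi)) in 1-based terms
    if lo + 1 > m or hi < 1 or lo + 1 > hi:
        return (np.nan, np.nan)
    actual = stats.binom.cdf(hi - 1, m, 0.5) - stats.binom.cdf(lo, m, 0.5)
    if actual < level - 1e-12 and m < 6:
        return (np.nan, np.nan)
    return (float(x[lo]), float(x[hi - 1]))


def summarize_parasites(
    totals: pd.DataFrame, n_samples: int, ci_level: float = 0.95
) -> pd.DataFrame:
    """Prevalence and intensity-of-infection summaries per taxon.

    ``totals`` carries columns taxon, sample, epg (one row per sample and
    taxon).  Prevalence is the percentage of all ``n_samples`` samples
    with epg > 0, printed to one decimal (round half to even).  Intensity
    statistics are computed over positive samples only: mean with a
    t-interval whose lower bound is floored at zero (the raw value is kept
    in ``mean_ci_low_raw``), median with a binomial order-statistic
    interval, both NA when too few positives.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rows = []
    for taxon, grp in totals.groupby("taxon", sort=True):
        epg = grp["epg"].to_numpy(dtype=float)
        pos = epg[epg > 0]
        m = len(pos)
        prevalence = round(100.0 * m / n_samples, 1)
        row = {
            "taxon": taxon,
            "n_positive": m,
            "prevalence": prevalence,
            "mean": np.nan, "mean_ci_low": np.nan, "mean_ci_low_raw": np.nan,
            "mean_ci_high": np.nan,
            "median": np.nan, "median_ci_low": np.nan, "median_ci_high": np.nan,
        }
        if m >= 1:
            row["mean"] = float(np.mean(pos))
            row["median"] = float(np.median(pos))
        if m >= 2:
            se = float(np.std(pos, ddof=1) / np.sqrt(m))
            tq = stats.t.ppf(0.5 + ci_level / 2, m - 1)
            lo, hi = row["mean"] - tq * se, row["mean"] + tq * se
            row["mean_ci_low_raw"] = lo
            row["mean_ci_low"] = max(lo, 0.0)
            row["mean_ci_high"] = hi
            row["median_ci_low"], row["median_ci_high"] = _median_ci(
                pos, ci_level
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int

    @property
    def valid(self) -> bool:
        return not np.isnan(self.rho)


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive average ranks.  Zero variance in either vector yields an
    NA result rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(np.nan, np.nan, len(x))
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), len(x))


def hierarchical_counts(
    genus_table: GenusTable,
    lineages: Mapping[str, Tuple[str, str, str, str, str]],
) -> Dict[str, pd.Series]:
    """Sequence counts per sample for every node of the genus->phylum
    hierarchy.

    Node keys are ``level:name``.  Genera missing from ``lineages`` only
    contribute their genus-level node.
    """
    nodes: Dict[str, pd.Series] = {}
    counts = genus_table.counts
    for genus in counts.index:
        vec = counts.loc[genus]
        lin = lineages.get(genus)
        keys = [f"genus:{genus}"]
        if lin is not None:
            phylum, klass, order, family, _ = lin
            keys += [
                f"family:{family}", f"order:{order}", f"class:{klass}",
                f"phylum:{phylum}",
            ]
        elif genus in genus_table.meta.index:
            keys.append(f"phylum:{genus_table.meta.loc[genus, 'phylum']}")
        for key in keys:
            nodes[key] = nodes[key].add(vec) if key in nodes else vec.copy()
    return nodes


@dataclass
class ScreenResult:
    """Ranked correlations of one morphotype against all taxonomy nodes."""

    morphotype: str
    entries: pd.DataFrame  # node, rho, p, n — sorted by rho descending
    top_k: int

    def top_nodes(self) -> List[str]:
        return list(self.entries["node"].head(self.top_k))


def correlation_screen(
    coprology_totals: pd.DataFrame,
    genus_table: GenusTable,
    lineages: Mapping[str, Tuple[str, str, str, str, str]],
    taxon_sets: Optional[Mapping[str, Sequence[str]]] = None,
    top_k: int = 4,
) -> Dict[str, ScreenResult]:
    """Rank Spearman correlations of each morphotype against all nodes.

    ``coprology_totals`` has columns sample, morphotype, epg (size classes
    already combined).  Sequence counts are taken at every taxonomic level
    plus optional user-declared genus unions (key ``set:<name>``).  NA
    correlations (constant vectors) are excluded from the ranking.
    """
    nodes = hierarchical_counts(genus_table, lineages)
    for name, genera in (taxon_sets or {}).items():
        present = [g for g in genera if g in genus_table.counts.index]
        if present:
            nodes[f"set:{name}"] = genus_table.counts.loc[present].sum(axis=0)

    results: Dict[str, ScreenResult] = {}
    for morph, grp in coprology_totals.groupby("morphotype", sort=True):
        epg = grp.set_index("sample")["epg"]
        shared = sorted(set(epg.index) & set(genus_table.counts.columns))
        if not shared:
            raise ValueError("no shared samples between coprology and counts")
        rows = []
        for node in sorted(nodes):
            res = spearman(epg.loc[shared], nodes[node].loc[shared])
            if res.valid:
                rows.append(
                    {"node": node, "rho": res.rho, "p": res.p, "n": res.n}
                )
        entries = (
            pd.DataFrame(rows, columns=["node", "rho", "p", "n"])
            .sort_values(["rho", "node"], ascending=[False, True], kind="stable")
            .reset_index(drop=True)
        )
        results[morph] = ScreenResult(morph, entries, top_k)
    return results


@dataclass
class LogLogModel:
    """OLS fit of log10(1+epg) on log10(1+count)."""

    intercept: float
    slope: float
    r_squared: float
    n: int

    def predict_epg(self, counts: Sequence[float]) -> np.ndarray:
        x = np.log10(1.0 + np.asarray(counts, dtype=float))
        return 10.0 ** (self.intercept + self.slope * x) - 1.0


def fit_loglog(
    epg: Sequence[float], counts: Sequence[float]
) -> LogLogModel:
    """Fit the predictive log-log linear model of egg counts on reads."""
    epg = np.asarray(epg, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(epg) != len(counts) or len(epg) < 3:
        raise ValueError("need paired vectors of length >= 3")
    y = np.log10(1.0 + epg)
    x = np.log10(1.0 + counts)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in transformed predictor")
    if np.ptp(y) == 0:
        return LogLogModel(float(y[0]), 0.0, 0.0, len(x))
    res = stats.linregress(x, y)
    return LogLogModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue ** 2),
        n=len(x),
    )
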