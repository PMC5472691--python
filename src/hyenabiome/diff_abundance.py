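"""Per-genus negative-binomial differential abundance between host groups.

Sequencing-depth differences enter as median-of-ratios size factors used
as GLM offsets.  Each genus is fitted with a log-link negative-binomial
GLM whose dispersion is estimated per genus by maximum (profile)
likelihood with a method-of-moments initializer; the group effect is
tested by a likelihood-ratio test against chi-squared with one degree of
freedom and p-values are Benjamini-Hochberg adjusted.  There is no
information sharing across genera (no empirical-Bayes dispersion
shrinkage), a documented simplification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "nb_glm_lrt",
    "DiffResult",
    "bh_adjust",
    "differential_abundance",
]

logger = logging.getLogger(__name__)

_MIN_ALPHA = 1e-8
_MAX_ALPHA = 1e3


def size_factors(counts: pd.DataFrame, min_presence: float = 0.9) -> pd.Series:
    """Median-of-ratios size factors per sample (column).

    For taxa positive in every sample, each sample's factor is the median
    ratio of its counts to the taxon-wise geometric means, rescaled so the
    factors have geometric mean 1.  When no taxon is positive everywhere,
    the fallback uses taxa positive in at least ``min_presence`` of the
    samples, with geometric means over their positive entries only.
    """
    if counts.size == 0:
        raise ValueError("empty count matrix")
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if all_positive.any():
        sub = x[all_positive]
        gm = np.exp(np.log(sub).mean(axis=1))
        ratios = sub / gm[:, None]
        sf = np.median(ratios, axis=0)
    else:
        presence = (x > 0).mean(axis=1)
        ok = presence >= min_presence
        if not ok.any():
            raise ValueError(
                "no taxon present in enough samples for size factors"
            )
        logger.info(
            "no all-positive taxon; size-factor fallback over %d taxa "
            "present in >= %.0f%% of samples", int(ok.sum()),
            100 * min_presence,
        )
        sub = x[ok]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        gm = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(sub > 0, sub / gm[:, None], np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sf = np.nanmedian(ratios, axis=0)
        if np.isnan(sf).any():
            # a sample with no count in any qualifying taxon: scale by its
            # total depth relative to the others
            totals = x.sum(axis=0)
            depth_ratio = totals / np.exp(np.mean(np.log(totals[~np.isnan(sf)])))
            scale = np.nanmedian(sf / depth_ratio)
            sf = np.where(np.isnan(sf), scale * depth_ratio, sf)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns)


@dataclass
class DiffResult:
    genus: str
    phylum: str
    base_mean: float
    log2_fold_change: float
    lrt: float
    p: float
    fdr: float = np.nan

    @property
    def valid(self) -> bool:
        return not np.isnan(self.p)


def _nb_llf(y, X, offset, alpha) -> tuple[float, Optional[np.ndarray]]:
    fam = sm.families.NegativeBinomial(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
        except Exception:
            return -np.inf, None
    return float(res.llf), np.asarray(res.params)


def _moment_alpha(y: np.ndarray, mu: float) -> float:
    v = y.var(ddof=1)
    if mu <= 0:
        return _MIN_ALPHA
    return float(np.clip((v - mu) / mu ** 2, _MIN_ALPHA, _MAX_ALPHA))


def nb_glm_lrt(
    counts: Sequence[int],
    group: Sequence,
    sf: Sequence[float],
    genus: str = "",
    phylum: str = "",
    min_nonzero: int = 3,
) -> DiffResult:
    """Likelihood-ratio test of a group effect on one taxon's counts.

    Full model: log mu = b0 + b1 * I(group == first level) + log sf; the
    reduced model drops b1.  The per-taxon dispersion maximizes the full
    model's profile likelihood (moment estimate as initializer and
    fallback) and is held fixed in both fits.  The statistic is
    2(l_full - l_reduced) against chi-squared(1); log2FC = b1 / ln 2.
    Taxa with fewer than ``min_nonzero`` positive samples give an NA
    result.
    """
    y = np.asarray(counts, dtype=float)
    g = np.asarray(group)
    sf = np.asarray(sf, dtype=float)
    levels = sorted(pd.unique(g))
    if len(levels) != 2 or min((g == lv).sum() for lv in levels) == 0:
        raise ValueError("group must have two non-empty levels")
    if not np.allclose(y, np.round(y)):
        raise ValueError("counts must be integers")
    base_mean = float((y / sf).mean())
    if (y > 0).sum() < min_nonzero:
        return DiffResult(genus, phylum, base_mean, np.nan, np.nan, np.nan)

    offset = np.log(sf)
    x_full = np.column_stack([np.ones_like(y), (g == levels[0]).astype(float)])
    x_red = x_full[:, :1]

    alpha0 = _moment_alpha(y, float((y / sf).mean()))

    def neg_profile(log_alpha: float) -> float:
        llf, _ = _nb_llf(y, x_full, offset, float(np.exp(log_alpha)))
        return -llf

    try:
        opt = minimize_scalar(
            neg_profile,
            bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)),
            method="bounded",
            options={"xatol": 1e-3},
        )
        alpha = float(np.exp(opt.x)) if np.isfinite(opt.fun) else alpha0
    except Exception:
        alpha = alpha0

    llf_full, params = _nb_llf(y, x_full, offset, alpha)
    llf_red, _ = _nb_llf(y, x_red, offset, alpha)
    if not np.isfinite(llf_full) or not np.isfinite(llf_red) or params is None:
        return DiffResult(genus, phylum, base_mean, np.nan, np.nan, np.nan)
    lrt = max(2.0 * (llf_full - llf_red), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    log2fc = float(params[1] / np.log(2.0))
    return DiffResult(genus, phylum, base_mean, log2fc, lrt, p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


_FACTOR_COLUMNS = {"age": "age_class", "rank": "rank_class"}


def differential_abundance(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    factor: str,
    phylum_of: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-genus NB-GLM screen between age or rank categories.

    ``counts`` is genus x sample integer counts; samples without the
    factor level (e.g. unranked juveniles for "rank") are dropped.  Taxa
    reported NA are excluded from the Benjamini-Hochberg family.
    """
    col = _FACTOR_COLUMNS[factor]
    md = meta.set_index("host_id")
    samples = [
        s for s in counts.columns
        if s in md.index and str(md.loc[s, col]) not in ("", "nan", "None")
    ]
    sub = counts[samples]
    group = md.loc[samples, col].to_numpy()
    sf = size_factors(sub)
    rows = []
    for genus in sub.index:
        phylum = str(phylum_of.get(genus, "")) if phylum_of is not None else ""
        res = nb_glm_lrt(
            sub.loc[genus].to_numpy(), group, sf.to_numpy(), genus, phylum
        )
        rows.append(res)
    df = pd.DataFrame(
        [
            {
                "genus": r.genus, "phylum": r.phylum, "base_mean": r.base_mean,
                "log2_fold_change": r.log2_fold_change, "lrt": r.lrt, "p": r.p,
            }
            for r in rows
        ]
    )
    tested = df["p"].notna()
    df["fdr"] = np.nan
    if tested.any():
        df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "p"].to_numpy())
    return df
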