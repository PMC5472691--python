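"""Bray-Curtis ordination, PLS-DA with LOO axis selection, and quartile
loading enrichment.

Composition analyses run on (1+log10)-transformed genus abundances: the
transform is the caller's job, the functions here treat their input as
already transformed.  Non-metric MDS minimizes Kruskal stress-1 with
pool-adjacent-violators monotone regression of configuration distances on
the dissimilarities, best of several random restarts.  PLS-DA is PLS1
(NIPALS) against a +/-1-coded class; the retained axis count is the
smallest one attaining the maximal leave-one-out accuracy.  Enrichment of
a phylum among extreme loadings uses Fisher's exact test on the 2x2 table
of phylum membership against extreme-quartile membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "log10_1p",
    "bray_curtis",
    "nmds",
    "OrdinationResult",
    "pls_da",
    "PLSResult",
    "fisher_exact",
    "loading_enrichment",
    "EnrichmentResult",
]


def log10_1p(x):
    """The (1+log10) transform used throughout composition analyses."""
    return np.log10(1.0 + np.asarray(x, dtype=float))


def bray_curtis(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarities between rows.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1] for non-negative
    input; a pair of all-zero rows is undefined (NaN).
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis needs non-negative input")
    d = squareform(pdist(x, metric="braycurtis"))
    zero_rows = np.nonzero(x.sum(axis=1) == 0)[0]
    for i in zero_rows:
        for j in zero_rows:
            if i != j:
                d[i, j] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class OrdinationResult:
    coords: np.ndarray  # n x k
    stress: float
    n_restarts: int
    seed: int
    stress_sequences: List[List[float]]


def _stress1(dhat: np.ndarray, dconf: np.ndarray) -> float:
    denom = (dconf ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dconf - dhat) ** 2).sum() / denom))


def nmds(
    dissimilarity: np.ndarray,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
    metric: bool = False,
) -> OrdinationResult:
    """Non-metric multidimensional scaling by iterative majorization.

    Each restart starts from a random configuration; one iteration fits
    monotone (PAV) disparities to the configuration distances and applies a
    Guttman transform.  Stress-1 is non-increasing within a restart and the
    best restart is returned.  ``metric=True`` skips the monotone
    regression (classical least-squares scaling on the raw
    dissimilarities).
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("dissimilarity must be square symmetric")
    if np.isnan(d).any():
        raise ValueError("NA dissimilarities are not embeddable")
    if k >= n:
        raise ValueError("k must be below the number of points")
    iu = np.triu_indices(n, 1)
    dvec = d[iu]
    order = np.argsort(dvec, kind="stable")
    rng = np.random.default_rng(seed)

    best: Optional[Tuple[float, np.ndarray]] = None
    sequences: List[List[float]] = []
    for _ in range(n_restarts):
        x = rng.normal(size=(n, k))
        seq: List[float] = []
        prev = np.inf
        for _it in range(max_iter):
            dc = squareform(pdist(x))
            dcvec = dc[iu]
            if metric:
                dhat_vec = dvec
            else:
                iso = IsotonicRegression(increasing=True)
                dhat_vec = iso.fit_transform(dvec[order], dcvec[order])
                inv = np.empty_like(dhat_vec)
                inv[order] = dhat_vec
                dhat_vec = inv
            s = _stress1(dhat_vec, dcvec)
            if seq and s > seq[-1] + 1e-12:
                break  # numerical stall; keep the last improving config
            seq.append(s)
            if prev - s < tol:
                break
            prev = s
            # Guttman transform toward the disparities
            dhat = squareform(dhat_vec)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dc > 0, dhat / dc, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = b @ x / n
        sequences.append(seq)
        final = seq[-1] if seq else np.inf
        if best is None or final < best[0]:
            best = (final, x.copy())
    assert best is not None
    return OrdinationResult(best[1], best[0], n_restarts, seed, sequences)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PLSResult:
    n_axes: int
    scores: np.ndarray  # n x A
    loadings: np.ndarray  # p x A (X weights per axis)
    cv_accuracy: Dict[int, float]
    predicted: np.ndarray
    classes: Tuple[str, str]


def _pls1_fit(x: np.ndarray, y: np.ndarray, n_axes: int):
    """NIPALS PLS1: returns (weights W, x-loadings P, y-loadings q, x_mean,
    y_mean, scores T)."""
    xm = x.mean(axis=0)
    ym = y.mean()
    e = x - xm
    f = y - ym
    n, p = e.shape
    w_mat = np.zeros((p, n_axes))
    p_mat = np.zeros((p, n_axes))
    q = np.zeros(n_axes)
    t_mat = np.zeros((n, n_axes))
    for a in range(n_axes):
        w = e.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            # response fully deflated; stop early
            return w_mat[:, :a], p_mat[:, :a], q[:a], xm, ym, t_mat[:, :a]
        w /= nw
        t = e @ w
        tt = t @ t
        pl = e.T @ t / tt
        qa = f @ t / tt
        e = e - np.outer(t, pl)
        f = f - qa * t
        w_mat[:, a], p_mat[:, a], q[a], t_mat[:, a] = w, pl, qa, t
    return w_mat, p_mat, q, xm, ym, t_mat


def _pls1_coef(w_mat, p_mat, q):
    if w_mat.shape[1] == 0:
        return np.zeros(w_mat.shape[0])
    r = w_mat @ np.linalg.pinv(p_mat.T @ w_mat)
    return r @ q


def pls_da(
    x: np.ndarray | pd.DataFrame,
    y: Sequence,
    max_axes: int = 5,
) -> PLSResult:
    """PLS-DA on a binary class with leave-one-out axis selection.

    The response is coded +1 for the lexicographically first class and -1
    for the other; a held-out sample is classified by the sign of its
    predicted response.  The smallest axis count attaining the maximal
    LOO accuracy is retained and the full-data fit at that count supplies
    scores and loadings.
    """
    xmat = np.asarray(x, dtype=float)
    labels = np.asarray(y)
    classes = tuple(sorted(pd.unique(labels)))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if len(labels) < 4:
        raise ValueError("need at least 4 samples")
    if np.allclose(xmat.std(axis=0), 0):
        raise ValueError("constant predictor matrix")
    ycode = np.where(labels == classes[0], 1.0, -1.0)
    n = len(ycode)
    max_axes = min(max_axes, n - 2, xmat.shape[1])

    cv: Dict[int, float] = {}
    correct = np.zeros(max_axes)
    for i in range(n):
        mask = np.arange(n) != i
        w_m, p_m, q, xm, ym, _ = _pls1_fit(xmat[mask], ycode[mask], max_axes)
        for a in range(1, max_axes + 1):
            aa = min(a, w_m.shape[1])
            coef = _pls1_coef(w_m[:, :aa], p_m[:, :aa], q[:aa])
            pred = (xmat[i] - xm) @ coef + ym
            if np.sign(pred) == np.sign(ycode[i]) and pred != 0:
                correct[a - 1] += 1
    for a in range(1, max_axes + 1):
        cv[a] = correct[a - 1] / n
    best_a = max(range(1, max_axes + 1), key=lambda a: (cv[a], -a))

    w_m, p_m, q, xm, ym, t_m = _pls1_fit(xmat, ycode, best_a)
    coef = _pls1_coef(w_m, p_m, q)
    pred = (xmat - xm) @ coef + ym
    predicted = np.where(pred >= 0, classes[0], classes[1])
    return PLSResult(
        n_axes=w_m.shape[1],
        scores=t_m,
        loadings=w_m,
        cv_accuracy=cv,
        predicted=predicted,
        classes=classes,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# Fisher's exact test and loading enrichment
# ---------------------------------------------------------------------------

def fisher_exact(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns the sample odds ratio ad/bc (infinite on a zero denominator
    cell) and the two-sided p (sum of hypergeometric probabilities of
    tables, at fixed margins, no more probable than the observed one).
    """
    cells = np.array([[a, b], [c, d]])
    if (cells < 0).any():
        raise ValueError("negative cell count")
    if cells.sum() == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact(cells, alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else (np.nan if a * d == 0 else np.inf)
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


@dataclass
class EnrichmentResult:
    phylum: str
    table: Tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    p: float


def loading_enrichment(
    loadings: np.ndarray | pd.DataFrame,
    phylum_labels: Sequence[str],
    n_axes_combine: int = 1,
    mode: str = "single",
    extreme: str = "union",
    phyla: Optional[Sequence[str]] = None,
) -> List[EnrichmentResult]:
    """Test phyla for over-representation among extreme PLS loadings.

    The working loading is axis 1, or the elementwise product of axes 1
    and 2 when ``n_axes_combine=2`` (the combined-quartile variant).  The
    extreme set is the top quartile (``extreme="top"``), bottom quartile
    ("bottom"), or their union ("union"); ties at the quartile boundary
    enter the extreme set.  Each tested phylum gives a 2x2 table of
    phylum membership against extreme membership, tested with Fisher's
    exact test.  ``mode`` is "single" (quartiles of axis 1) or "combined"
    (quartiles of the axis-1 x axis-2 product); it overrides
    ``n_axes_combine`` when given explicitly.
    """
    lmat = np.asarray(loadings, dtype=float)
    if lmat.ndim == 1:
        lmat = lmat[:, None]
    labels = np.asarray(phylum_labels)
    if len(labels) != lmat.shape[0]:
        raise ValueError("loadings and phylum labels differ in length")
    if len(labels) < 8:
        raise ValueError("need at least 8 genera for quartile enrichment")
    if mode not in ("single", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "combined":
        n_axes_combine = 2
    if n_axes_combine == 1:
        work = lmat[:, 0]
    elif n_axes_combine == 2:
        if lmat.shape[1] < 2:
            raise ValueError("combined mode needs at least 2 axes")
        work = lmat[:, 0] * lmat[:, 1]
    else:
        raise ValueError("n_axes_combine must be 1 or 2")

    q25, q75 = np.percentile(work, [25, 75])
    top = work >= q75
    bottom = work <= q25
    if extreme == "top":
        ext = top
    elif extreme == "bottom":
        ext = bottom
    elif extreme == "union":
        ext = top | bottom
    else:
        raise ValueError(f"unknown extreme set {extreme!r}")

    tested = sorted(set(labels)) if phyla is None else list(phyla)
    results = []
    for ph in tested:
        inp = labels == ph
        a = int((inp & ext).sum())
        b = int((inp & ~ext).sum())
        c = int((~inp & ext).sum())
        d = int((~inp & ~ext).sum())
        odds, p = fisher_exact(a, b, c, d)
        results.append(EnrichmentResult(ph, (a, b, c, d), odds, p))
    return results
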