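"""Replicate QC against water controls, collapsing, scaling and rarefaction.

Failed PCR replicates are found by complete-linkage hierarchical
clustering of log-scaled primer-stratified read counts cut into two
clusters; the cluster holding the majority of the water negative controls
is the failure cluster.  Sample counts are the sum of surviving technical
replicates.  Depth normalization scales every sample total to the median
total; rarefaction subsamples without replacement to a common depth
(diversity estimates use rarefied counts, ordination and correlation use
normalized counts).
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .denoise import RSVTable

__all__ = [
    "flag_failed_replicates",
    "collapse_replicates",
    "median_scale",
    "rarefy",
]

logger = logging.getLogger(__name__)


def flag_failed_replicates(
    counts: pd.DataFrame, is_water: Mapping[str, bool]
) -> Set[str]:
    """Flag non-water replicates that cluster with the water controls.

    ``counts`` is the replicate x amplicon assigned-read matrix.  Rows are
    embedded as log10(1+count) vectors, clustered with complete linkage on
    Euclidean distances and cut into two clusters; every non-water
    replicate in the cluster holding the majority of water controls is
    flagged as a failed PCR.
    """
    waters = [r for r in counts.index if is_water.get(r, False)]
    if not waters:
        raise ValueError(
            "no water controls in the replicate matrix; replicate QC needs "
            "negative controls (or use an explicit read-count threshold)"
        )
    rows = sorted(counts.index)
    x = np.log10(1.0 + counts.loc[rows].to_numpy(dtype=float))
    if len(rows) < 3:
        return set()
    z = linkage(x, method="complete", metric="euclidean")
    labels = fcluster(z, t=2, criterion="maxclust")
    lab = pd.Series(labels, index=rows)
    water_cluster = lab.loc[waters].mode().iloc[0]
    return {
        r for r in rows
        if lab[r] == water_cluster and not is_water.get(r, False)
    }


def collapse_replicates(
    rsv_table: RSVTable,
    replicate_to_sample: Mapping[str, str],
    failed: Set[str],
    water: Optional[Set[str]] = None,
) -> RSVTable:
    """Sum counts over surviving technical replicates per sample.

    Water controls and flagged replicates are excluded; a sample whose
    replicates all failed is dropped with a warning.
    """
    water = water or set()
    table = rsv_table.table
    groups: Dict[str, list] = {}
    for rep in table.columns:
        if rep in failed or rep in water:
            continue
        sample = replicate_to_sample.get(rep)
        if sample is None:
            raise ValueError(f"replicate {rep!r} maps to no sample")
        groups.setdefault(sample, []).append(rep)
    expected = {
        replicate_to_sample[r] for r in table.columns
        if r not in water and r in replicate_to_sample
    }
    dropped = expected - set(groups)
    for s in sorted(dropped):
        logger.warning("sample %s lost all technical replicates; dropped", s)
    collapsed = pd.DataFrame(
        {s: table[reps].sum(axis=1) for s, reps in sorted(groups.items())}
    )
    return RSVTable(collapsed)


def median_scale(table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Scale each sample (column) so its total equals the median total.

    Returns the real-valued normalized table and the per-sample factors
    (median total divided by sample total).
    """
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total sample(s): {bad}")
    factors = totals.median() / totals
    return table * factors, factors


def rarefy(
    table: pd.DataFrame, depth: Optional[int] = None, seed: int = 0
) -> pd.DataFrame:
    """Subsample each sample (column) without replacement to ``depth`` reads.

    Draws follow the multivariate hypergeometric distribution given the
    sample's counts; the default depth is the smallest sample total.
    """
    counts = table.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction needs integer counts")
    counts = np.round(counts).astype(np.int64)
    totals = counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if (totals < depth).any():
        bad = list(table.columns[totals < depth])
        raise ValueError(f"depth {depth} exceeds total of sample(s) {bad}")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return pd.DataFrame(out, index=table.index, columns=table.columns)
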