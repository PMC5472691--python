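"""Sequence-variant inference, mate concatenation and de novo bimera removal.

Variant inference here is a deliberately simple, fully specified
abundance-skew rule rather than a learned error model: after exact
dereplication, a rare sequence is absorbed into a more abundant retained
center when it lies within ``d_max`` mismatches and its count is at most
``skew`` per mismatch times the center's count.  The rule is exposed behind
a pluggable interface (any callable mapping dereplicated counts to variant
counts can stand in).  Mates are kept in lockstep and concatenated with a
10-N spacer before dereplication, so every inferred variant is a full
concatenated sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .study_data import ReadPair, revcomp

__all__ = [
    "SPACER",
    "concat_pairs",
    "dereplicate",
    "infer_rsvs",
    "build_rsv_table",
    "remove_bimeras",
    "RSVTable",
]

SPACER = "N" * 10


def concat_pairs(fwd: str, rev: str) -> str:
    """Concatenate denoised mates: forward + 10-N spacer + revcomp(reverse)."""
    if not fwd or not rev:
        raise ValueError("empty mate in concatenation")
    return fwd + SPACER + revcomp(rev)


def dereplicate(seqs: Iterable[str]) -> Dict[str, int]:
    """Exact dereplication: unique sequence -> count."""
    return dict(Counter(seqs))


def _hamming(a: str, b: str, limit: int) -> int:
    """Hamming distance, short-circuited once it exceeds ``limit``."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def infer_rsvs(
    counts: Mapping[str, int],
    d_max: int = 1,
    skew: float = 0.1,
    min_count: int = 1,
) -> Dict[str, int]:
    """Collapse likely-erroneous sequences into abundant centers.

    Unique sequences are visited by descending count (ties broken
    lexicographically).  A sequence ``u`` is absorbed into the most
    abundant already-retained center ``c`` with Hamming(u, c) <= ``d_max``
    when count(u) <= skew^d * count(c); absorbed counts add to the center.
    Sequences of unequal length within one partition are an error.
    """
    if not counts:
        return {}
    lengths = {len(s) for s in counts}
    if len(lengths) != 1:
        raise ValueError(f"unequal read lengths within an amplicon: {sorted(lengths)}")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    retained: List[str] = []
    out: Dict[str, int] = {}
    for seq, cnt in ordered:
        absorbed = False
        # centers are visited in retention order = descending abundance at
        # retention time; the first eligible center is the most abundant
        for c in sorted(retained, key=lambda s: (-out[s], s)):
            d = _hamming(seq, c, d_max)
            if d <= d_max and cnt <= (skew ** d) * out[c]:
                out[c] += cnt
                absorbed = True
                break
        if not absorbed:
            retained.append(seq)
            out[seq] = cnt
    return {s: c for s, c in out.items() if c >= min_count}


Denoiser = Callable[[Mapping[str, int]], Dict[str, int]]


@dataclass
class RSVTable:
    """Variant x replicate count table with the amplicon of origin.

    ``table`` is indexed by (amplicon_id, sequence) with one integer count
    column per replicate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table.values < 0).any():
            raise ValueError("negative counts in RSV table")

    @property
    def sequences(self) -> List[Tuple[str, str]]:
        return list(self.table.index)

    def to_frame(self) -> pd.DataFrame:
        df = self.table.reset_index()
        df.insert(0, "rsv_id", [f"rsv{i + 1:05d}" for i in range(len(df))])
        return df


def build_rsv_table(
    pairs: Mapping[Tuple[str, str], Sequence[ReadPair]],
    denoiser: Denoiser = infer_rsvs,
) -> RSVTable:
    """Denoise each (replicate, amplicon) partition and collate the table.

    Pairs are concatenated mate-wise, dereplicated exactly, then passed to
    the pluggable denoiser; the result is the variant x replicate matrix.
    """
    cells: Dict[Tuple[str, str], Dict[str, int]] = {}
    replicates: Set[str] = set()
    for (rep, amp), plist in pairs.items():
        replicates.add(rep)
        concat = [concat_pairs(p.seq1, p.seq2) for p in plist]
        if not concat:
            continue
        rsvs = denoiser(dereplicate(concat))
        for seq, cnt in rsvs.items():
            cells.setdefault((amp, seq), {})[rep] = (
                cells.setdefault((amp, seq), {}).get(rep, 0) + cnt
            )
    index = pd.MultiIndex.from_tuples(
        sorted(cells), names=["amplicon_id", "sequence"]
    )
    cols = sorted(replicates)
    table = pd.DataFrame(0, index=index, columns=cols, dtype=int)
    for key, repcounts in cells.items():
        for rep, cnt in repcounts.items():
            table.loc[key, rep] = cnt
    return RSVTable(table)


def _is_bimera_of(seq: str, parents: List[str]) -> bool:
    """True when seq = prefix(A) + suffix(B) exactly, A != B, split >= 1."""
    if len(parents) < 2:
        return False
    L = len(seq)
    # longest exact shared prefix / suffix with each parent
    pref = []
    suff = []
    for p in parents:
        if len(p) != L:
            pref.append(0)
            suff.append(0)
            continue
        i = 0
        while i < L and seq[i] == p[i]:
            i += 1
        j = 0
        while j < L and seq[L - 1 - j] == p[L - 1 - j]:
            j += 1
        pref.append(i)
        suff.append(j)
    for ia, a in enumerate(parents):
        if pref[ia] < 1:
            continue
        for ib, b in enumerate(parents):
            if ia == ib:
                continue
            # need split k with 1 <= k <= pref[a] and L - k <= suff[b],
            # i.e. k >= L - suff[b]
            if pref[ia] >= max(1, L - suff[ib]) and suff[ib] >= 1:
                return True
    return False


def remove_bimeras(
    rsv_table: RSVTable, parent_ratio: float = 2.0
) -> Tuple[RSVTable, Set[Tuple[str, str]]]:
    """Flag and drop two-parent chimeras (bimeras) per amplicon.

    Within a sample, a variant is a bimera candidate when two distinct
    parents, each at least ``parent_ratio`` times as abundant in that
    sample, can be split at some point k so the candidate equals the first
    parent up to k and the second from k+1 on, exactly.  A variant is
    removed table-wide when flagged in a majority of the samples where it
    occurs; the most abundant variant of the table is never flagged.
    """
    table = rsv_table.table
    if table.empty:
        return rsv_table, set()
    totals = table.sum(axis=1)
    top_variant = totals.sort_values(ascending=False, kind="stable").index[0]
    flagged: Set[Tuple[str, str]] = set()
    for amp in table.index.get_level_values(0).unique():
        sub = table.loc[amp]
        seqs = list(sub.index)
        if len(seqs) < 3:
            continue
        for seq in seqs:
            if (amp, seq) == top_variant:
                continue
            occ = 0
            hits = 0
            row = sub.loc[seq]
            for rep in sub.columns:
                c = row[rep]
                if c == 0:
                    continue
                occ += 1
                parents = [
                    s for s in seqs
                    if s != seq and sub.loc[s, rep] >= parent_ratio * c
                ]
                if _is_bimera_of(seq, parents):
                    hits += 1
            if occ > 0 and hits > occ / 2:
                flagged.add((amp, seq))
    kept = table.drop(index=list(flagged))
    return RSVTable(kept), flagged
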