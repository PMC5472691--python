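"""Quality filtering of read pairs and zero-mismatch primer stratification.

Filtering follows the standard amplicon-workflow contract: each mate is
truncated at the first base at or below ``trunc_q``, cut to ``trunc_len``,
and rejected when it is then too short, still contains an N, or its
expected number of errors exceeds ``max_ee``.  Stratification sorts a pair
into an amplicon only when the forward primer matches read 1 and the
reverse primer matches read 2, both starting at base one with zero
mismatches (IUPAC degeneracy in the primer counts as a match); matching
primers are trimmed off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .study_data import IUPAC_EXPANSION, PrimerPanel, ReadPair

__all__ = [
    "expected_errors",
    "quality_filter",
    "FilterResult",
    "stratify_by_primer",
    "AmpliconMatrix",
    "UNASSIGNED",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"


def expected_errors(quals: Sequence[int]) -> float:
    """Expected number of errors of a read: sum of 10^(-Q/10) per base."""
    if len(quals) == 0:
        return 0.0
    q = np.asarray(quals, dtype=float)
    if (q < 0).any():
        raise ValueError("negative Phred score")
    return float(np.sum(10.0 ** (-q / 10.0)))


@dataclass
class FilterResult:
    kept: bool
    pair: Optional[ReadPair] = None
    reason: Optional[str] = None


def _filter_mate(
    seq: str, qual: Sequence[int], trunc_len: int, max_n: int, max_ee: float,
    trunc_q: int,
) -> Tuple[Optional[Tuple[str, List[int]]], Optional[str]]:
    # truncate at the first position with quality <= trunc_q
    cut = len(seq)
    for i, q in enumerate(qual):
        if q <= trunc_q:
            cut = i
            break
    seq, qual = seq[:cut], list(qual[:cut])
    if len(seq) < trunc_len:
        return None, "too_short"
    seq, qual = seq[:trunc_len], qual[:trunc_len]
    if seq.count("N") > max_n:
        return None, "maxN"
    if expected_errors(qual) > max_ee:
        return None, "maxEE"
    return (seq, qual), None


def quality_filter(
    pair: ReadPair,
    trunc_len: Tuple[int, int] = (170, 170),
    max_n: int = 0,
    max_ee: Tuple[float, float] = (2.0, 2.0),
    trunc_q: int = 2,
) -> FilterResult:
    """Filter one read pair; both mates must pass for the pair to be kept.

    Rejection is a tagged result (``kept=False`` with a reason), never an
    exception.
    """
    kept1, why1 = _filter_mate(
        pair.seq1, pair.qual1, trunc_len[0], max_n, max_ee[0], trunc_q
    )
    if kept1 is None:
        return FilterResult(False, reason=why1)
    kept2, why2 = _filter_mate(
        pair.seq2, pair.qual2, trunc_len[1], max_n, max_ee[1], trunc_q
    )
    if kept2 is None:
        return FilterResult(False, reason=why2)
    return FilterResult(
        True,
        ReadPair(pair.id, kept1[0], kept2[0], kept1[1], kept2[1]),
    )


def _primer_matches(primer: str, read: str) -> bool:
    """Zero-mismatch IUPAC match of the primer at base one of the read.

    Degenerate primer codes match their expansion set; N in the read never
    matches."""
    if len(read) < len(primer):
        return False
    for p, b in zip(primer, read):
        if b == "N" or b not in IUPAC_EXPANSION[p]:
            return False
    return True


def _check_panel_distinct(panel: PrimerPanel) -> None:
    """Two panel entries with Hamming-identical primer pairs under IUPAC
    expansion can never be told apart; reject such panels outright."""
    entries = list(panel)
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            a, b = entries[i], entries[j]
            if len(a.fwd_primer) != len(b.fwd_primer):
                continue
            if len(a.rev_primer) != len(b.rev_primer):
                continue
            if _iupac_overlap(a.fwd_primer, b.fwd_primer) and _iupac_overlap(
                a.rev_primer, b.rev_primer
            ):
                raise ValueError(
                    f"panel entries {a.amplicon_id!r} and {b.amplicon_id!r} "
                    "have indistinguishable primer pairs under IUPAC expansion"
                )


def _iupac_overlap(p1: str, p2: str) -> bool:
    return all(
        IUPAC_EXPANSION[a] & IUPAC_EXPANSION[b] for a, b in zip(p1, p2)
    )


@dataclass
class AmpliconMatrix:
    """Primer-stratified reads: per (replicate, amplicon) trimmed pairs.

    ``counts()`` returns the replicate x amplicon assigned-read matrix used
    for replicate QC.
    """

    pairs: Dict[Tuple[str, str], List[ReadPair]]
    unassigned: Dict[str, int]
    amplicon_ids: List[str]

    def counts(self) -> pd.DataFrame:
        reps = sorted({rep for rep, _ in self.pairs} | set(self.unassigned))
        mat = pd.DataFrame(0, index=reps, columns=self.amplicon_ids)
        for (rep, amp), lst in self.pairs.items():
            mat.loc[rep, amp] = len(lst)
        return mat

    def assignments_frame(self) -> pd.DataFrame:
        rows = [
            {"replicate": rep, "amplicon_id": amp, "read_id": p.id}
            for (rep, amp), lst in sorted(self.pairs.items())
            for p in lst
        ]
        return pd.DataFrame(rows, columns=["replicate", "amplicon_id", "read_id"])


def stratify_by_primer(
    pairs_by_replicate: Dict[str, Iterable[ReadPair]],
    panel: PrimerPanel,
) -> AmpliconMatrix:
    """Sort read pairs into amplicons by exact primer-pair match at base one.

    A pair matching several panel entries (possible with degenerate
    primers) goes to the entry with the longest combined primer; an exact
    tie is conservative and counts as unassigned.  Primers are trimmed
    from sequence and qualities on assignment.
    """
    _check_panel_distinct(panel)
    entries = sorted(
        panel,
        key=lambda e: -(len(e.fwd_primer) + len(e.rev_primer)),
    )
    out: Dict[Tuple[str, str], List[ReadPair]] = {}
    unassigned: Dict[str, int] = {}
    for rep, pairs in pairs_by_replicate.items():
        unassigned[rep] = 0
        for pair in pairs:
            matches = [
                e for e in entries
                if _primer_matches(e.fwd_primer, pair.seq1)
                and _primer_matches(e.rev_primer, pair.seq2)
            ]
            if not matches:
                unassigned[rep] += 1
                continue
            best_len = len(matches[0].fwd_primer) + len(matches[0].rev_primer)
            top = [
                e for e in matches
                if len(e.fwd_primer) + len(e.rev_primer) == best_len
            ]
            if len(top) > 1:
                logger.warning(
                    "read %s matches %d panel entries of equal primer length; "
                    "left unassigned", pair.id, len(top),
                )
                unassigned[rep] += 1
                continue
            e = top[0]
            nf, nr = len(e.fwd_primer), len(e.rev_primer)
            trimmed = ReadPair(
                pair.id,
                pair.seq1[nf:], pair.seq2[nr:],
                list(pair.qual1[nf:]), list(pair.qual2[nr:]),
            )
            out.setdefault((rep, e.amplicon_id), []).append(trimmed)
    return AmpliconMatrix(out, unassigned, [e.amplicon_id for e in panel])
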