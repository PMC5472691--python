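"""Naive-Bayes k-mer taxonomy, genus agglomeration and phylum accounting.

The classifier is the classical ribosomal-database naive Bayes: a genus g
is scored by the sum over the query's k-mer words w of log P(w|g), with

    P(w|g) = (m(w,g) + Pr(w)) / (M(g) + 1),   Pr(w) = (n(w) + 0.5) / (N + 1)

where n(w) counts training references containing w (once per reference),
N is the number of references, m(w,g) the references of genus g containing
w and M(g) the number of references of g.  Confidence comes from
bootstrapping one eighth of the query words; lineage levels whose
bootstrap support falls below ``min_boot`` are reported UNDEFINED.

Genus agglomeration mirrors the standard multi-amplicon merge: counts are
summed over variants sharing a genus annotation across amplicons, then
genera with missing or uninformative names, genera that are the sole genus
of their phylum, and genera with an undefined phylum are excluded, in that
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .denoise import RSVTable

__all__ = [
    "UNDEFINED",
    "LEVELS",
    "UNINFORMATIVE_TERMS",
    "DISPLAY_ROLES",
    "LineageAssignment",
    "NaiveBayesClassifier",
    "train_classifier",
    "classify",
    "GenusTable",
    "agglomerate_genus",
    "summarize_phyla",
]

logger = logging.getLogger(__name__)

UNDEFINED = "UNDEFINED"
LEVELS = ("phylum", "class", "order", "family", "genus")

#: Genus names that carry no taxonomic information (matched case-insensitively).
UNINFORMATIVE_TERMS = frozenset(
    {"undefined", "uncultured", "unidentified", "environmental", "metagenome",
     "incertae sedis"}
)

DISPLAY_ROLES = {
    "microbiome": "Microbiome",
    "eukaryome": "Eukaryome",
    "eukaryome_parasite": "Eukaryome (parasites)",
    "food_item": "Food items",
    "passing_material": "Passing material",
    "undetermined": "Undetermined role",
}

Lineage = Tuple[str, str, str, str, str]


@dataclass
class LineageAssignment:
    """Taxonomic call for one variant with per-level bootstrap support."""

    lineage: Lineage
    bootstrap: Dict[str, float]
    rsv_id: Optional[str] = None

    def level(self, name: str) -> str:
        return self.lineage[LEVELS.index(name)]


def _words(seq: str, k: int) -> List[str]:
    """All k-mers over unambiguous bases; words containing N are skipped."""
    return [
        seq[i:i + k]
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i:i + k]
    ]


@dataclass
class NaiveBayesClassifier:
    k: int
    genera: List[str]
    lineages: Dict[str, Lineage]
    word_index: Dict[str, int]
    log_prob: np.ndarray = field(repr=False)  # genera x known words
    log_floor: np.ndarray = field(repr=False)  # per-genus unseen-word log prob


def train_classifier(
    references: Sequence[Tuple[str, str]],
    lineages: pd.DataFrame,
    k: int = 8,
) -> NaiveBayesClassifier:
    """Fit the word-probability model from a reference FASTA + lineage table.

    ``lineages`` needs columns seq_id, phylum, class, order, family, genus.
    Exact duplicate (genus, sequence) references are counted once.
    """
    lin = lineages.set_index("seq_id")
    genus_of: Dict[str, str] = {}
    lineage_of_genus: Dict[str, Lineage] = {}
    seen: set = set()
    ref_words: List[Tuple[str, set]] = []  # (genus, word set)
    for seq_id, seq in references:
        if seq_id not in lin.index:
            raise ValueError(f"no lineage for reference {seq_id!r}")
        row = lin.loc[seq_id]
        genus = str(row["genus"])
        if len(seq) < k:
            raise ValueError(f"reference {seq_id!r} shorter than k={k}")
        key = (genus, seq)
        if key in seen:
            continue
        seen.add(key)
        genus_of[seq_id] = genus
        lineage_of_genus.setdefault(
            genus,
            (str(row["phylum"]), str(row["class"]), str(row["order"]),
             str(row["family"]), genus),
        )
        ref_words.append((genus, set(_words(seq, k))))

    genera = sorted(lineage_of_genus)
    if len(genera) < 2:
        raise ValueError("need at least 2 genera to train")
    m_of_genus = {g: 0 for g in genera}
    for g, _ in ref_words:
        m_of_genus[g] += 1
    if min(m_of_genus.values()) == 0:
        raise ValueError("genus with no reference sequence")

    all_words = sorted(set().union(*(w for _, w in ref_words)))
    word_index = {w: i for i, w in enumerate(all_words)}
    N = len(ref_words)
    n_w = np.zeros(len(all_words))
    m_wg = np.zeros((len(genera), len(all_words)))
    gidx = {g: i for i, g in enumerate(genera)}
    for g, words in ref_words:
        idx = [word_index[w] for w in words]
        n_w[idx] += 1
        m_wg[gidx[g], idx] += 1

    prior = (n_w + 0.5) / (N + 1.0)
    M = np.array([m_of_genus[g] for g in genera], dtype=float)
    log_prob = np.log((m_wg + prior[None, :]) / (M[:, None] + 1.0))
    prior_unseen = 0.5 / (N + 1.0)
    log_floor = np.log(prior_unseen / (M + 1.0))
    return NaiveBayesClassifier(
        k=k, genera=genera, lineages=lineage_of_genus,
        word_index=word_index, log_prob=log_prob, log_floor=log_floor,
    )


def _score_words(model: NaiveBayesClassifier, idx: np.ndarray) -> np.ndarray:
    """Summed log P(w|g) per genus for word indices (-1 = unseen word)."""
    known = idx[idx >= 0]
    unseen = int((idx < 0).sum())
    scores = model.log_prob[:, known].sum(axis=1) if known.size else np.zeros(
        len(model.genera)
    )
    return scores + unseen * model.log_floor


def classify(
    sequence: str,
    model: NaiveBayesClassifier,
    n_bootstrap: int = 100,
    min_boot: float = 0.5,
    seed: int = 0,
) -> LineageAssignment:
    """Assign a lineage with bootstrap confidence.

    The winning genus maximizes the full-word score (ties broken by genus
    name); each of ``n_bootstrap`` resamples draws one eighth of the words
    with replacement, and per-level confidence is the fraction of
    bootstrap winners agreeing with the winner's lineage at that level.
    Levels below ``min_boot`` are reported UNDEFINED.
    """
    words = _words(sequence.upper(), model.k)
    if not words:
        raise ValueError("sequence contains no valid k-mer word")
    idx = np.array([model.word_index.get(w, -1) for w in words])
    scores = _score_words(model, idx)
    winner = int(np.argmax(scores))
    win_lineage = model.lineages[model.genera[winner]]

    rng = np.random.default_rng(seed)
    n_draw = max(1, len(words) // 8)
    agree = np.zeros(len(LEVELS))
    for _ in range(n_bootstrap):
        sub = rng.choice(idx, size=n_draw, replace=True)
        bscores = _score_words(model, sub)
        # exact score ties (e.g. no informative word drawn) are broken at
        # random so uninformative queries cannot accrue spurious support
        top = np.nonzero(bscores >= bscores.max() - 1e-12)[0]
        bwin = int(top[rng.integers(0, len(top))]) if len(top) > 1 else int(top[0])
        blin = model.lineages[model.genera[bwin]]
        for li in range(len(LEVELS)):
            if blin[li] == win_lineage[li]:
                agree[li] += 1
    conf = agree / n_bootstrap
    # lineage levels are nested, so support is monotone non-increasing from
    # phylum to genus; cutting below min_boot keeps a defined prefix
    lineage = tuple(
        win_lineage[i] if conf[i] >= min_boot else UNDEFINED
        for i in range(len(LEVELS))
    )
    defined = True
    final = []
    for i, name in enumerate(lineage):
        if name == UNDEFINED:
            defined = False
        final.append(name if defined else UNDEFINED)
    return LineageAssignment(
        lineage=tuple(final),
        bootstrap={lvl: float(conf[i]) for i, lvl in enumerate(LEVELS)},
    )


def _uninformative(name: str) -> bool:
    low = name.strip().lower()
    return (
        not low
        or low == UNDEFINED.lower()
        or any(term in low for term in UNINFORMATIVE_TERMS)
    )


@dataclass
class GenusTable:
    """Genus x sample counts with phylum, domain and functional role."""

    counts: pd.DataFrame  # genus x sample
    meta: pd.DataFrame  # index genus; columns phylum, domain, role

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta indexed by different genera")

    @property
    def genera(self) -> List[str]:
        return list(self.counts.index)

    def subset_domain(self, domain: str) -> "GenusTable":
        keep = self.meta.index[self.meta["domain"] == domain]
        return GenusTable(self.counts.loc[keep], self.meta.loc[keep])

    def subset_phylum(self, phylum: str) -> "GenusTable":
        keep = self.meta.index[self.meta["phylum"] == phylum]
        return GenusTable(self.counts.loc[keep], self.meta.loc[keep])

    def phylum_rows(self) -> pd.DataFrame:
        """Per-phylum accounting rows (domain, phylum, n_genera, n_reads)."""
        df = self.meta.copy()
        df["n_reads"] = self.counts.sum(axis=1)
        agg = (
            df.groupby(["domain", "phylum"], sort=True)
            .agg(n_genera=("phylum", "size"), n_reads=("n_reads", "sum"))
            .reset_index()
        )
        return agg


def agglomerate_genus(
    rsv_table: RSVTable,
    assignments: Mapping[Tuple[str, str], LineageAssignment],
    amplicon_targets: Mapping[str, str],
    role_map: Optional[Mapping[str, str]] = None,
) -> GenusTable:
    """Merge variant counts across amplicons by shared genus annotation.

    Exclusions, applied in order and logged: variants without an
    informative genus; genera that are the sole genus of their phylum;
    genera with an undefined phylum.
    """
    table = rsv_table.table
    rows: Dict[str, np.ndarray] = {}
    meta_rows: Dict[str, dict] = {}
    n_na = 0
    for key in table.index:
        amp, _seq = key
        if key not in assignments:
            raise ValueError(f"missing assignment for RSV {key[0]}:{key[1][:16]}...")
        asg = assignments[key]
        genus = asg.level("genus")
        if genus == UNDEFINED or _uninformative(genus):
            n_na += 1
            continue
        vec = table.loc[key].to_numpy()
        if genus in rows:
            rows[genus] = rows[genus] + vec
        else:
            rows[genus] = vec.astype(np.int64).copy()
            meta_rows[genus] = {
                "phylum": asg.level("phylum"),
                "domain": amplicon_targets.get(amp, UNDEFINED),
            }
    if n_na:
        logger.info("dropped %d RSVs without informative genus", n_na)

    if not rows:
        empty = pd.DataFrame(index=pd.Index([], name="genus"),
                             columns=table.columns)
        meta = pd.DataFrame(
            index=pd.Index([], name="genus"),
            columns=["phylum", "domain", "role"],
        )
        return GenusTable(empty.fillna(0), meta)
    counts = pd.DataFrame(rows, index=table.columns).T.sort_index()
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").sort_index()

    # sole genus of its phylum
    phylum_sizes = meta.groupby("phylum")["phylum"].transform("size")
    sole = meta.index[phylum_sizes == 1]
    if len(sole):
        logger.info("dropped %d sole-genus-in-phylum genera: %s",
                    len(sole), list(sole))
    counts = counts.drop(index=sole)
    meta = meta.drop(index=sole)

    # undefined phylum
    bad_phylum = meta.index[
        [(_uninformative(p) or p == UNDEFINED) for p in meta["phylum"]]
    ]
    if len(bad_phylum):
        logger.info("dropped %d undefined-phylum genera", len(bad_phylum))
    counts = counts.drop(index=bad_phylum)
    meta = meta.drop(index=bad_phylum)

    role_map = role_map or {}
    meta["role"] = [
        role_map.get(p, "undetermined") for p in meta["phylum"]
    ]
    return GenusTable(counts, meta)


def summarize_phyla(
    phylum_rows: pd.DataFrame,
    role_map: Mapping[str, str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-phylum accounting with functional roles plus domain totals.

    ``phylum_rows`` carries one row per (domain, phylum) with any of the
    columns n_genera, n_rsvs, n_reads.  Rows whose phylum is UNDEFINED (or
    uninformative) enter the full domain totals but not the named totals.
    Returns (per-phylum table, domain totals with named and full rows).
    """
    df = phylum_rows.copy()
    value_cols = [c for c in ("n_genera", "n_rsvs", "n_reads") if c in df.columns]
    if not value_cols:
        raise ValueError("phylum_rows carries no accounting columns")
    if df.empty:
        df["role"] = pd.Series(dtype=str)
        df["role_label"] = pd.Series(dtype=str)
        return df, pd.DataFrame(
            columns=["domain", "scope", *value_cols]
        )

    def role_of(phylum: str) -> str:
        if _uninformative(phylum) or phylum == UNDEFINED:
            return "undetermined"
        if phylum not in role_map:
            logger.warning("phylum %s missing from role map; role undetermined",
                           phylum)
            return "undetermined"
        return role_map[phylum]

    df["role"] = [role_of(p) for p in df["phylum"]]
    df["role_label"] = [DISPLAY_ROLES[r] for r in df["role"]]

    named = df[
        ~df["phylum"].map(lambda p: _uninformative(p) or p == UNDEFINED)
    ]
    totals = []
    for domain, grp in df.groupby("domain", sort=True):
        row = {"domain": domain, "scope": "full"}
        for c in value_cols:
            row[c] = int(grp[c].sum())
        totals.append(row)
    for domain, grp in named.groupby("domain", sort=True):
        row = {"domain": domain, "scope": "named"}
        for c in value_cols:
            row[c] = int(grp[c].sum())
        totals.append(row)
    domain_totals = pd.DataFrame(totals).sort_values(
        ["domain", "scope"]
    ).reset_index(drop=True)
    return df, domain_totals
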