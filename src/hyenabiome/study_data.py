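"""Host metadata semantics and the synthetic-data generator.

The study design emulated here: individually known spotted hyenas (adult
females holding a standardized social rank in [-1, +1], plus juveniles
below 24 months of age) sampled once each, every fecal sample amplified in
a panel of 16S (bacterial) and 18S (eukaryote) amplicons across technical
replicates, with water negative controls on the same PCR array.  The
generator produces the full statistical structure downstream stages need:
per-sample true genus abundances with configurable age and rank effects on
richness, primer-prefixed paired reads with substitution errors, PCR
chimeras and deliberately failed replicates, McMaster chamber counts that
are log-linearly coupled to true parasite abundance, and a reference
database with lineages for classifier training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AGE_CLASS_BOUNDARY_MONTHS",
    "HostMetadata",
    "PanelEntry",
    "PrimerPanel",
    "TruthParams",
    "ReadParams",
    "CoprologyCoupling",
    "SyntheticTruth",
    "ReadPair",
    "SyntheticReads",
    "standardize_ranks",
    "classify_host",
    "generate_truth",
    "generate_reads",
    "generate_coprology",
    "generate_reference_db",
    "default_panel",
    "revcomp",
]

AGE_CLASS_BOUNDARY_MONTHS = 24.0

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC nucleotide codes and the unambiguous bases they stand for.
IUPAC_EXPANSION: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Host metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostMetadata:
    """One host individual: identity, age and (for adults) social rank.

    ``std_rank`` is the standardized dominance rank in [-1, +1]; juveniles
    carry no rank (the rank analysis concerns adult females only).
    """

    host_id: str
    age_months: float
    clan_id: str = "clan1"
    std_rank: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age_months < 0:
            raise ValueError(f"negative age for host {self.host_id!r}")
        if self.std_rank is not None and not -1.0 <= self.std_rank <= 1.0:
            raise ValueError(
                f"std_rank {self.std_rank} outside [-1, 1] for {self.host_id!r}"
            )

    @property
    def age_class(self) -> str:
        return classify_host(self.age_months, self.std_rank)[0]

    @property
    def rank_class(self) -> Optional[str]:
        return classify_host(self.age_months, self.std_rank)[1]


def standardize_ranks(dominance_order: Sequence[str]) -> Dict[str, float]:
    """Distribute standardized ranks evenly in [+1, -1] along a hierarchy.

    Position ``i`` (1-based, highest rank first) of ``n`` hosts scores
    ``1 - 2(i-1)/(n-1)``; the top host scores +1, the bottom -1, and for an
    odd number of hosts the median host scores exactly 0.  A single host
    scores 0 (the degenerate median).
    """
    hosts = list(dominance_order)
    if not hosts:
        raise ValueError("empty dominance order")
    if len(set(hosts)) != len(hosts):
        raise ValueError("duplicate host id in dominance order")
    n = len(hosts)
    if n == 1:
        return {hosts[0]: 0.0}
    return {h: 1.0 - 2.0 * i / (n - 1) for i, h in enumerate(hosts)}


def classify_host(
    age_months: float, std_rank: Optional[float] = None
) -> Tuple[str, Optional[str]]:
    """Age class (juvenile below 24 months, adult at or above) and rank
    class (high at standardized rank >= 0, low below; absent without a
    rank)."""
    if age_months < 0:
        raise ValueError("negative age")
    age_class = "juvenile" if age_months < AGE_CLASS_BOUNDARY_MONTHS else "adult"
    rank_class: Optional[str] = None
    if std_rank is not None:
        rank_class = "high" if std_rank >= 0 else "low"
    return age_class, rank_class


# ---------------------------------------------------------------------------
# Primer panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelEntry:
    amplicon_id: str
    fwd_primer: str
    rev_primer: str
    target: str  # "16S" or "18S"

    def __post_init__(self) -> None:
        for p in (self.fwd_primer, self.rev_primer):
            if not p:
                raise ValueError(f"empty primer in amplicon {self.amplicon_id!r}")
            bad = set(p) - set(IUPAC_EXPANSION)
            if bad:
                raise ValueError(
                    f"non-IUPAC characters {sorted(bad)} in primer of "
                    f"{self.amplicon_id!r}"
                )
        if self.target not in ("16S", "18S"):
            raise ValueError(f"target must be 16S or 18S, got {self.target!r}")


@dataclass
class PrimerPanel:
    """The amplicon panel: unique amplicon ids with unique primer pairs."""

    entries: List[PanelEntry]

    def __post_init__(self) -> None:
        ids = [e.amplicon_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate amplicon_id in panel")
        pairs = [(e.fwd_primer, e.rev_primer) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate primer pair in panel")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def by_target(self, target: str) -> List[PanelEntry]:
        return [e for e in self.entries if e.target == target]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.entries],
            columns=["amplicon_id", "fwd_primer", "rev_primer", "target"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PrimerPanel":
        return cls(
            [
                PanelEntry(
                    str(r.amplicon_id), str(r.fwd_primer), str(r.rev_primer),
                    str(r.target),
                )
                for r in df.itertuples()
            ]
        )


def default_panel(
    n_16s: int = 4, n_18s: int = 44, primer_length: int = 20, seed: int = 7_001
) -> PrimerPanel:
    """A synthetic panel shaped like the study's array: 4 bacterial 16S and
    44 eukaryote 18S amplicons, each with its own primer pair."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    entries: List[PanelEntry] = []
    seen = set()
    for target, n in (("16S", n_16s), ("18S", n_18s)):
        made = 0
        while made < n:
            fwd = "".join(rng.choice(bases, size=primer_length))
            rev = "".join(rng.choice(bases, size=primer_length))
            if (fwd, rev) in seen or fwd == rev:
                continue
            seen.add((fwd, rev))
            made += 1
            entries.append(
                PanelEntry(f"{target}_{made:02d}", fwd, rev, target)
            )
    return PrimerPanel(entries)


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

#: Functional roles by phylum, mirroring the conventional assignment of
#: eukaryote phyla to eukaryome members, parasites, food items or material
#: passing through the gut.
DEFAULT_ROLE_MAP: Dict[str, str] = {
    "Actinobacteria": "microbiome",
    "Bacteroidetes": "microbiome",
    "Firmicutes": "microbiome",
    "Fusobacteria": "microbiome",
    "Proteobacteria": "microbiome",
    "Tenericutes": "microbiome",
    "Apicomplexa": "eukaryome_parasite",
    "Nematoda": "eukaryome_parasite",
    "Platyhelminthes": "eukaryome_parasite",
    "Ascomycota": "eukaryome",
    "Basidiomycota": "eukaryome",
    "Chordata": "food_item",
    "Arthropoda": "food_item",
    "Chlorophyta": "passing_material",
}

# phylum -> (domain, number of synthetic genera)
_DEFAULT_POOL: Dict[str, Tuple[str, int]] = {
    "Firmicutes": ("16S", 12),
    "Bacteroidetes": ("16S", 8),
    "Actinobacteria": ("16S", 6),
    "Proteobacteria": ("16S", 6),
    "Tenericutes": ("16S", 4),
    "Fusobacteria": ("16S", 3),
    "Ascomycota": ("18S", 10),
    "Basidiomycota": ("18S", 8),
    "Chlorophyta": ("18S", 5),
    "Chordata": ("18S", 3),
    "Arthropoda": ("18S", 4),
}

# Real parasite lineages needed for coprology coupling and the taxonomic
# agreement screen (genus, family, order, class, phylum).
_PARASITE_LINEAGES: List[Tuple[str, str, str, str, str]] = [
    ("Ancylostoma", "Ancylostomatidae", "Rhabditida", "Chromadorea", "Nematoda"),
    ("Haemonchus", "Haemonchidae", "Rhabditida", "Chromadorea", "Nematoda"),
    ("Trichuris", "Trichuridae", "Trichocephalida", "Enoplea", "Nematoda"),
    ("Diphyllobothrium", "Diphyllobothriidae", "Diphyllobothriidea",
     "Cestoda", "Platyhelminthes"),
    ("Spirometra", "Diphyllobothriidae", "Diphyllobothriidea",
     "Cestoda", "Platyhelminthes"),
    ("Taenia", "Taeniidae", "Cyclophyllidea", "Cestoda", "Platyhelminthes"),
    ("Eimeria", "Eimeriidae", "Eucoccidiorida", "Conoidasida", "Apicomplexa"),
    ("Isospora", "Eimeriidae", "Eucoccidiorida", "Conoidasida", "Apicomplexa"),
    ("Toxoplasma", "Sarcocystidae", "Eucoccidiorida", "Conoidasida",
     "Apicomplexa"),
    ("Sarcocystis", "Sarcocystidae", "Eucoccidiorida", "Conoidasida",
     "Apicomplexa"),
]

Lineage = Tuple[str, str, str, str, str]  # phylum, class, order, family, genus


def _default_lineages() -> Dict[str, Lineage]:
    """Genus -> (phylum, class, order, family, genus) for the default pool.

    Synthetic genera are nested two-per-family, two-families-per-order,
    two-orders-per-class so that higher-rank aggregation is non-trivial.
    """
    lineages: Dict[str, Lineage] = {}
    for phylum, (_, n) in _DEFAULT_POOL.items():
        stem = phylum[:4]
        for i in range(n):
            genus = f"{stem}_genus{i + 1:02d}"
            fam = f"{stem}_fam{i // 2 + 1:02d}"
            order = f"{stem}_ord{i // 4 + 1:02d}"
            klass = f"{stem}_cls{i // 8 + 1:02d}"
            lineages[genus] = (phylum, klass, order, fam, genus)
    for genus, fam, order, klass, phylum in _PARASITE_LINEAGES:
        lineages[genus] = (phylum, klass, order, fam, genus)
    return lineages


def _default_domains(lineages: Mapping[str, Lineage]) -> Dict[str, str]:
    domains = {}
    for genus, (phylum, *_rest) in lineages.items():
        dom = _DEFAULT_POOL.get(phylum, (None, 0))[0]
        if dom is None:
            dom = "18S"  # parasite phyla are eukaryote 18S targets
        domains[genus] = dom
    return domains


@dataclass
class CoprologyCoupling:
    """Log-linear coupling of a McMaster morphotype to sequence abundance:
    expected log10(1+FEC) = a + b * log10(1 + true abundance), chamber
    counts drawn with gamma-Poisson overdispersion (Poisson at 0)."""

    morphotype: str
    taxa: Tuple[str, ...]
    a: float = 0.0
    b: float = 1.0
    dispersion: float = 0.1
    size_classes: Tuple[str, ...] = ("all",)
    size_class_props: Tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("negative dispersion")
        if len(self.size_classes) != len(self.size_class_props):
            raise ValueError("size class / proportion length mismatch")


def default_couplings() -> List[CoprologyCoupling]:
    return [
        CoprologyCoupling(
            "strongyle_egg", ("Ancylostoma",),
            size_classes=("<80um", ">=80um"), size_class_props=(0.95, 0.05),
        ),
        CoprologyCoupling("diphyllobothriid_egg", ("Diphyllobothrium",)),
        CoprologyCoupling(
            "coccidia_oocyst", ("Eimeria", "Isospora"),
            size_classes=("<20um", ">=20um"), size_class_props=(0.7, 0.3),
        ),
    ]


@dataclass
class TruthParams:
    """Study-condition parameters for the truth generator.

    Defaults emulate the study's sampling frame: 42 hosts (35 adult
    females with standardized ranks, 7 juveniles), two technical
    replicates each, two water controls and two deliberately failed
    replicate PCRs.  Richness effects are expressed as additional genera
    drawn: adults carry ``age_effect_bacteria`` more bacterial genera than
    juveniles and high-ranking adults ``rank_effect_eukaryote`` more
    eukaryote genera than low-ranking ones, matching the direction and
    order of magnitude of the reported group differences (adult median 49
    vs juvenile 41 bacterial genera, scaled to the synthetic pool).
    """

    n_juveniles: int = 7
    n_clans: int = 3
    base_richness_bacteria: int = 18
    base_richness_eukaryote: int = 20
    core_bacteria: int = 8
    core_eukaryote: int = 8
    core_abundance_bonus: float = 1.5
    age_effect_bacteria: int = 8
    rank_effect_eukaryote: int = 8
    abundance_mu: float = 4.0
    abundance_sigma: float = 1.5
    parasite_mu: float = 7.0
    parasite_sigma: float = 1.5
    parasite_prevalence: float = 0.8
    n_replicates: int = 2
    n_water: int = 2
    n_failed: int = 2
    couplings: List[CoprologyCoupling] = field(default_factory=default_couplings)
    lineages: Dict[str, Lineage] = field(default_factory=_default_lineages)
    domains: Dict[str, str] = field(default_factory=dict)
    roles: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLE_MAP))

    def __post_init__(self) -> None:
        if not self.domains:
            self.domains = _default_domains(self.lineages)


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: List[int]
    qual2: List[int]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in {self.id!r}")


@dataclass
class SyntheticTruth:
    """Everything downstream recovery tests need to score the pipeline."""

    abundance: pd.DataFrame  # genus x sample, true read-scale abundance
    hosts: List[HostMetadata]
    lineages: Dict[str, Lineage]
    domains: Dict[str, str]
    roles: Dict[str, str]
    references: Dict[str, str]  # genus -> reference sequence
    replicate_map: Dict[str, str]  # replicate id -> sample id
    failed_replicates: set
    water_controls: set
    couplings: List[CoprologyCoupling]
    params: TruthParams
    seed: int

    @property
    def samples(self) -> List[str]:
        return list(self.abundance.columns)

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hosts:
            rows.append(
                {
                    "host_id": h.host_id,
                    "age_months": h.age_months,
                    "clan_id": h.clan_id,
                    "std_rank": np.nan if h.std_rank is None else h.std_rank,
                    "age_class": h.age_class,
                    "rank_class": h.rank_class or "",
                }
            )
        return pd.DataFrame(rows)


def generate_truth(
    n_hosts: int = 42,
    params: Optional[TruthParams] = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw per-sample true genus abundances with age and rank effects.

    One fecal sample per host.  Each sample carries a random subset of the
    bacterial and eukaryote genus pools; adults draw more bacterial genera
    and high-ranking adults more eukaryote genera, by the configured
    effect sizes.  Abundances of present genera are log-normal; seeded
    parasite genera use a wider log-normal so coprology coupling spans
    several orders of magnitude, and are present with the configured
    prevalence.
    """
    params = params or TruthParams()
    if n_hosts < 2:
        raise ValueError("need at least 2 hosts")
    rng = np.random.default_rng(seed)

    bacteria = sorted(g for g, d in params.domains.items() if d == "16S")
    eukaryotes = sorted(g for g, d in params.domains.items() if d == "18S")
    parasites = sorted(
        {g for c in params.couplings for g in c.taxa} & set(eukaryotes)
    )
    non_parasite_euks = [g for g in eukaryotes if g not in parasites]

    for label, base, effect, pool in (
        ("bacteria", params.base_richness_bacteria,
         params.age_effect_bacteria, bacteria),
        ("eukaryote", params.base_richness_eukaryote,
         params.rank_effect_eukaryote, non_parasite_euks),
    ):
        if base <= 0 or base + effect <= 0:
            raise ValueError(f"effect sizes produce non-positive {label} richness")
        if base + max(effect, 0) > len(pool):
            raise ValueError(f"{label} richness exceeds genus pool size")

    n_juv = min(params.n_juveniles, n_hosts - 1)
    n_adult = n_hosts - n_juv
    adult_ids = [f"host{i + 1:02d}" for i in range(n_adult)]
    ranks = standardize_ranks(adult_ids)
    hosts: List[HostMetadata] = []
    for i, hid in enumerate(adult_ids):
        age = float(rng.uniform(25.0, 150.0))
        hosts.append(
            HostMetadata(hid, age, f"clan{i % params.n_clans + 1}", ranks[hid])
        )
    for j in range(n_juv):
        hid = f"host{n_adult + j + 1:02d}"
        age = float(rng.uniform(3.0, 23.0))
        hosts.append(HostMetadata(hid, age, f"clan{j % params.n_clans + 1}", None))

    samples = [h.host_id for h in hosts]
    genera = bacteria + eukaryotes
    abundance = pd.DataFrame(0.0, index=genera, columns=samples)

    # core community members present in every host, as in real gut biomes
    n_core_b = min(params.core_bacteria, params.base_richness_bacteria)
    n_core_e = min(params.core_eukaryote, params.base_richness_eukaryote)
    core_b = list(rng.choice(bacteria, size=n_core_b, replace=False))
    core_e = list(
        rng.choice(non_parasite_euks, size=n_core_e, replace=False)
    )
    var_b = [g for g in bacteria if g not in core_b]
    var_e = [g for g in non_parasite_euks if g not in core_e]

    for h in hosts:
        # bacterial richness: adults draw age_effect_bacteria more genera
        rich_b = params.base_richness_bacteria
        if h.age_class == "adult":
            rich_b += params.age_effect_bacteria
        chosen_b = core_b + list(
            rng.choice(var_b, size=rich_b - len(core_b), replace=False)
        )
        # eukaryote richness: high-ranking adults draw more genera
        rich_e = params.base_richness_eukaryote
        if h.rank_class == "high":
            rich_e += params.rank_effect_eukaryote
        rich_e = min(rich_e, len(non_parasite_euks))
        chosen_e = core_e + list(
            rng.choice(var_e, size=rich_e - len(core_e), replace=False)
        )
        for g in chosen_b + chosen_e:
            # core members are the abundant, ubiquitous fraction of the
            # community, hence the location bonus
            mu = params.abundance_mu + (
                params.core_abundance_bonus if g in core_b or g in core_e
                else 0.0
            )
            abundance.loc[g, h.host_id] = rng.lognormal(
                mu, params.abundance_sigma
            )
        for g in parasites:
            if rng.uniform() < params.parasite_prevalence:
                abundance.loc[g, h.host_id] = rng.lognormal(
                    params.parasite_mu, params.parasite_sigma
                )

    references = _make_references(sorted(params.lineages), rng)

    replicate_map: Dict[str, str] = {}
    for s in samples:
        for r in range(1, params.n_replicates + 1):
            replicate_map[f"{s}_r{r}"] = s
    ordinary = sorted(replicate_map)
    failed = set(
        rng.choice(ordinary, size=min(params.n_failed, len(ordinary)),
                   replace=False).tolist()
    )
    water = {f"water_{w + 1}" for w in range(params.n_water)}
    for w in sorted(water):
        replicate_map[w] = w

    return SyntheticTruth(
        abundance=abundance,
        hosts=hosts,
        lineages=dict(params.lineages),
        domains=dict(params.domains),
        roles=dict(params.roles),
        references=references,
        replicate_map=replicate_map,
        failed_replicates=failed,
        water_controls=water,
        couplings=list(params.couplings),
        params=params,
        seed=seed,
    )


def _make_references(
    genera: Sequence[str], rng: np.random.Generator, length: int = 1500
) -> Dict[str, str]:
    bases = np.array(list("ACGT"))
    return {g: "".join(rng.choice(bases, size=length)) for g in genera}


def generate_reference_db(
    lineages: Mapping[str, Lineage],
    seed: int = 0,
    length: int = 1500,
    n_per_genus: int = 1,
    max_shared_kmer_fraction: Optional[float] = None,
    k: int = 8,
    sequences: Optional[Mapping[str, str]] = None,
    within_genus_divergence: float = 0.02,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Reference FASTA records plus a lineage table for classifier training.

    Each genus receives ``n_per_genus`` reference sequences: the first is
    the genus base sequence (taken from ``sequences`` when given, e.g. the
    truth's marker sequences, otherwise random), further ones are slightly
    diverged copies of it.  Independent random sequences of typical marker
    length already share well under 5% of their 8-mers between genera;
    when ``max_shared_kmer_fraction`` is given, random bases are redrawn
    until every pairwise shared k-mer fraction is below it.
    """
    if not lineages:
        raise ValueError("empty lineage set")
    genera = sorted(lineages)
    phyla = {lin[0] for lin in lineages.values()}
    if len(genera) < 2 or len(phyla) < 2:
        raise ValueError("need at least 2 genera across at least 2 phyla")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records: List[Tuple[str, str]] = []
    kmer_sets: List[set] = []
    for g in genera:
        base: Optional[str] = sequences.get(g) if sequences else None
        for j in range(n_per_genus):
            for _attempt in range(50):
                if j == 0 and base is not None:
                    seq = base
                elif j == 0:
                    seq = "".join(rng.choice(bases, size=length))
                else:
                    seq = _mutate(
                        base if base is not None else records[-1][1],
                        within_genus_divergence, rng,
                    )
                kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
                if max_shared_kmer_fraction is None or (j == 0 and base is not None):
                    break
                frac = max(
                    (len(kmers & other) / len(kmers) for other in kmer_sets),
                    default=0.0,
                )
                if frac < max_shared_kmer_fraction:
                    break
            if j == 0 and base is None:
                base = seq
            kmer_sets.append(kmers)
            records.append((f"{g}_ref{j + 1}", seq))
    lineage_rows = [
        {
            "seq_id": f"{g}_ref{j + 1}",
            "phylum": lineages[g][0],
            "class": lineages[g][1],
            "order": lineages[g][2],
            "family": lineages[g][3],
            "genus": lineages[g][4],
        }
        for g in genera
        for j in range(n_per_genus)
    ]
    return records, pd.DataFrame(lineage_rows)


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

@dataclass
class ReadParams:
    """Sequencing-emulation parameters.

    ``depth`` is read pairs per ordinary technical replicate;
    ``substitution_rate`` is the per-base error rate applied to the whole
    read (primer included, as on a real sequencer); ``chimera_rate`` the
    probability a pair derives from a two-parent prefix+suffix join.
    Failed replicates receive a near-zero Poisson depth; water controls a
    small Poisson cross-contamination depth.
    """

    depth: int = 500
    substitution_rate: float = 0.0
    chimera_rate: float = 0.0
    read_length: int = 250
    template_length: int = 400
    amplicons_per_genus: int = 3
    base_quality: int = 35
    failed_depth_mean: float = 2.0
    water_depth_mean: float = 5.0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive for ordinary replicates")


@dataclass
class SyntheticReads:
    """Per-replicate read pairs plus the per-read truth labels."""

    reads: Dict[str, List[ReadPair]]  # replicate id -> pairs
    labels: pd.DataFrame  # replicate, read_id, amplicon_id, template_id, is_chimera
    templates: Dict[Tuple[str, str], str]  # (genus, amplicon) -> template seq
    params: ReadParams
    seed: int

    def template_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"genus": g, "amplicon_id": a, "template": t}
                for (g, a), t in sorted(self.templates.items())
            ]
        )


def _assign_templates(
    truth: SyntheticTruth, panel: PrimerPanel, params: ReadParams,
    rng: np.random.Generator,
) -> Dict[Tuple[str, str], str]:
    """Each genus is amplified by a fixed subset of same-domain amplicons;
    the template is an amplicon-specific slice of the genus reference."""
    templates: Dict[Tuple[str, str], str] = {}
    by_target = {t: panel.by_target(t) for t in ("16S", "18S")}
    for genus in sorted(truth.references):
        dom = truth.domains[genus]
        pool = by_target[dom]
        if not pool:
            raise ValueError(f"panel has no amplicon for target {dom}")
        n_amp = min(params.amplicons_per_genus, len(pool))
        chosen = rng.choice(len(pool), size=n_amp, replace=False)
        ref = truth.references[genus]
        max_start = len(ref) - params.template_length
        for idx in sorted(chosen):
            start = int(rng.integers(0, max_start + 1))
            templates[(genus, pool[idx].amplicon_id)] = ref[
                start:start + params.template_length
            ]
    return templates


def _make_pair(
    read_id: str, template: str, entry: PanelEntry, params: ReadParams,
    rng: np.random.Generator,
) -> ReadPair:
    n1 = params.read_length - len(entry.fwd_primer)
    n2 = params.read_length - len(entry.rev_primer)
    seq1 = entry.fwd_primer + template[:n1]
    seq2 = entry.rev_primer + revcomp(template)[:n2]
    e = params.substitution_rate
    if e > 0:
        seq1 = _mutate(seq1, e, rng)
        seq2 = _mutate(seq2, e, rng)
    q1 = [params.base_quality] * len(seq1)
    q2 = [params.base_quality] * len(seq2)
    return ReadPair(read_id, seq1, seq2, q1, q2)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.uniform(size=len(arr)) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def generate_reads(
    truth: SyntheticTruth,
    panel: PrimerPanel,
    params: Optional[ReadParams] = None,
    seed: int = 0,
) -> SyntheticReads:
    """Emit primer-prefixed paired reads per technical replicate.

    Each pair is drawn from the sample's true (genus, amplicon) templates
    with probability proportional to genus abundance; with probability
    ``chimera_rate`` the template is replaced by a two-parent prefix+suffix
    join within the same amplicon.  Water controls receive low-level
    cross-contamination from random templates.  Output is deterministic
    given the seed.
    """
    params = params or ReadParams()
    rng = np.random.default_rng(seed)
    templates = _assign_templates(truth, panel, params, rng)
    entry_by_id = {e.amplicon_id: e for e in panel}

    # per sample: candidate (genus, amplicon) list + weights
    sample_choices: Dict[str, Tuple[List[Tuple[str, str]], np.ndarray]] = {}
    for s in truth.samples:
        cands = [
            (g, a) for (g, a) in templates
            if truth.abundance.loc[g, s] > 0
        ]
        w = np.array([truth.abundance.loc[g, s] for g, a in cands], dtype=float)
        sample_choices[s] = (cands, w / w.sum() if w.sum() > 0 else w)

    all_template_keys = sorted(templates)
    reads: Dict[str, List[ReadPair]] = {}
    label_rows: List[dict] = []

    for rep in sorted(truth.replicate_map):
        is_water = rep in truth.water_controls
        if is_water:
            depth = int(rng.poisson(params.water_depth_mean))
        elif rep in truth.failed_replicates:
            depth = int(rng.poisson(params.failed_depth_mean))
        else:
            depth = params.depth
        pairs: List[ReadPair] = []
        sample = truth.replicate_map[rep]
        if not is_water:
            cands, probs = sample_choices[sample]
        for i in range(depth):
            read_id = f"{rep}:{i + 1}"
            if is_water or not len(sample_choices[sample][0]):
                g, a = all_template_keys[rng.integers(0, len(all_template_keys))]
            else:
                g, a = cands[rng.choice(len(cands), p=probs)]
            entry = entry_by_id[a]
            tmpl = templates[(g, a)]
            template_id = f"{g}|{a}"
            is_chimera = False
            if not is_water and params.chimera_rate > 0 and rng.uniform() < params.chimera_rate:
                # the second parent joins in proportion to its template
                # concentration, as in PCR chimera formation
                same_amp = [
                    (g2, a2) for (g2, a2) in cands
                    if a2 == a and g2 != g
                ]
                if same_amp:
                    w2 = np.array(
                        [truth.abundance.loc[g2, sample] for g2, _ in same_amp]
                    )
                    g2, _ = same_amp[rng.choice(len(same_amp), p=w2 / w2.sum())]
                    tmpl2 = templates[(g2, a)]
                    k = int(rng.integers(50, params.template_length - 50))
                    tmpl = tmpl[:k] + tmpl2[k:]
                    template_id = f"{g}|{g2}|{a}|chimera"
                    is_chimera = True
            pairs.append(_make_pair(read_id, tmpl, entry, params, rng))
            label_rows.append(
                {
                    "replicate": rep,
                    "read_id": read_id,
                    "amplicon_id": a,
                    "template_id": template_id,
                    "is_chimera": is_chimera,
                    "is_water": is_water,
                }
            )
        reads[rep] = pairs

    labels = pd.DataFrame(
        label_rows,
        columns=["replicate", "read_id", "amplicon_id", "template_id",
                 "is_chimera", "is_water"],
    )
    return SyntheticReads(reads, labels, templates, params, seed)


# ---------------------------------------------------------------------------
# Coprology generation
# ---------------------------------------------------------------------------

def generate_coprology(
    truth: SyntheticTruth,
    couplings: Optional[Sequence[CoprologyCoupling]] = None,
    seed: int = 0,
    dilution: float = 15.0,
    chamber_volume_ml: float = 0.15,
    n_chambers: int = 4,
) -> pd.DataFrame:
    """McMaster chamber counts log-linearly coupled to true abundance.

    For each (sample, morphotype), expected eggs per gram satisfy
    log10(1+FEC) = a + b*log10(1+abundance) where abundance is the summed
    true abundance of the coupled taxa.  The total counted eggs across the
    four chambers are drawn gamma-Poisson with the configured
    overdispersion (Poisson when dispersion is 0) around FEC divided by
    the McMaster multiplier, split multinomially over chambers and size
    classes.  Zero abundance with a = 0 yields zero counts.
    """
    couplings = list(couplings) if couplings is not None else truth.couplings
    rng = np.random.default_rng(seed)
    multiplier = dilution / (n_chambers * chamber_volume_ml)
    rows: List[dict] = []
    for coup in couplings:
        if coup.dispersion < 0:
            raise ValueError("negative dispersion")
        for s in truth.samples:
            abund = float(
                sum(
                    truth.abundance.loc[t, s]
                    for t in coup.taxa
                    if t in truth.abundance.index
                )
            )
            if abund == 0 and coup.a == 0:
                expected_fec = 0.0
            else:
                expected_fec = 10.0 ** (
                    coup.a + coup.b * np.log10(1.0 + abund)
                ) - 1.0
                expected_fec = max(expected_fec, 0.0)
            mean_total = expected_fec / multiplier
            for sc, prop in zip(coup.size_classes, coup.size_class_props):
                m = mean_total * prop
                if m == 0:
                    total = 0
                elif coup.dispersion == 0:
                    total = int(rng.poisson(m))
                else:
                    lam = rng.gamma(
                        shape=1.0 / coup.dispersion,
                        scale=m * coup.dispersion,
                    )
                    total = int(rng.poisson(lam))
                chambers = rng.multinomial(total, [1.0 / n_chambers] * n_chambers)
                rows.append(
                    {
                        "sample": s,
                        "morphotype": coup.morphotype,
                        "size_class": sc,
                        "c1": int(chambers[0]),
                        "c2": int(chambers[1]),
                        "c3": int(chambers[2]),
                        "c4": int(chambers[3]),
                        "epg": float(total * multiplier),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sample", "morphotype", "size_class", "c1", "c2", "c3", "c4",
                 "epg"],
    )
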