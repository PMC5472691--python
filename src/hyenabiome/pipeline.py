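"""File formats, configuration and the end-to-end pipeline.

All tables are TSV (header row, UTF-8, '.' decimal); FASTQ is Phred+33
with gzip decided by file extension; nested results are JSON.  The
pipeline stages run in the method's order: simulate (optional) -> filter +
stratify -> denoise -> replicate QC / collapse / scaling -> taxonomy and
genus agglomeration -> coprology screen, diversity tests, ordination +
PLS, differential abundance.  Every run writes a manifest carrying the
seed and a hash of the configuration so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import composition as comp
from . import coprology as copro
from . import diff_abundance as da
from . import diversity as dv
from . import qc_normalize as qc
from . import read_prep, taxonomy
from .denoise import RSVTable, build_rsv_table, infer_rsvs, remove_bimeras
from .study_data import (
    CoprologyCoupling,
    PrimerPanel,
    ReadPair,
    ReadParams,
    SyntheticTruth,
    TruthParams,
    default_panel,
    generate_coprology,
    generate_reads,
    generate_reference_db,
    generate_truth,
)
from .taxonomy import GenusTable

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_paired_fastq",
    "write_paired_fastq",
    "write_fasta",
    "read_fasta",
    "PipelineConfig",
    "Pipeline",
    "run_pipeline",
    "STAGES",
]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "demux", "denoise", "qc", "taxonomy", "coprology",
    "diversity", "composition", "diffabund",
)


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O
# ---------------------------------------------------------------------------

def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[Tuple[str, str, List[int]]]:
    """Yield (id, sequence, phred qualities) from a Phred+33 FASTQ file."""
    path = Path(path)
    with _open_text(path, "r") as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
            seq = str(rec.seq)
            qual = rec.letter_annotations["phred_quality"]
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: record {rec.id!r} (#{i + 1}) has "
                    f"{len(seq)} bases but {len(qual)} qualities"
                )
            yield rec.id, seq, list(qual)


def write_fastq(path, records: Iterable[Tuple[str, str, List[int]]]) -> None:
    path = Path(path)
    with _open_text(path, "w") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {rid!r}: {len(seq)} bases vs {len(qual)} qualities"
                )
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = list(qual)
            SeqIO.write(rec, fh, "fastq")


def read_paired_fastq(r1_path, r2_path) -> List[ReadPair]:
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(
        read_fastq(r1_path), read_fastq(r2_path)
    ):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
        pairs.append(ReadPair(id1, s1, s2, q1, q2))
    return pairs


def write_paired_fastq(r1_path, r2_path, pairs: Iterable[ReadPair]) -> None:
    pairs = list(pairs)
    write_fastq(r1_path, ((p.id, p.seq1, p.qual1) for p in pairs))
    write_fastq(r2_path, ((p.id, p.seq2, p.qual2) for p in pairs))


def write_fasta(path, records: Iterable[Tuple[str, str]]) -> None:
    with _open_text(Path(path), "w") as fh:
        for rid, seq in records:
            SeqIO.write(SeqRecord(Seq(seq), id=rid, description=""), fh, "fasta")


def read_fasta(path) -> List[Tuple[str, str]]:
    with _open_text(Path(path), "r") as fh:
        return [(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration (YAML-serializable).

    When ``simulate`` is true, all inputs are generated under
    ``out_dir/simulate``; otherwise ``reads_dir``, ``panel``, ``metadata``,
    ``coprology`` and the reference database paths must exist.
    """

    out_dir: str = "hyenabiome_out"
    seed: int = 0
    simulate: bool = True
    # synthetic scale (used when simulate is true)
    n_hosts: int = 42
    n_16s: int = 4
    n_18s: int = 44
    depth: int = 500
    substitution_rate: float = 0.002
    chimera_rate: float = 0.02
    amplicons_per_genus: int = 3
    # external inputs (used when simulate is false)
    reads_dir: Optional[str] = None
    panel: Optional[str] = None
    metadata: Optional[str] = None
    coprology: Optional[str] = None
    reference_fasta: Optional[str] = None
    reference_lineages: Optional[str] = None
    replicates: Optional[str] = None
    # stage parameters
    trunc_len: int = 170
    max_ee: float = 2.0
    trunc_q: int = 2
    d_max: int = 1
    skew: float = 0.1
    k: int = 8
    n_bootstrap: int = 100
    min_boot: float = 0.5
    max_axes: int = 5
    fdr_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if not self.simulate:
            missing = [
                name for name in (
                    "reads_dir", "panel", "metadata", "coprology",
                    "reference_fasta", "reference_lineages", "replicates",
                )
                if getattr(self, name) is None
                or not Path(getattr(self, name)).exists()
            ]
            if missing:
                raise ValueError(
                    f"config paths missing or nonexistent: {missing}"
                )

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Table round-trips for stage intermediates
# ---------------------------------------------------------------------------

def rsv_table_to_tsv(table: RSVTable, path) -> None:
    write_tsv(table.to_frame(), path)


def rsv_table_from_tsv(path) -> RSVTable:
    df = read_tsv(path)
    df = df.drop(columns=["rsv_id"]).set_index(["amplicon_id", "sequence"])
    return RSVTable(df)


def genus_table_to_tsv(gt: GenusTable, path) -> None:
    df = gt.meta.join(gt.counts)
    df.index.name = "genus"
    write_tsv(df.reset_index(), path)


def genus_table_from_tsv(path) -> GenusTable:
    df = read_tsv(path).set_index("genus")
    meta = df[["phylum", "domain", "role"]]
    counts = df.drop(columns=["phylum", "domain", "role"])
    return GenusTable(counts, meta)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class Pipeline:
    """Stage orchestration with on-disk intermediates.

    Each stage writes its outputs under ``out_dir/<stage>/``; a stage that
    is run alone loads whatever it needs from earlier stage outputs, so
    the pipeline is re-runnable from intermediates.
    """

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.truth: Optional[SyntheticTruth] = None
        self._reads: Optional[Dict[str, List[ReadPair]]] = None
        self._amplicon_matrix = None
        self._rsv_table: Optional[RSVTable] = None
        self._sample_table: Optional[RSVTable] = None
        self._normalized: Optional[pd.DataFrame] = None
        self._genus_table: Optional[GenusTable] = None
        self._genus_norm: Optional[pd.DataFrame] = None
        self._reports: List[str] = []

    # -- stage: simulate ---------------------------------------------------

    def simulate(self) -> None:
        cfg = self.cfg
        sim = self.out / "simulate"
        (sim / "reads").mkdir(parents=True, exist_ok=True)
        params = TruthParams()
        truth = generate_truth(cfg.n_hosts, params, seed=cfg.seed)
        panel = default_panel(cfg.n_16s, cfg.n_18s, seed=cfg.seed + 101)
        rparams = ReadParams(
            depth=cfg.depth,
            substitution_rate=cfg.substitution_rate,
            chimera_rate=cfg.chimera_rate,
            amplicons_per_genus=cfg.amplicons_per_genus,
        )
        reads = generate_reads(truth, panel, rparams, seed=cfg.seed + 202)
        coprology = generate_coprology(truth, seed=cfg.seed + 303)
        refs, lineages = generate_reference_db(
            truth.lineages, seed=cfg.seed + 404, sequences=truth.references
        )

        write_tsv(panel.to_frame(), sim / "panel.tsv")
        write_tsv(truth.metadata_frame(), sim / "metadata.tsv")
        write_tsv(coprology, sim / "coprology.tsv")
        write_fasta(sim / "reference.fasta", refs)
        write_tsv(lineages, sim / "reference_lineages.tsv")
        abundance = truth.abundance.copy()
        abundance.index.name = "genus"
        write_tsv(abundance.reset_index(), sim / "truth_abundance.tsv")
        write_tsv(reads.labels, sim / "read_labels.tsv")
        reps = pd.DataFrame(
            [
                {
                    "replicate": r,
                    "sample": s,
                    "is_water": r in truth.water_controls,
                }
                for r, s in sorted(truth.replicate_map.items())
            ]
        )
        write_tsv(reps, sim / "replicates.tsv")
        for rep, pairs in sorted(reads.reads.items()):
            write_paired_fastq(
                sim / "reads" / f"{rep}_R1.fastq",
                sim / "reads" / f"{rep}_R2.fastq",
                pairs,
            )
        self.truth = truth
        self._reads = reads.reads
        roles = pd.DataFrame(
            sorted(truth.roles.items()), columns=["phylum", "role"]
        )
        write_tsv(roles, sim / "roles.tsv")

    # -- input loading -----------------------------------------------------

    def _paths(self) -> Dict[str, Path]:
        cfg = self.cfg
        if cfg.simulate:
            sim = self.out / "simulate"
            return {
                "reads_dir": sim / "reads",
                "panel": sim / "panel.tsv",
                "metadata": sim / "metadata.tsv",
                "coprology": sim / "coprology.tsv",
                "reference_fasta": sim / "reference.fasta",
                "reference_lineages": sim / "reference_lineages.tsv",
                "replicates": sim / "replicates.tsv",
                "roles": sim / "roles.tsv",
            }
        return {
            k: Path(getattr(cfg, k))
            for k in ("reads_dir", "panel", "metadata", "coprology",
                      "reference_fasta", "reference_lineages", "replicates")
        }

    def _load_panel(self) -> PrimerPanel:
        return PrimerPanel.from_frame(read_tsv(self._paths()["panel"]))

    def _load_replicates(self) -> pd.DataFrame:
        return read_tsv(self._paths()["replicates"])

    def _load_reads(self) -> Dict[str, List[ReadPair]]:
        if self._reads is not None:
            return self._reads
        reads_dir = self._paths()["reads_dir"]
        out: Dict[str, List[ReadPair]] = {}
        for r1 in sorted(reads_dir.glob("*_R1.fastq*")):
            rep = r1.name.split("_R1.fastq")[0]
            r2 = Path(str(r1).replace("_R1.fastq", "_R2.fastq"))
            out[rep] = read_paired_fastq(r1, r2)
        if not out:
            raise ValueError(f"no paired FASTQ files under {reads_dir}")
        self._reads = out
        return out

    def _load_roles(self) -> Dict[str, str]:
        p = self._paths().get("roles")
        if p is not None and Path(p).exists():
            df = read_tsv(p)
            return dict(zip(df["phylum"], df["role"]))
        from .study_data import DEFAULT_ROLE_MAP
        return dict(DEFAULT_ROLE_MAP)

    # -- stage: demux (filter + stratify) ------------------------------------

    def demux(self) -> None:
        cfg = self.cfg
        reads = self._load_reads()
        panel = self._load_panel()
        filtered: Dict[str, List[ReadPair]] = {}
        stats_rows = []
        for rep, pairs in sorted(reads.items()):
            kept = []
            for p in pairs:
                res = read_prep.quality_filter(
                    p,
                    trunc_len=(cfg.trunc_len, cfg.trunc_len),
                    max_ee=(cfg.max_ee, cfg.max_ee),
                    trunc_q=cfg.trunc_q,
                )
                if res.kept:
                    kept.append(res.pair)
            filtered[rep] = kept
            stats_rows.append(
                {"replicate": rep, "input": len(pairs), "passed": len(kept)}
            )
        matrix = read_prep.stratify_by_primer(filtered, panel)
        out = self.out / "demux"
        out.mkdir(parents=True, exist_ok=True)
        counts = matrix.counts()
        counts.index.name = "replicate"
        write_tsv(counts.reset_index(), out / "amplicon_counts.tsv")
        write_tsv(pd.DataFrame(stats_rows), out / "filter_stats.tsv")
        # per-amplicon FASTQ pairs; read ids carry the replicate
        by_amp: Dict[str, List[ReadPair]] = {}
        for (rep, amp), plist in matrix.pairs.items():
            by_amp.setdefault(amp, []).extend(
                ReadPair(f"{rep}::{p.id}", p.seq1, p.seq2, p.qual1, p.qual2)
                for p in plist
            )
        for amp, plist in sorted(by_amp.items()):
            plist.sort(key=lambda p: p.id)
            write_paired_fastq(
                out / f"{amp}_R1.fastq", out / f"{amp}_R2.fastq", plist
            )
        self._amplicon_matrix = matrix
        self._reports.append("demux/amplicon_counts.tsv")

    def _load_amplicon_pairs(self) -> Dict[Tuple[str, str], List[ReadPair]]:
        if self._amplicon_matrix is not None:
            return self._amplicon_matrix.pairs
        out = self.out / "demux"
        pairs: Dict[Tuple[str, str], List[ReadPair]] = {}
        for r1 in sorted(out.glob("*_R1.fastq")):
            amp = r1.name.split("_R1.fastq")[0]
            r2 = out / f"{amp}_R2.fastq"
            for p in read_paired_fastq(r1, r2):
                rep, rid = p.id.split("::", 1)
                pairs.setdefault((rep, amp), []).append(
                    ReadPair(rid, p.seq1, p.seq2, p.qual1, p.qual2)
                )
        if not pairs:
            raise ValueError("no demultiplexed reads found; run demux first")
        return pairs

    # -- stage: denoise -------------------------------------------------------

    def denoise(self) -> None:
        cfg = self.cfg
        pairs = self._load_amplicon_pairs()

        def denoiser(counts):
            return infer_rsvs(counts, d_max=cfg.d_max, skew=cfg.skew)

        table = build_rsv_table(pairs, denoiser=denoiser)
        table, flagged = remove_bimeras(table)
        out = self.out / "denoise"
        out.mkdir(parents=True, exist_ok=True)
        rsv_table_to_tsv(table, out / "rsv_table.tsv")
        write_fasta(
            out / "rsv.fasta",
            [
                (f"rsv{i + 1:05d}", seq)
                for i, (_amp, seq) in enumerate(table.table.index)
            ],
        )
        pd.DataFrame(
            sorted(flagged), columns=["amplicon_id", "sequence"]
        ).to_csv(out / "bimeras.tsv", sep="\t", index=False)
        self._rsv_table = table
        self._reports.append("denoise/rsv_table.tsv")

    def _load_rsv_table(self) -> RSVTable:
        if self._rsv_table is None:
            self._rsv_table = rsv_table_from_tsv(
                self.out / "denoise" / "rsv_table.tsv"
            )
        return self._rsv_table

    # -- stage: qc -----------------------------------------------------------

    def qc(self) -> None:
        reps = self._load_replicates()
        is_water = dict(zip(reps["replicate"], reps["is_water"]))
        rep_to_sample = dict(zip(reps["replicate"], reps["sample"]))
        counts = read_tsv(self.out / "demux" / "amplicon_counts.tsv").set_index(
            "replicate"
        )
        failed = qc.flag_failed_replicates(counts, is_water)
        rsv_table = self._load_rsv_table()
        water = {r for r, w in is_water.items() if w}
        sample_table = qc.collapse_replicates(
            rsv_table, rep_to_sample, failed, water
        )
        normalized, factors = qc.median_scale(sample_table.table)
        out = self.out / "qc"
        out.mkdir(parents=True, exist_ok=True)
        report = counts.sum(axis=1).rename("total_reads").to_frame()
        report["is_water"] = [is_water.get(r, False) for r in report.index]
        report["flagged"] = [r in failed for r in report.index]
        report.index.name = "replicate"
        write_tsv(report.reset_index(), out / "qc_report.tsv")
        rsv_table_to_tsv(sample_table, out / "sample_rsv_table.tsv")
        norm = RSVTable(normalized)
        rsv_table_to_tsv(norm, out / "normalized_rsv_table.tsv")
        write_tsv(
            factors.rename("factor").to_frame().reset_index(names="sample"),
            out / "scaling_factors.tsv",
        )
        self._sample_table = sample_table
        self._normalized = normalized
        self._reports.append("qc/qc_report.tsv")

    def _load_sample_table(self) -> RSVTable:
        if self._sample_table is None:
            self._sample_table = rsv_table_from_tsv(
                self.out / "qc" / "sample_rsv_table.tsv"
            )
        return self._sample_table

    # -- stage: taxonomy -------------------------------------------------------

    def taxonomy(self) -> None:
        cfg = self.cfg
        paths = self._paths()
        refs = read_fasta(paths["reference_fasta"])
        lineages = read_tsv(paths["reference_lineages"])
        model = taxonomy.train_classifier(refs, lineages, k=cfg.k)
        sample_table = self._load_sample_table()
        panel = self._load_panel()
        targets = {e.amplicon_id: e.target for e in panel}
        assignments = {}
        rows = []
        for i, key in enumerate(sample_table.table.index):
            amp, seq = key
            asg = taxonomy.classify(
                seq, model, n_bootstrap=cfg.n_bootstrap,
                min_boot=cfg.min_boot, seed=cfg.seed + 505 + i,
            )
            assignments[key] = asg
            rows.append(
                {
                    "amplicon_id": amp,
                    "sequence": seq[:32] + "...",
                    **dict(zip(taxonomy.LEVELS, asg.lineage)),
                    **{f"boot_{k}": v for k, v in asg.bootstrap.items()},
                }
            )
        roles = self._load_roles()
        genus_table = taxonomy.agglomerate_genus(
            sample_table, assignments, targets, roles
        )
        norm_counts, _ = qc.median_scale(genus_table.counts)
        out = self.out / "taxonomy"
        out.mkdir(parents=True, exist_ok=True)
        write_tsv(pd.DataFrame(rows), out / "assignments.tsv")
        genus_table_to_tsv(genus_table, out / "genus_table.tsv")
        genus_table_to_tsv(
            GenusTable(norm_counts, genus_table.meta),
            out / "genus_table_normalized.tsv",
        )
        phylum_rows = genus_table.phylum_rows()
        summary, totals = taxonomy.summarize_phyla(phylum_rows, roles)
        write_tsv(summary, out / "phylum_summary.tsv")
        write_tsv(totals, out / "domain_totals.tsv")
        self._genus_table = genus_table
        self._genus_norm = norm_counts
        self._reports.append("taxonomy/genus_table.tsv")

    def _load_genus_table(self) -> GenusTable:
        if self._genus_table is None:
            self._genus_table = genus_table_from_tsv(
                self.out / "taxonomy" / "genus_table.tsv"
            )
        return self._genus_table

    def _load_genus_norm(self) -> pd.DataFrame:
        if self._genus_norm is None:
            self._genus_norm = genus_table_from_tsv(
                self.out / "taxonomy" / "genus_table_normalized.tsv"
            ).counts
        return self._genus_norm

    def _load_lineages(self) -> Dict[str, Tuple[str, str, str, str, str]]:
        df = read_tsv(self._paths()["reference_lineages"])
        return {
            str(row["genus"]): (
                str(row["phylum"]), str(row["class"]), str(row["order"]),
                str(row["family"]), str(row["genus"]),
            )
            for _, row in df.iterrows()
        }

    # -- stage: coprology -------------------------------------------------------

    def coprology(self) -> None:
        gt = self._load_genus_table()
        norm = self._load_genus_norm()
        gtn = GenusTable(norm, gt.meta)
        table = read_tsv(self._paths()["coprology"])
        lineages = self._load_lineages()
        morphs = sorted(table["morphotype"].unique())
        totals = pd.concat(
            [
                copro.combine_size_classes(table, m).rename("epg").reset_index()
                .assign(morphotype=m)
                for m in morphs
            ],
            ignore_index=True,
        )
        screen = copro.correlation_screen(totals, gtn, lineages)
        out = self.out / "coprology"
        out.mkdir(parents=True, exist_ok=True)
        loglog_rows = []
        for morph, res in sorted(screen.items()):
            write_tsv(res.entries, out / f"screen_{morph}.tsv")
            if len(res.entries):
                best = res.entries.iloc[0]["node"]
                node_counts = copro.hierarchical_counts(gtn, lineages)[best]
                epg = totals[totals["morphotype"] == morph].set_index("sample")[
                    "epg"
                ]
                shared = sorted(set(epg.index) & set(node_counts.index))
                model = copro.fit_loglog(
                    epg.loc[shared], node_counts.loc[shared]
                )
                loglog_rows.append(
                    {
                        "morphotype": morph, "node": best,
                        "intercept": model.intercept, "slope": model.slope,
                        "r_squared": model.r_squared, "n": model.n,
                    }
                )
        write_tsv(pd.DataFrame(loglog_rows), out / "loglog_models.tsv")
        summary_in = totals.rename(columns={"morphotype": "taxon"})
        n_samples = totals["sample"].nunique()
        write_tsv(
            copro.summarize_parasites(summary_in, n_samples),
            out / "parasite_summary.tsv",
        )
        self._reports.append("coprology/loglog_models.tsv")

    # -- stage: diversity -------------------------------------------------------

    def diversity(self) -> None:
        gt = self._load_genus_table()
        meta = read_tsv(self._paths()["metadata"])
        out = self.out / "diversity"
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for domain, factor in (("16S", "age"), ("18S", "rank")):
            sub = gt.subset_domain(domain)
            if sub.counts.empty:
                continue
            totals = sub.counts.sum(axis=0)
            keep = totals.index[totals > 0]
            counts = sub.counts[keep]
            rare = qc.rarefy(counts, seed=self.cfg.seed + 606)
            div = dv.diversity_frame(rare)
            div.insert(0, "domain", domain)
            write_tsv(div.reset_index(), out / f"diversity_{domain}.tsv")
            gt_r = GenusTable(rare, sub.meta)
            for scope in ("all", "per-phylum"):
                try:
                    results = dv.compare_groups(gt_r, meta, factor, scope)
                except ValueError as exc:
                    logger.warning("diversity %s/%s skipped: %s",
                                   domain, factor, exc)
                    continue
                for r in results:
                    rows.append(
                        {
                            "domain": domain, "factor": factor,
                            "scope": r.scope, "measure": r.measure,
                            "U": r.U, "n1": r.n1, "n2": r.n2, "p": r.p,
                        }
                    )
        write_tsv(pd.DataFrame(rows), out / "group_tests.tsv")
        self._reports.append("diversity/group_tests.tsv")

    # -- stage: composition -------------------------------------------------------

    def composition(self) -> None:
        cfg = self.cfg
        gt = self._load_genus_table()
        norm = self._load_genus_norm()
        meta = read_tsv(self._paths()["metadata"]).set_index("host_id")
        out = self.out / "composition"
        out.mkdir(parents=True, exist_ok=True)
        enrichment_rows = []
        for domain, factor, col in (
            ("16S", "age", "age_class"), ("18S", "rank", "rank_class"),
        ):
            keep = gt.meta.index[gt.meta["domain"] == domain]
            x = comp.log10_1p(norm.loc[keep].T.to_numpy())
            samples = list(norm.columns)
            labels = [
                str(meta.loc[s, col]) if s in meta.index else ""
                for s in samples
            ]
            row_sums = x.sum(axis=1)
            ok = [i for i, lab in enumerate(labels)
                  if lab not in ("", "nan", "None") and row_sums[i] > 0]
            if len(ok) < 4:
                continue
            xs = x[ok]
            ys = [labels[i] for i in ok]
            d = comp.bray_curtis(xs)
            ord_res = comp.nmds(d, k=2, n_restarts=10, seed=cfg.seed + 707)
            coords = pd.DataFrame(
                ord_res.coords, columns=["dim1", "dim2"],
                index=[samples[i] for i in ok],
            )
            coords["group"] = ys
            coords["stress"] = ord_res.stress
            coords.index.name = "sample"
            write_tsv(coords.reset_index(), out / f"nmds_{domain}_{factor}.tsv")
            if len(set(ys)) == 2:
                pls = comp.pls_da(xs, ys, max_axes=cfg.max_axes)
                load_df = pd.DataFrame(
                    pls.loadings,
                    index=keep,
                    columns=[f"axis{a + 1}" for a in range(pls.n_axes)],
                )
                load_df.index.name = "genus"
                write_tsv(
                    load_df.reset_index(), out / f"pls_loadings_{factor}.tsv"
                )
                cv = pd.DataFrame(
                    sorted(pls.cv_accuracy.items()),
                    columns=["n_axes", "loo_accuracy"],
                )
                cv["retained"] = cv["n_axes"] == pls.n_axes
                write_tsv(cv, out / f"pls_cv_{factor}.tsv")
                if len(keep) >= 8:
                    n_comb = 2 if pls.n_axes >= 2 else 1
                    enr = comp.loading_enrichment(
                        pls.loadings,
                        list(gt.meta.loc[keep, "phylum"]),
                        n_axes_combine=n_comb,
                    )
                    for e in enr:
                        enrichment_rows.append(
                            {
                                "domain": domain, "factor": factor,
                                "phylum": e.phylum,
                                "a": e.table[0], "b": e.table[1],
                                "c": e.table[2], "d": e.table[3],
                                "odds_ratio": e.odds_ratio, "p": e.p,
                            }
                        )
        write_tsv(pd.DataFrame(enrichment_rows), out / "enrichment.tsv")
        self._reports.append("composition/enrichment.tsv")

    # -- stage: diffabund -------------------------------------------------------

    def diffabund(self) -> None:
        gt = self._load_genus_table()
        meta = read_tsv(self._paths()["metadata"])
        out = self.out / "diffabund"
        out.mkdir(parents=True, exist_ok=True)
        for factor in ("age", "rank"):
            try:
                df = da.differential_abundance(
                    gt.counts, meta, factor, phylum_of=gt.meta["phylum"]
                )
            except ValueError as exc:
                logger.warning("diffabund %s skipped: %s", factor, exc)
                continue
            df["significant"] = df["fdr"] < self.cfg.fdr_threshold
            write_tsv(df, out / f"diffabund_{factor}.tsv")
            self._reports.append(f"diffabund/diffabund_{factor}.tsv")

    # -- driver ------------------------------------------------------------

    def run(self, stages: Optional[List[str]] = None) -> Dict[str, str]:
        self.cfg.validate()
        stages = list(stages or STAGES)
        if not self.cfg.simulate and "simulate" in stages:
            stages.remove("simulate")
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            logger.info("running stage %s", stage)
            try:
                getattr(self, stage)()
            except Exception as exc:  # halt with stage name and cause
                raise StageError(stage, exc) from exc
        manifest = self._write_manifest(stages)
        return manifest

    def _write_manifest(self, stages: List[str]) -> Dict[str, str]:
        checksums = {}
        for rel in sorted(set(self._reports)):
            path = self.out / rel
            if path.exists():
                checksums[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest = {
            "seed": self.cfg.seed,
            "config_hash": self.cfg.digest(),
            "stages": stages,
            "report_checksums": checksums,
        }
        self.out.mkdir(parents=True, exist_ok=True)
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def run_pipeline(
    config: PipelineConfig, stages: Optional[List[str]] = None
) -> Dict[str, str]:
    """Run the pipeline end to end (or a subset of stages) and return the
    manifest."""
    return Pipeline(config).run(stages)
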