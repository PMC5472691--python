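"""Host metadata rules and the synthetic-data generator contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyenabiome.coprology import fit_loglog
from hyenabiome.study_data import (
    CoprologyCoupling,
    HostMetadata,
    ReadParams,
    SyntheticTruth,
    TruthParams,
    classify_host,
    default_panel,
    generate_coprology,
    generate_reads,
    generate_reference_db,
    generate_truth,
    standardize_ranks,
    revcomp,
)


class TestStandardizeRanks:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (3, [1.0, 0.0, -1.0]),
            (5, [1.0, 0.5, 0.0, -0.5, -1.0]),
            (4, [1.0, 1.0 / 3, -1.0 / 3, -1.0]),
        ],
    )
    def test_even_spacing(self, n, expected):
        hosts = [f"h{i}" for i in range(n)]
        ranks = standardize_ranks(hosts)
        assert np.allclose([ranks[h] for h in hosts], expected)

    def test_single_host_scores_zero(self):
        assert standardize_ranks(["only"]) == {"only": 0.0}

    def test_duplicate_host_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            standardize_ranks(["a", "b", "a"])

    @given(st.integers(min_value=2, max_value=60))
    @settings(deadline=None)
    def test_symmetric_about_zero(self, n):
        hosts = [f"h{i}" for i in range(n)]
        ranks = standardize_ranks(hosts)
        vals = [ranks[h] for h in hosts]
        assert np.allclose(vals, [-v for v in reversed(vals)])
        assert vals[0] == 1.0 and vals[-1] == -1.0


class TestClassifyHost:
    @pytest.mark.parametrize(
        "age, expected", [(23.9, "juvenile"), (24.0, "adult"), (0.0, "juvenile")]
    )
    def test_age_boundary(self, age, expected):
        assert classify_host(age)[0] == expected

    def test_rank_zero_is_high(self):
        assert classify_host(30, 0.0)[1] == "high"
        assert classify_host(30, -0.01)[1] == "low"

    def test_rank_class_absent_without_rank(self):
        assert classify_host(10, None)[1] is None

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            classify_host(-1)
        with pytest.raises(ValueError):
            HostMetadata("h", -2.0)


class TestGenerateTruth:
    def test_same_seed_identical(self):
        t1 = generate_truth(8, seed=5)
        t2 = generate_truth(8, seed=5)
        pd.testing.assert_frame_equal(t1.abundance, t2.abundance)
        assert t1.failed_replicates == t2.failed_replicates

    def test_null_effects_give_equal_richness(self):
        params = TruthParams(age_effect_bacteria=0, rank_effect_eukaryote=0)
        truth = generate_truth(12, params, seed=3)
        bact = [g for g, d in truth.domains.items() if d == "16S"]
        rich = (truth.abundance.loc[bact] > 0).sum(axis=0)
        assert rich.nunique() == 1  # every host draws exactly base richness

    def test_age_effect_monte_carlo(self):
        """Adults' mean observed bacterial richness exceeds juveniles' in at
        least 95% of generator runs with a +10 genus effect."""
        params = TruthParams(age_effect_bacteria=10)
        wins = 0
        n_runs = 200
        for seed in range(n_runs):
            truth = generate_truth(40, params, seed=seed)
            bact = [g for g, d in truth.domains.items() if d == "16S"]
            rich = (truth.abundance.loc[bact] > 0).sum(axis=0)
            meta = truth.metadata_frame().set_index("host_id")
            adults = rich[meta["age_class"] == "adult"].mean()
            juv = rich[meta["age_class"] == "juvenile"].mean()
            wins += adults > juv
        assert wins / n_runs >= 0.95

    def test_negative_richness_rejected(self):
        with pytest.raises(ValueError, match="richness"):
            generate_truth(6, TruthParams(age_effect_bacteria=-30), seed=0)

    def test_water_and_failed_disjoint(self, small_truth):
        assert not (small_truth.failed_replicates & small_truth.water_controls)


class TestGenerateReads:
    def test_no_noise_reads_equal_template_with_primer(
        self, small_truth, small_panel, clean_reads
    ):
        entry = {e.amplicon_id: e for e in small_panel}
        labeled = clean_reads.labels.set_index(["replicate", "read_id"])
        rep = sorted(clean_reads.reads)[0]
        for pair in clean_reads.reads[rep][:20]:
            lab = labeled.loc[(rep, pair.id)]
            e = entry[lab["amplicon_id"]]
            genus = lab["template_id"].split("|")[0]
            tmpl = clean_reads.templates[(genus, lab["amplicon_id"])]
            assert pair.seq1 == e.fwd_primer + tmpl[: 250 - len(e.fwd_primer)]
            assert pair.seq2 == e.rev_primer + revcomp(tmpl)[: 250 - len(e.rev_primer)]

    def test_depth_conservation(self, small_truth, clean_reads):
        ordinary = [
            r for r in small_truth.replicate_map
            if r not in small_truth.water_controls
            and r not in small_truth.failed_replicates
        ]
        for rep in ordinary:
            assert len(clean_reads.reads[rep]) == clean_reads.params.depth

    def test_every_nonchimeric_read_maps_to_one_template(self, clean_reads):
        labs = clean_reads.labels
        clean = labs[~labs["is_chimera"]]
        keys = set(clean_reads.templates)
        for tid in clean["template_id"].unique():
            genus, amp = tid.split("|")
            assert (genus, amp) in keys

    def test_chimera_rate_within_binomial_bounds(self, small_panel):
        truth = generate_truth(4, TruthParams(n_juveniles=1), seed=9)
        params = ReadParams(depth=2000, chimera_rate=0.05,
                            amplicons_per_genus=8)
        reads = generate_reads(truth, small_panel, params, seed=10)
        labs = reads.labels
        ordinary = labs[~labs["is_water"]]
        n = len(ordinary)
        frac = ordinary["is_chimera"].mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < half + 0.003  # allow for missing partners

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            ReadParams(depth=0)

    def test_determinism(self, small_truth, small_panel):
        params = ReadParams(depth=50, substitution_rate=0.01, chimera_rate=0.05)
        r1 = generate_reads(small_truth, small_panel, params, seed=77)
        r2 = generate_reads(small_truth, small_panel, params, seed=77)
        rep = sorted(r1.reads)[0]
        assert [p.seq1 for p in r1.reads[rep]] == [p.seq1 for p in r2.reads[rep]]
        pd.testing.assert_frame_equal(r1.labels, r2.labels)


def _manual_truth(abundances: dict, seed=0) -> SyntheticTruth:
    """Minimal truth object carrying only an abundance matrix."""
    ab = pd.DataFrame(abundances)
    return SyntheticTruth(
        abundance=ab, hosts=[], lineages={}, domains={}, roles={},
        references={}, replicate_map={}, failed_replicates=set(),
        water_controls=set(), couplings=[], params=TruthParams(), seed=seed,
    )


class TestGenerateCoprology:
    def test_decoupled_when_slope_zero(self):
        rng = np.random.default_rng(0)
        samples = {f"s{i}": {"Ancylostoma": v}
                   for i, v in enumerate(rng.lognormal(4, 2, size=120))}
        truth = _manual_truth(samples)
        coup = CoprologyCoupling("egg", ("Ancylostoma",), a=2.0, b=0.0,
                                 dispersion=0.05)
        table = generate_coprology(truth, [coup], seed=1)
        epg = table.groupby("sample")["epg"].sum()
        ab = truth.abundance.loc["Ancylostoma", epg.index]
        corr = np.corrcoef(np.log10(1 + ab), np.log10(1 + epg))[0, 1]
        assert abs(corr) < 0.3

    def test_zero_abundance_zero_intercept_gives_zero_counts(self):
        truth = _manual_truth({"s1": {"Ancylostoma": 0.0},
                               "s2": {"Ancylostoma": 0.0}})
        coup = CoprologyCoupling("egg", ("Ancylostoma",), a=0.0, b=1.0)
        table = generate_coprology(truth, [coup], seed=2)
        assert (table[["c1", "c2", "c3", "c4"]].to_numpy() == 0).all()
        assert (table["epg"] == 0).all()

    def test_slope_recovery_low_noise(self):
        """With unit slope and vanishing overdispersion the fitted log-log
        slope recovers 1 within +/-0.05 at n = 200."""
        rng = np.random.default_rng(3)
        # intensities well above the McMaster detection limit (25 epg per
        # counted egg), as in the study's helminth loads
        ab = rng.lognormal(8, 1.5, size=200)
        truth = _manual_truth(
            {f"s{i}": {"Ancylostoma": v} for i, v in enumerate(ab)}
        )
        coup = CoprologyCoupling("egg", ("Ancylostoma",), a=0.0, b=1.0,
                                 dispersion=0.0)
        table = generate_coprology(truth, [coup], seed=4)
        epg = table.groupby("sample")["epg"].sum()
        model = fit_loglog(epg.to_numpy(),
                           truth.abundance.loc["Ancylostoma", epg.index])
        assert 0.95 <= model.slope <= 1.05

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            CoprologyCoupling("egg", ("A",), dispersion=-1.0)


class TestGenerateReferenceDb:
    def test_fixed_seed_identical(self, small_truth):
        r1, _ = generate_reference_db(small_truth.lineages, seed=8)
        r2, _ = generate_reference_db(small_truth.lineages, seed=8)
        assert r1 == r2

    def test_pairwise_shared_kmers_low(self):
        lineages = {
            f"g{i}": (f"p{i % 2}", "c", "o", "f", f"g{i}") for i in range(10)
        }
        records, _ = generate_reference_db(
            lineages, seed=3, max_shared_kmer_fraction=0.05
        )
        kmers = [
            {s[i:i + 8] for i in range(len(s) - 7)} for _, s in records
        ]
        for i in range(len(kmers)):
            for j in range(i + 1, len(kmers)):
                assert len(kmers[i] & kmers[j]) / len(kmers[i]) < 0.05

    def test_empty_lineages_rejected(self):
        with pytest.raises(ValueError):
            generate_reference_db({}, seed=0)
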