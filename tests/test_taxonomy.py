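"""Naive-Bayes classifier, genus agglomeration and phylum accounting."""

import numpy as np
import pandas as pd
import pytest

from hyenabiome.denoise import RSVTable
from hyenabiome.study_data import DEFAULT_ROLE_MAP
from hyenabiome.taxonomy import (
    UNDEFINED,
    GenusTable,
    LineageAssignment,
    agglomerate_genus,
    classify,
    summarize_phyla,
    train_classifier,
)


def _lineage_frame(rows):
    return pd.DataFrame(
        rows, columns=["seq_id", "phylum", "class", "order", "family", "genus"]
    )


def _random_seq(rng, n=400):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def four_genus_model():
    rng = np.random.default_rng(42)
    refs = [(f"g{i}_ref", _random_seq(rng)) for i in range(4)]
    lin = _lineage_frame(
        [
            (f"g{i}_ref", f"P{i}", f"C{i}", f"O{i}", f"F{i}", f"G{i}")
            for i in range(4)
        ]
    )
    return train_classifier(refs, lin, k=8), refs


class TestTrainClassifier:
    def test_self_classification_disjoint_genera(self, four_genus_model):
        model, refs = four_genus_model
        for i, (_, seq) in enumerate(refs):
            asg = classify(seq, model, seed=7)
            assert asg.level("genus") == f"G{i}"
            assert all(v == 1.0 for v in asg.bootstrap.values())

    def test_duplicate_references_equal_deduplicated_model(self):
        rng = np.random.default_rng(1)
        s1, s2 = _random_seq(rng), _random_seq(rng)
        lin = _lineage_frame(
            [
                ("a1", "P1", "C", "O", "F", "GA"),
                ("a2", "P1", "C", "O", "F", "GA"),
                ("b1", "P2", "C", "O", "F", "GB"),
            ]
        )
        dup = train_classifier([("a1", s1), ("a2", s1), ("b1", s2)], lin)
        dedup = train_classifier([("a1", s1), ("b1", s2)], lin)
        assert np.allclose(dup.log_prob, dedup.log_prob)
        assert np.allclose(dup.log_floor, dedup.log_floor)

    def test_unseen_word_floor_matches_formula(self, four_genus_model):
        model, _ = four_genus_model
        n_refs = 4
        expected = np.log((0.5 / (n_refs + 1)) / (1 + 1))  # M(g) = 1 per genus
        assert np.allclose(model.log_floor, expected)

    def test_genus_without_sequence_rejected(self):
        lin = _lineage_frame(
            [("a", "P1", "C", "O", "F", "GA"), ("b", "P2", "C", "O", "F", "GB")]
        )
        with pytest.raises(ValueError):
            train_classifier([("a", "ACGTACGTACGT")], lin)


class TestClassify:
    def test_no_shared_kmers_all_undefined(self, four_genus_model):
        model, refs = four_genus_model
        # a sequence sharing no k-mer with any reference: scores reduce to
        # the unseen-word floor and bootstrap winners split across genera
        query = "GT" * 200
        assert all("GTGTGTGT" not in seq for _, seq in refs)
        asg = classify(query, model, seed=11)
        assert asg.lineage == (UNDEFINED,) * 5

    def test_fifty_fifty_concatenation_splits_genus_confidence(
        self, four_genus_model
    ):
        model, refs = four_genus_model
        # g0 (phylum P0) and g1 (phylum P1) contribute half the words each
        query = refs[0][1][:200] + refs[1][1][:200]
        asg = classify(query, model, seed=13)
        assert asg.bootstrap["genus"] < 0.9
        assert asg.level("genus") == UNDEFINED or asg.bootstrap["genus"] >= 0.5

    def test_no_valid_word_rejected(self, four_genus_model):
        model, _ = four_genus_model
        with pytest.raises(ValueError):
            classify("NNNNNNNNNNNN", model)

    def test_deterministic_given_seed(self, four_genus_model):
        model, refs = four_genus_model
        query = refs[2][1][:120] + refs[3][1][:120]
        a1 = classify(query, model, seed=5)
        a2 = classify(query, model, seed=5)
        assert a1.lineage == a2.lineage and a1.bootstrap == a2.bootstrap

    def test_confidence_monotone_phylum_to_genus(self, four_genus_model):
        model, refs = four_genus_model
        query = refs[0][1][:250] + refs[2][1][:150]
        asg = classify(query, model, seed=17)
        conf = [asg.bootstrap[l] for l in
                ("phylum", "class", "order", "family", "genus")]
        assert all(a >= b - 1e-12 for a, b in zip(conf, conf[1:]))


def _asg(phylum, genus, boot=1.0):
    return LineageAssignment(
        (phylum, "C", "O", "F", genus),
        {l: boot for l in ("phylum", "class", "order", "family", "genus")},
    )


def _rsv_table(entries):
    idx = pd.MultiIndex.from_tuples(
        [k for k, _ in entries], names=["amplicon_id", "sequence"]
    )
    return RSVTable(pd.DataFrame([v for _, v in entries], index=idx))


class TestAgglomerate:
    def test_counts_summed_across_amplicons(self):
        table = _rsv_table(
            [
                (("amp1", "AAAA"), {"s1": 3}),
                (("amp2", "CCCC"), {"s1": 4}),
                (("amp1", "GGGG"), {"s1": 9}),
            ]
        )
        assignments = {
            ("amp1", "AAAA"): _asg("P1", "GA"),
            ("amp2", "CCCC"): _asg("P1", "GA"),
            ("amp1", "GGGG"): _asg("P1", "GB"),
        }
        gt = agglomerate_genus(
            table, assignments, {"amp1": "16S", "amp2": "16S"}
        )
        assert gt.counts.loc["GA", "s1"] == 7
        assert gt.counts.loc["GB", "s1"] == 9

    def test_sole_genus_of_phylum_dropped(self):
        table = _rsv_table(
            [
                (("amp1", "AAAA"), {"s1": 3}),
                (("amp1", "CCCC"), {"s1": 4}),
                (("amp1", "GGGG"), {"s1": 9}),
            ]
        )
        assignments = {
            ("amp1", "AAAA"): _asg("P1", "GA"),
            ("amp1", "CCCC"): _asg("P1", "GB"),
            ("amp1", "GGGG"): _asg("P2", "GC"),  # sole genus of P2
        }
        gt = agglomerate_genus(table, assignments, {"amp1": "16S"})
        assert "GC" not in gt.counts.index
        assert set(gt.counts.index) == {"GA", "GB"}

    def test_undefined_and_uninformative_genus_excluded(self):
        table = _rsv_table(
            [
                (("amp1", "AAAA"), {"s1": 3}),
                (("amp1", "CCCC"), {"s1": 4}),
                (("amp1", "GGGG"), {"s1": 5}),
                (("amp1", "TTTT"), {"s1": 6}),
            ]
        )
        assignments = {
            ("amp1", "AAAA"): _asg("P1", UNDEFINED),
            ("amp1", "CCCC"): _asg("P1", "uncultured organism"),
            ("amp1", "GGGG"): _asg("P1", "GA"),
            ("amp1", "TTTT"): _asg("P1", "GB"),
        }
        gt = agglomerate_genus(table, assignments, {"amp1": "16S"})
        assert set(gt.counts.index) == {"GA", "GB"}

    def test_missing_assignment_rejected(self):
        table = _rsv_table([(("amp1", "AAAA"), {"s1": 3})])
        with pytest.raises(ValueError, match="missing assignment"):
            agglomerate_genus(table, {}, {"amp1": "16S"})

    def test_read_conservation_among_retained(self):
        table = _rsv_table(
            [
                (("amp1", "AAAA"), {"s1": 3, "s2": 1}),
                (("amp1", "CCCC"), {"s1": 4, "s2": 2}),
                (("amp1", "GGGG"), {"s1": 9, "s2": 5}),
            ]
        )
        assignments = {
            ("amp1", "AAAA"): _asg("P1", "GA"),
            ("amp1", "CCCC"): _asg("P1", "GB"),
            ("amp1", "GGGG"): _asg("P1", "GA"),
        }
        gt = agglomerate_genus(table, assignments, {"amp1": "16S"})
        assert gt.counts.to_numpy().sum() == table.table.to_numpy().sum()


def _table1_bacteria_rows():
    # per-phylum genus counts of the bacterial domain, with the undetermined
    # phylum carried separately
    named = {
        "Actinobacteria": 24, "Bacteroidetes": 20, "Firmicutes": 112,
        "Fusobacteria": 3, "Proteobacteria": 33, "Spirochaetes": 3,
        "Tenericutes": 6,
    }
    rows = [
        {"domain": "16S", "phylum": p, "n_genera": n} for p, n in named.items()
    ]
    rows.append({"domain": "16S", "phylum": UNDEFINED, "n_genera": 1})
    return pd.DataFrame(rows)


class TestSummarizePhyla:
    def test_bacterial_named_genus_total(self):
        """The named bacterial phyla sum to 201 identified genera; including
        the undetermined phylum gives the full 202."""
        role_map = {p: "microbiome" for p in _table1_bacteria_rows()["phylum"]}
        _, totals = summarize_phyla(_table1_bacteria_rows(), role_map)
        named = totals[(totals["domain"] == "16S") & (totals["scope"] == "named")]
        full = totals[(totals["domain"] == "16S") & (totals["scope"] == "full")]
        assert int(named["n_genera"].iloc[0]) == 201
        assert int(full["n_genera"].iloc[0]) == 202

    def test_empty_rows_give_zero_totals(self):
        empty = pd.DataFrame(columns=["domain", "phylum", "n_genera"])
        summary, totals = summarize_phyla(empty, {})
        assert totals.empty or totals["n_genera"].sum() == 0

    def test_nematoda_role_label(self):
        rows = pd.DataFrame(
            [{"domain": "18S", "phylum": "Nematoda", "n_genera": 36}]
        )
        summary, _ = summarize_phyla(rows, DEFAULT_ROLE_MAP)
        assert summary["role_label"].iloc[0] == "Eukaryome (parasites)"

    def test_named_plus_undefined_equals_full(self, rng):
        rows = []
        for d in ("16S", "18S"):
            for i in range(4):
                rows.append(
                    {"domain": d, "phylum": f"P{i}",
                     "n_genera": int(rng.integers(1, 40)),
                     "n_reads": int(rng.integers(10, 1000))}
                )
            rows.append(
                {"domain": d, "phylum": UNDEFINED,
                 "n_genera": int(rng.integers(1, 5)),
                 "n_reads": int(rng.integers(10, 100))}
            )
        df = pd.DataFrame(rows)
        summary, totals = summarize_phyla(df, {})
        for d in ("16S", "18S"):
            und = df[(df["domain"] == d) & (df["phylum"] == UNDEFINED)]
            named = totals[(totals["domain"] == d) & (totals["scope"] == "named")]
            full = totals[(totals["domain"] == d) & (totals["scope"] == "full")]
            for c in ("n_genera", "n_reads"):
                assert (
                    int(named[c].iloc[0]) + int(und[c].sum())
                    == int(full[c].iloc[0])
                )

    def test_missing_phylum_gets_undetermined_role(self):
        rows = pd.DataFrame(
            [{"domain": "18S", "phylum": "Mystery", "n_genera": 2}]
        )
        summary, _ = summarize_phyla(rows, {})
        assert summary["role"].iloc[0] == "undetermined"
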