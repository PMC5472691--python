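"""McMaster quantification, parasite summaries and the correlation screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyenabiome.coprology import (
    combine_size_classes,
    correlation_screen,
    fec_from_chambers,
    fit_loglog,
    spearman,
    summarize_parasites,
)
from hyenabiome.taxonomy import GenusTable


class TestFecFromChambers:
    @pytest.mark.parametrize(
        "counts, expected",
        [((0, 0, 0, 0), 0.0), ((1, 0, 0, 0), 25.0), ((2, 3, 1, 2), 200.0)],
    )
    def test_multiplier(self, counts, expected):
        assert fec_from_chambers(counts) == expected

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=4,
                    max_size=4))
    @settings(deadline=None)
    def test_linearity(self, counts):
        doubled = [2 * c for c in counts]
        assert fec_from_chambers(doubled) == pytest.approx(
            2 * fec_from_chambers(counts)
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fec_from_chambers((1, -1, 0, 0))

    def test_fractional_count_rejected(self):
        with pytest.raises(ValueError):
            fec_from_chambers((1.5, 0, 0, 0))


class TestCombineSizeClasses:
    def _table(self):
        return pd.DataFrame(
            [
                {"sample": "s1", "morphotype": "egg", "size_class": "small",
                 "epg": 50.0},
                {"sample": "s1", "morphotype": "egg", "size_class": "large",
                 "epg": 25.0},
                {"sample": "s2", "morphotype": "egg", "size_class": "small",
                 "epg": 0.0},
            ]
        )

    def test_sum_over_classes(self):
        totals = combine_size_classes(self._table(), "egg")
        assert totals["s1"] == 75.0
        assert totals["s2"] == 0.0

    def test_unknown_morphotype_rejected(self):
        with pytest.raises(ValueError):
            combine_size_classes(self._table(), "oocyst")


class TestSummarizeParasites:
    def test_prevalence_to_one_decimal(self):
        """26 positive of 32 samples prints as 81.2% (round half to even)."""
        rows = [
            {"taxon": "Diphyllobothriidae", "sample": f"s{i}",
             "epg": 100.0 if i < 26 else 0.0}
            for i in range(32)
        ]
        out = summarize_parasites(pd.DataFrame(rows), n_samples=32)
        assert out["prevalence"].iloc[0] == 81.2

    def test_zero_positives_all_na(self):
        rows = [{"taxon": "t", "sample": f"s{i}", "epg": 0.0} for i in range(5)]
        out = summarize_parasites(pd.DataFrame(rows), n_samples=5)
        r = out.iloc[0]
        assert r["prevalence"] == 0.0
        assert np.isnan(r["mean"]) and np.isnan(r["median"])

    def test_single_positive_mean_without_ci(self):
        rows = [
            {"taxon": "t", "sample": "s1", "epg": 50.0},
            {"taxon": "t", "sample": "s2", "epg": 0.0},
        ]
        out = summarize_parasites(pd.DataFrame(rows), n_samples=2)
        r = out.iloc[0]
        assert r["mean"] == 50.0
        assert np.isnan(r["mean_ci_low"]) and np.isnan(r["median_ci_high"])

    def test_mean_ci_floored_at_zero_with_raw_kept(self):
        rows = [
            {"taxon": "t", "sample": f"s{i}", "epg": v}
            for i, v in enumerate([25.0, 25.0, 10000.0])
        ]
        out = summarize_parasites(pd.DataFrame(rows), n_samples=3)
        r = out.iloc[0]
        assert r["mean_ci_low"] == 0.0
        assert r["mean_ci_low_raw"] < 0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize_parasites(pd.DataFrame(columns=["taxon", "epg"]), 0)


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, [2, 4, 6, 9]).rho == pytest.approx(1.0)
        assert spearman(x, [9, 6, 4, 2]).rho == pytest.approx(-1.0)

    def test_rank_difference_example(self):
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)

    def test_zero_variance_is_na(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.rho) and not res.valid


def _genus_table(counts: pd.DataFrame) -> GenusTable:
    meta = pd.DataFrame(
        {"phylum": ["Nematoda"] * len(counts), "domain": "18S",
         "role": "eukaryome_parasite"},
        index=counts.index,
    )
    return GenusTable(counts, meta)


LINEAGES = {
    "Ancylostoma": ("Nematoda", "Chromadorea", "Rhabditida",
                    "Ancylostomatidae", "Ancylostoma"),
    "Haemonchus": ("Nematoda", "Chromadorea", "Rhabditida",
                   "Haemonchidae", "Haemonchus"),
    "Trichuris": ("Nematoda", "Enoplea", "Trichocephalida",
                  "Trichuridae", "Trichuris"),
    "Noise1": ("Nematoda", "CX", "OX", "FX", "Noise1"),
    "Noise2": ("Nematoda", "CX", "OX", "FY", "Noise2"),
    "Noise3": ("Nematoda", "CZ", "OZ", "FZ", "Noise3"),
    "Noise4": ("Nematoda", "CZ", "OZ", "FW", "Noise4"),
}


class TestCorrelationScreen:
    def _fixture(self, seed=0, couple_to="Ancylostoma"):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(24)]
        counts = pd.DataFrame(
            rng.lognormal(3, 1, size=(len(LINEAGES), len(samples))).round(),
            index=sorted(LINEAGES),
            columns=samples,
        )
        epg = counts.loc[couple_to] * 2.0  # perfect monotone coupling
        copro = pd.DataFrame(
            {"sample": samples, "morphotype": "egg", "epg": epg.to_numpy()}
        )
        return _genus_table(counts), copro

    def test_coupled_taxon_or_ancestor_in_top_k(self):
        gt, copro = self._fixture()
        res = correlation_screen(copro, gt, LINEAGES)["egg"]
        targets = {"genus:Ancylostoma", "family:Ancylostomatidae",
                   "order:Rhabditida", "class:Chromadorea", "phylum:Nematoda"}
        assert targets & set(res.top_nodes())

    def test_perfect_coupling_is_rank_one(self):
        gt, copro = self._fixture()
        res = correlation_screen(copro, gt, LINEAGES)["egg"]
        assert res.entries.iloc[0]["rho"] == pytest.approx(1.0)
        assert res.entries.iloc[0]["node"] in (
            "genus:Ancylostoma", "family:Ancylostomatidae"
        )

    def test_constant_coprology_vector_excluded(self):
        gt, copro = self._fixture()
        copro["epg"] = 5.0
        res = correlation_screen(copro, gt, LINEAGES)["egg"]
        assert res.entries.empty

    def test_declared_set_sums_members(self):
        gt, copro = self._fixture()
        res = correlation_screen(
            copro, gt, LINEAGES,
            taxon_sets={"pair": ["Ancylostoma", "Haemonchus"]},
        )["egg"]
        assert "set:pair" in set(res.entries["node"])
        # the set's counts equal the elementwise sum of its members
        from hyenabiome.coprology import hierarchical_counts
        nodes = hierarchical_counts(gt, LINEAGES)
        manual = gt.counts.loc["Ancylostoma"] + gt.counts.loc["Haemonchus"]
        r_set = spearman(copro.set_index("sample")["epg"][manual.index], manual)
        row = res.entries[res.entries["node"] == "set:pair"].iloc[0]
        assert row["rho"] == pytest.approx(r_set.rho)

    def test_ranking_invariant_to_sample_order(self):
        gt, copro = self._fixture(seed=5)
        res1 = correlation_screen(copro, gt, LINEAGES)["egg"]
        res2 = correlation_screen(
            copro.iloc[::-1].reset_index(drop=True), gt, LINEAGES
        )["egg"]
        assert list(res1.entries["node"]) == list(res2.entries["node"])

    def test_no_shared_samples_rejected(self):
        gt, copro = self._fixture()
        copro["sample"] = [f"x{i}" for i in range(len(copro))]
        with pytest.raises(ValueError, match="shared"):
            correlation_screen(copro, gt, LINEAGES)


class TestFitLogLog:
    def test_exact_loglinear_data(self):
        counts = np.array([10.0, 100.0, 1000.0, 10000.0])
        epg = 10 ** (0.5 + 0.8 * np.log10(1 + counts)) - 1
        model = fit_loglog(epg, counts)
        assert model.r_squared == pytest.approx(1.0)
        assert model.slope == pytest.approx(0.8)
        assert model.intercept == pytest.approx(0.5)

    def test_constant_epg_gives_flat_fit(self):
        model = fit_loglog([0.0, 0.0, 0.0, 0.0], [1.0, 10.0, 100.0, 1000.0])
        assert model.slope == 0.0 and model.r_squared == 0.0

    def test_constant_counts_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_loglog([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
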