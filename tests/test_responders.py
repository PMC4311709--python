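"""Tests of the rare-responder classifier and its summaries."""

import numpy as np
import pandas as pd
import pytest

import rarepulse as rp
from rarepulse.exceptions import InvalidParameterError, UndefinedFractionError
from rarepulse.responders import PairedSample, RareResponderReport, report_table


def pair_from(dry, rewetted, otu_ids=None, ecosystem="E1"):
    n = len(dry)
    ids = otu_ids or [f"OTU{i + 1:03d}" for i in range(n)]
    return PairedSample(pair_id="p1", ecosystem=ecosystem, otu_ids=ids, dry=dry, rewetted=rewetted)


class TestPartition:
    def test_three_otu_exhaustive_case(self):
        pair = pair_from([5, 1, 0], [2, 0, 7], otu_ids=["A", "B", "C"])
        shared, dry_only, rewet_only = rp.partition_shared(pair)
        assert shared == {"A"}
        assert dry_only == {"B"}
        assert rewet_only == {"C"}

    def test_identical_samples_all_shared(self):
        pair = pair_from([3, 2, 1], [3, 2, 1])
        shared, dry_only, rewet_only = rp.partition_shared(pair)
        assert len(shared) == 3 and not dry_only and not rewet_only

    def test_partition_conserves_union(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            dry = rng.integers(0, 5, 20)
            wet = rng.integers(0, 5, 20)
            pair = pair_from(dry, wet)
            shared, dry_only, rewet_only = rp.partition_shared(pair)
            union = {o for o, d, w in zip(pair.otu_ids, dry, wet) if d > 0 or w > 0}
            assert shared | dry_only | rewet_only == union
            assert not (shared & dry_only or shared & rewet_only or dry_only & rewet_only)


class TestRareFractions:
    def test_hand_arithmetic_seq_fraction(self):
        pair = pair_from([3, 0], [2, 8], otu_ids=["A", "C"])
        rof, rsf = rp.rare_fractions(pair)
        assert rsf == pytest.approx(0.8)
        assert rof == pytest.approx(0.5)

    def test_no_responders(self):
        pair = pair_from([1, 2], [3, 4])
        assert rp.rare_fractions(pair) == (0.0, 0.0)

    def test_all_new(self):
        pair = pair_from([0, 0], [3, 4])
        assert rp.rare_fractions(pair) == (1.0, 1.0)

    def test_empty_rewetted_rejected(self):
        with pytest.raises(UndefinedFractionError):
            rp.rare_fractions(pair_from([1, 1], [0, 0]))

    def test_two_route_cross_check(self):
        """rare_seq_fraction equals 1 - (rewetted reads on dry-detected
        OTUs) / depth — an independent complementary computation."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            dry = rng.integers(0, 4, 30)
            wet = rng.integers(0, 6, 30)
            if wet.sum() == 0:
                continue
            pair = pair_from(dry, wet)
            _, rsf = rp.rare_fractions(pair)
            complement = wet[dry > 0].sum() / wet.sum()
            assert rsf == pytest.approx(1.0 - complement, abs=1e-12)


class TestSingletonDoubleton:
    def test_hand_case(self):
        pair = pair_from([1, 2, 5], [4, 4, 4])
        assert rp.singleton_doubleton_fraction(pair) == pytest.approx(2 / 3)

    def test_all_abundant(self):
        pair = pair_from([3, 9], [1, 1])
        assert rp.singleton_doubleton_fraction(pair) == 0.0

    def test_all_rare(self):
        pair = pair_from([1, 2], [1, 1])
        assert rp.singleton_doubleton_fraction(pair) == 1.0

    def test_empty_shared_rejected(self):
        with pytest.raises(UndefinedFractionError):
            rp.singleton_doubleton_fraction(pair_from([1, 0], [0, 1]))


class TestRankShift:
    def test_rank_swap(self):
        pair = pair_from([5, 1], [1, 5], otu_ids=["A", "B"])
        rs = rp.rank_shift(pair)
        assert rs.loc["A", "dry_rank"] == 1 and rs.loc["A", "rewet_rank"] == 2
        assert rs.loc["B", "dry_rank"] == 2 and rs.loc["B", "rewet_rank"] == 1

    def test_tie_broken_by_otu_id(self):
        pair = pair_from([3, 3], [1, 1], otu_ids=["A", "B"])
        rs = rp.rank_shift(pair)
        assert rs.loc["A", "dry_rank"] == 1
        assert rs.loc["B", "dry_rank"] == 2

    def test_undetected_flagged_unranked(self):
        pair = pair_from([0, 4], [2, 2], otu_ids=["A", "B"])
        rs = rp.rank_shift(pair)
        assert np.isnan(rs.loc["A", "dry_rank"])
        assert rs.loc["A", "rewet_rank"] in (1.0, 2.0)

    def test_ranks_form_permutation(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            dry = rng.integers(0, 6, 25)
            wet = rng.integers(0, 6, 25)
            rs = rp.rank_shift(pair_from(dry, wet))
            for col, counts in (("dry_rank", dry), ("rewet_rank", wet)):
                detected = (counts > 0).sum()
                ranks = rs[col].dropna().to_numpy()
                assert sorted(ranks) == list(range(1, detected + 1))


class TestDominantResponders:
    def test_recovery_above_threshold(self):
        dry = np.zeros(3, dtype=int)
        dry[1] = 92
        wet = np.array([8, 91, 1])
        pair = pair_from(dry, wet, otu_ids=["A", "B", "C"])
        dom = rp.dominant_responders(pair, threshold=0.01)
        assert "A" in dom.index  # 8% responder
        assert "B" not in dom.index  # shared, not a responder
        assert "C" in dom.index  # exactly 1%: inclusive threshold

    def test_threshold_inclusive_at_exact_value(self):
        pair = pair_from([0, 99], [1, 99], otu_ids=["A", "B"])
        dom = rp.dominant_responders(pair, threshold=0.01)
        assert list(dom.index) == ["A"]

    def test_no_dominant_responders(self):
        pair = pair_from([0, 5], [1, 999], otu_ids=["A", "B"])
        assert rp.dominant_responders(pair, threshold=0.01).empty

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_invalid_threshold(self, bad):
        pair = pair_from([1], [1])
        with pytest.raises(InvalidParameterError):
            rp.dominant_responders(pair, threshold=bad)


class TestTaxonomy:
    taxonomy = {
        **{f"S{i}": "Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae" for i in range(5)},
        **{f"C{i}": "Proteobacteria;Betaproteobacteria;Burkholderiales;Comamonadaceae" for i in range(3)},
        **{f"O{i}": "Proteobacteria;Betaproteobacteria;Burkholderiales;Oxalobacteraceae" for i in range(2)},
        "P0": "Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae",
        "A0": "Actinobacteria;Actinobacteria_cl;Actinomycetales;Actinobacteria_fam1",
        "B0": "Bacteroidetes;Bacteroidetes_cl;Bacteroidetes_or;Bacteroidetes_fam1",
    }

    def test_thirteen_otu_family_composition(self):
        """A 13-OTU dominant-responder set with 5/3/2 members of the three
        big families: 38/23/15% at family level, 85% Proteobacteria."""
        ids = list(self.taxonomy)
        fam = rp.taxon_composition(ids, self.taxonomy, "family")
        assert fam["Sphingomonadaceae"] == pytest.approx(5 / 13)
        assert fam["Comamonadaceae"] == pytest.approx(3 / 13)
        assert fam["Oxalobacteraceae"] == pytest.approx(2 / 13)
        phy = rp.taxon_composition(ids, self.taxonomy, "phylum")
        assert phy["Proteobacteria"] == pytest.approx(11 / 13)
        assert round(100 * phy["Proteobacteria"]) == 85

    def test_missing_taxonomy_unclassified(self):
        comp = rp.taxon_composition(["X1", "S0"], self.taxonomy, "family")
        assert comp["unclassified"] == pytest.approx(0.5)

    def test_unknown_level_rejected(self):
        with pytest.raises(InvalidParameterError):
            rp.taxon_composition(["S0"], self.taxonomy, "kingdom")

    def test_single_family_cell_equals_seq_fraction(self):
        """All responders in one family: that family's matrix entry equals
        the unit's rare sequence fraction."""
        pair = pair_from([4, 0, 0], [2, 5, 3], otu_ids=["A0", "S0", "S1"])
        _, rsf = rp.rare_fractions(pair)
        mat = rp.taxonomy_recovery_matrix([pair], self.taxonomy, level="family",
                                          contribution_floor=0.0)
        assert mat.loc["Sphingomonadaceae", "E1"] == pytest.approx(rsf)

    def test_identical_ecosystems_identical_columns(self):
        p1 = pair_from([4, 0, 0], [2, 5, 3], otu_ids=["A0", "S0", "C0"], ecosystem="E1")
        p2 = pair_from([4, 0, 0], [2, 5, 3], otu_ids=["A0", "S0", "C0"], ecosystem="E2")
        mat = rp.taxonomy_recovery_matrix([p1, p2], self.taxonomy, level="family",
                                          contribution_floor=0.0)
        np.testing.assert_allclose(mat["E1"], mat["E2"])

    def test_minor_groups_collapse_into_other(self):
        dry = np.zeros(4, dtype=int)
        wet = np.array([96, 1, 2, 1])
        pair = pair_from(dry, wet, otu_ids=["S0", "A0", "B0", "P0"])
        mat = rp.taxonomy_recovery_matrix([pair], self.taxonomy, level="family",
                                          contribution_floor=0.05)
        assert "other" in mat.index
        assert mat.loc["other", "E1"] == pytest.approx(0.04)


class TestClassifierAgainstGroundTruth:
    def test_sensitivity_increases_with_depth(self):
        """Deeper sequencing detects more truly resuscitated taxa (common
        random numbers across three depths)."""
        sens = []
        for depth in (300, 1500, 8000):
            params = rp.SeedBankParams(
                n_taxa=500, seq_depth=depth, n_ecosystems=2, n_replicates=2, seed=21
            )
            table, truth = rp.generate_paired_otu_tables(params)
            vals = []
            for pid in table.pair_ids():
                pair = PairedSample.from_table(table, pid, seed=1)
                perf = rp.classifier_performance(pair, truth.resuscitated[pid])
                vals.append(perf["sensitivity"])
            sens.append(np.mean(vals))
        assert sens[0] < sens[1] < sens[2]

    def test_null_floor_matches_analytic_multinomial_baseline(self):
        """dormant_fraction=0: the measured rare-OTU fraction equals the
        analytic multinomial missed-detection floor within Monte-Carlo
        error."""
        params = rp.SeedBankParams(
            n_taxa=400, seq_depth=800, dormant_fraction=0.0,
            n_ecosystems=4, n_replicates=3, ecosystem_effect_sd=0.0, seed=17,
        )
        measured, expected = [], []
        for seed in range(6):
            table, truth = rp.generate_paired_otu_tables(
                rp.SeedBankParams(**{**params.__dict__, "seed": seed})
            )
            for pid in table.pair_ids():
                pair = PairedSample.from_table(table, pid, rarefy_to_min=False)
                measured.append(rp.rare_fractions(pair)[0])
            p = truth.true_abundances.iloc[0].to_numpy()
            expected.append(rp.expected_null_rare_otu_fraction(p, 800, 800))
        assert min(expected) > 0.0  # the null floor is real, not hidden
        assert np.mean(measured) == pytest.approx(np.mean(expected), abs=0.02)

    def test_monotone_in_growth_factor(self):
        """Stronger growth of resuscitated taxa never lowers their sequence
        share (common random numbers)."""
        vals = []
        for gm in (np.log(2e5), np.log(2e6), np.log(2e7)):
            params = rp.SeedBankParams(
                n_taxa=500, n_ecosystems=1, n_replicates=3, growth_log_mean=gm, seed=8
            )
            table, _ = rp.generate_paired_otu_tables(params)
            vals.append(
                np.mean(
                    [
                        rp.rare_fractions(PairedSample.from_table(table, pid, seed=0))[1]
                        for pid in table.pair_ids()
                    ]
                )
            )
        assert vals[0] <= vals[1] <= vals[2]


class TestReports:
    def test_report_consistency(self):
        params = rp.SeedBankParams(n_taxa=300, seq_depth=500, n_ecosystems=2, n_replicates=2, seed=4)
        table, _ = rp.generate_paired_otu_tables(params)
        reports = []
        for pid in table.pair_ids():
            pair = PairedSample.from_table(table, pid, seed=2)
            reports.append(RareResponderReport.from_pair(pair))
        df = report_table(reports)
        assert len(df) == 4
        assert ((df["rare_otu_fraction"] >= 0) & (df["rare_otu_fraction"] <= 1)).all()
        expected = df["n_rewet_only"] / (df["n_rewet_only"] + df["n_shared"])
        np.testing.assert_allclose(df["rare_otu_fraction"], expected)

    def test_ecosystem_summary_shape(self):
        params = rp.SeedBankParams(n_taxa=200, seq_depth=300, n_ecosystems=2, n_replicates=3, seed=6)
        table, _ = rp.generate_paired_otu_tables(params)
        reports = [
            RareResponderReport.from_pair(PairedSample.from_table(table, pid, seed=2))
            for pid in table.pair_ids()
        ]
        from rarepulse.responders import summarize_by_ecosystem

        summary = summarize_by_ecosystem(reports)
        assert list(summary.index) == ["E1", "E2"]
        assert "rare_otu_fraction_mean" in summary.columns
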