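"""Tests of rarefaction, Bray-Curtis, richness and the two-factor PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import kstest

import rarepulse as rp
from rarepulse.community import (
    distance_matrix,
    observed_richness,
    pairwise_turnover,
    permanova,
    rarefy,
    rarefy_counts,
)
from rarepulse.exceptions import (
    DegenerateFactorError,
    InsufficientDepthError,
    UndefinedDistanceError,
)

from conftest import crossed_fixture, make_table


class TestRarefy:
    def test_identity_at_full_depth(self, tiny_pair_table):
        out = rarefy(tiny_pair_table, depth=6, seed=0)
        # dry sample total is 6; rewetted total 9 is subsampled
        assert out.counts.loc["u1_dry"].tolist() == [5, 1, 0]
        assert out.sample_totals().tolist() == [6, 6]

    def test_single_otu_forcing(self):
        rng = np.random.default_rng(0)
        assert rarefy_counts(np.array([10, 0]), 5, rng).tolist() == [5, 0]

    def test_hypergeometric_mean(self):
        """Sample (5, 5) rarefied to 4: first-OTU count has hypergeometric
        mean 2.0; check the Monte-Carlo mean within 4 standard errors."""
        rng = np.random.default_rng(42)
        n = 10_000
        draws = np.array([rarefy_counts(np.array([5, 5]), 4, rng)[0] for _ in range(n)])
        # Var of hypergeometric(N=10, K=5, n=4) = 4 * .5 * .5 * 6/9
        se = np.sqrt(4 * 0.25 * (6 / 9) / n)
        assert draws.mean() == pytest.approx(2.0, abs=4 * se)

    def test_depth_exceeding_total_names_sample(self, tiny_pair_table):
        with pytest.raises(InsufficientDepthError) as exc:
            rarefy(tiny_pair_table, depth=8, seed=0)
        assert "u1_dry" in str(exc.value)

    def test_deterministic_and_bounded(self):
        table = crossed_fixture(seed=3)
        a = rarefy(table, depth=400, seed=5)
        b = rarefy(table, depth=400, seed=5)
        assert a.counts.equals(b.counts)
        assert (a.counts.to_numpy() <= table.counts.to_numpy()).all()
        assert (a.sample_totals() == 400).all()


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert rp.bray_curtis([3, 2, 1], [3, 2, 1]) == 0.0

    def test_disjoint_supports(self):
        assert rp.bray_curtis([5, 0, 0], [0, 2, 7]) == 1.0

    def test_hand_arithmetic(self):
        assert rp.bray_curtis([6, 2], [2, 2]) == pytest.approx(1 - 8 / 12)

    def test_both_zero_rejected(self):
        with pytest.raises(UndefinedDistanceError):
            rp.bray_curtis([0, 0], [0, 0])

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.integers(0, 20, 15)
            y = rng.integers(0, 20, 15)
            if x.sum() + y.sum() == 0:
                continue
            assert rp.bray_curtis(x, y) == pytest.approx(
                scipy_braycurtis(x, y), abs=1e-12
            )


class TestDistanceMatrix:
    def test_matches_elementwise_oracle(self):
        table = crossed_fixture(seed=7, n_eco=2, n_rep=1, n_otu=10, depth=100)
        dm = distance_matrix(table)
        counts = table.counts.to_numpy(dtype=float)
        for i in range(len(counts)):
            for j in range(len(counts)):
                expected = 0.0 if i == j else rp.bray_curtis(counts[i], counts[j])
                assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_sample_zero_distance(self):
        table = make_table(
            {"s1": [3, 1], "s2": [3, 1]},
            [
                {"sample": "s1", "ecosystem": "E1", "treatment": "dry", "replicate": 1, "pair": "p1"},
                {"sample": "s2", "ecosystem": "E1", "treatment": "rewetted", "replicate": 1, "pair": "p1"},
            ],
        )
        assert distance_matrix(table).data[0, 1] == 0.0

    def test_sample_permutation_equivariance(self):
        table = crossed_fixture(seed=9, n_eco=2, n_rep=1, n_otu=12, depth=80)
        dm = distance_matrix(table)
        perm = list(reversed(table.sample_ids))
        dm_perm = distance_matrix(table.subset_samples(perm))
        reordered = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).loc[perm, perm]
        np.testing.assert_allclose(dm_perm.data, reordered.to_numpy())


class TestRichness:
    def test_counts_positive_entries(self):
        assert observed_richness([0, 3, 1]) == 2
        assert observed_richness([0, 0]) == 0

    def test_rarefaction_never_increases_richness(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            counts = rng.integers(0, 8, 30)
            total = counts.sum()
            if total < 5:
                continue
            sub = rarefy_counts(counts, 5, rng)
            assert observed_richness(sub) <= observed_richness(counts)


class TestPermanova:
    def test_matches_vegan_adonis2(self):
        """Frozen oracle: R vegan adonis2(d ~ ecosystem * treatment,
        by="terms") run once on this exact deterministic fixture."""
        table = crossed_fixture(seed=42)
        dm = distance_matrix(table)
        meta = table.metadata
        res = permanova(dm, meta["ecosystem"], meta["treatment"], n_perm=999, seed=0)
        np.testing.assert_allclose(
            res.loc[["A", "B", "A:B"], "SS"],
            [0.7886966667, 0.0539830000, 0.1420280000],
            rtol=1e-8,
        )
        np.testing.assert_allclose(
            res.loc[["A", "B", "A:B"], "pseudo_F"],
            [19.20933, 2.62960, 3.45920],
            rtol=1e-5,
        )
        assert res.loc["Residual", "SS"] == pytest.approx(0.1231740000, rel=1e-8)

    @staticmethod
    def _classical_one_way_ss(d2: np.ndarray, labels) -> float:
        """Independent oracle: SS explained by a one-way grouping via the
        classical pairwise-distance formulas (balanced designs)."""
        labels = list(labels)
        n = len(labels)
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in set(labels):
            idx = [i for i, l in enumerate(labels) if l == g]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ss_total - ss_within

    def _brute_force_terms(self, d, a, b):
        d2 = d**2
        n = len(a)
        cells = [f"{x}|{y}" for x, y in zip(a, b)]
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_a = self._classical_one_way_ss(d2, a)
        ss_b = self._classical_one_way_ss(d2, b)
        ss_cells = self._classical_one_way_ss(d2, cells)
        return ss_a, ss_b, ss_cells - ss_a - ss_b, ss_total - ss_cells

    def test_ss_matches_classical_pairwise_formula(self):
        """On a balanced crossed design the sequential SS decomposition
        equals the classical within-group pairwise-distance formulas."""
        table = crossed_fixture(seed=13, n_eco=2, n_rep=3, n_otu=20, depth=200)
        dm = distance_matrix(table)
        meta = table.metadata
        res = permanova(dm, meta["ecosystem"], meta["treatment"], n_perm=99, seed=0)
        ss_a, ss_b, ss_ab, ss_res = self._brute_force_terms(
            dm.data, list(meta["ecosystem"]), list(meta["treatment"])
        )
        np.testing.assert_allclose(
            res.loc[["A", "B", "A:B", "Residual"], "SS"],
            [ss_a, ss_b, ss_ab, ss_res],
            atol=1e-8,
        )

    def test_p_matches_exhaustive_label_enumeration(self):
        """8-sample balanced fixture: the sampled permutation p-value agrees
        with exhaustive enumeration of all distinct relabelings, with
        pseudo-F computed by the classical formulas."""
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 30, size=(8, 10))
        n = 8
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = rp.bray_curtis(counts[i], counts[j])
        a = ["x"] * 4 + ["y"] * 4
        b = ["u", "u", "v", "v"] * 2
        from skbio.stats.distance import DistanceMatrix

        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        res = permanova(dm, a, b, n_perm=999, seed=0)

        df_a, df_res = 1, 4
        labelings = set(itertools.permutations(zip(a, b)))
        f_vals = []
        for labeling in labelings:
            la = [t[0] for t in labeling]
            lb = [t[1] for t in labeling]
            ss_a, _, _, ss_res = self._brute_force_terms(d, la, lb)
            f_vals.append((ss_a / df_a) / (ss_res / df_res))
        ss_a, _, _, ss_res = self._brute_force_terms(d, a, b)
        f_obs = (ss_a / df_a) / (ss_res / df_res)
        assert f_obs == pytest.approx(res.loc["A", "pseudo_F"], rel=1e-8)
        exact_p = np.mean([f >= f_obs - 1e-12 for f in f_vals])
        assert res.loc["A", "p"] == pytest.approx(exact_p, abs=0.05)

    def test_maximal_separation_minimum_p(self):
        """Two blocks of duplicated identical samples at distance 1: the
        observed pseudo-F beats every sampled permutation, p = 1/(n_perm+1)."""
        from skbio.stats.distance import DistanceMatrix

        n = 12
        d = np.zeros((n, n))
        d[:6, 6:] = 1.0
        d[6:, :6] = 1.0
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        a = ["g1"] * 6 + ["g2"] * 6
        b = (["u"] * 3 + ["v"] * 3) * 2
        res = permanova(dm, a, b, n_perm=199, seed=1)
        assert res.loc["A", "p"] == pytest.approx(1 / 200)

    def test_p_values_on_discrete_support(self):
        table = crossed_fixture(seed=5)
        res = permanova(
            distance_matrix(table),
            table.metadata["ecosystem"],
            table.metadata["treatment"],
            n_perm=99,
            seed=3,
        )
        for p in res.loc[["A", "B", "A:B"], "p"]:
            k = round(p * 100)
            assert p == pytest.approx(k / 100)
            assert 1 <= k <= 100

    def test_null_p_uniform(self):
        """Labels assigned to structureless data: p is uniform on its
        support (KS test over 100 independent runs)."""
        rng = np.random.default_rng(7)
        pvals = []
        for run in range(100):
            counts = rng.integers(0, 40, size=(12, 25))
            d = np.zeros((12, 12))
            for i in range(12):
                for j in range(i + 1, 12):
                    d[i, j] = d[j, i] = rp.bray_curtis(counts[i], counts[j])
            from skbio.stats.distance import DistanceMatrix

            dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
            a = ["x"] * 6 + ["y"] * 6
            b = (["u"] * 3 + ["v"] * 3) * 2
            res = permanova(dm, a, b, n_perm=99, seed=1000 + run)
            pvals.append(res.loc["B", "p"])
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.15

    def test_degenerate_factor_rejected(self):
        table = crossed_fixture(seed=1)
        with pytest.raises(DegenerateFactorError):
            permanova(
                distance_matrix(table),
                ["only"] * table.n_samples,
                table.metadata["treatment"],
            )

    def test_restricted_permutation_runs(self):
        table = crossed_fixture(seed=8)
        res = rp.permanova_table(table, n_perm=99, seed=0, restrict_within_ecosystem=True)
        assert res.loc["B", "p"] <= 1.0


class TestPairwiseTurnover:
    def test_turnover_uses_pairs(self):
        table = crossed_fixture(seed=11, n_eco=2, n_rep=2)
        out = pairwise_turnover(table)
        assert len(out) == 4
        assert ((out["bray_curtis"] >= 0) & (out["bray_curtis"] <= 1)).all()
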