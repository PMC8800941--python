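import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from radsig.robustness import (
    cluster_correlations,
    lin_ccc,
    prune_correlated,
    spearman_matrix,
    volume_dependency,
)
from radsig.robustness import test_retest_screen as retest_screen


class TestLinCcc:
    def test_perfect_concordance(self):
        assert lin_ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_shifted_vector_hand_value(self):
        # 2*cov/(var+var+shift^2) = 2*(2/3)/(2/3+2/3+1) = 4/7
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_reversed_vector(self):
        assert lin_ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_both_constant_undefined(self):
        with pytest.raises(ValueError):
            lin_ccc([2, 2, 2], [2, 2, 2])

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_lins_inequality_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        ccc = lin_ccc(x, y)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(pearson) + 1e-12
        assert -1 - 1e-12 <= ccc <= 1 + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        assert lin_ccc(x, y) == pytest.approx(
            oracles.lin_ccc(list(x), list(y)), abs=1e-12
        )


class TestTestRetestScreen:
    def _table(self, rng, n=40, k=6):
        cols = [f"f{i}" for i in range(k)]
        idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
        return pd.DataFrame(rng.normal(size=(n, k)), index=idx, columns=cols)

    def test_identical_days_all_pass(self):
        t = self._table(np.random.default_rng(0))
        rep = retest_screen(t, t.copy())
        assert np.allclose(rep["lcc"], 1.0)
        assert rep["lcc_pass"].all()

    def test_independent_noise_mostly_fails(self):
        rng = np.random.default_rng(1)
        rep = retest_screen(self._table(rng, k=20), self._table(rng, k=20))
        assert rep["lcc_pass"].mean() < 0.1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        d1 = self._table(rng, k=20)
        d2 = d1 + rng.normal(0, 0.5, d1.shape)
        pass_07 = set(retest_screen(d1, d2, 0.7).query("lcc_pass").index)
        pass_09 = set(retest_screen(d1, d2, 0.9).query("lcc_pass").index)
        assert pass_09 <= pass_07

    def test_unpaired_subjects_rejected(self):
        t = self._table(np.random.default_rng(3))
        other = t.copy()
        other.index = [f"x{i}" for i in range(len(t))]
        with pytest.raises(ValueError):
            retest_screen(t, other)


class TestSpearman:
    def test_duplicate_and_monotone_transform(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=30)
        t = pd.DataFrame({"a": a, "dup": a, "cube": a**3, "b": rng.uniform(size=30)})
        rho, p = spearman_matrix(t)
        assert rho.loc["a", "dup"] == pytest.approx(1.0)
        assert rho.loc["a", "cube"] == pytest.approx(1.0)  # rank invariance

    def test_independent_features_weakly_correlated(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.uniform(size=(100, 2)), columns=["a", "b"])
        rho, _ = spearman_matrix(t)
        assert abs(rho.loc["a", "b"]) < 0.3


class TestPruneCorrelated:
    def _matrices(self, rho_pairs, features):
        n = len(features)
        rho = pd.DataFrame(np.eye(n), index=features, columns=features)
        p = pd.DataFrame(np.ones((n, n)), index=features, columns=features)
        for a, b, r in rho_pairs:
            rho.loc[a, b] = rho.loc[b, a] = r
            p.loc[a, b] = p.loc[b, a] = 1e-9
        return rho, p

    def test_duplicate_keeps_higher_lcc(self):
        rho, p = self._matrices([("a", "b", 1.0)], ["a", "b"])
        lcc = pd.Series({"a": 0.9, "b": 0.8})
        assert prune_correlated(rho, p, lcc) == ["a"]

    def test_chain_keeps_best_only(self):
        rho, p = self._matrices(
            [("a", "b", 0.95), ("b", "c", 0.95)], ["a", "b", "c"]
        )
        lcc = pd.Series({"a": 0.9, "b": 0.8, "c": 0.7})
        assert prune_correlated(rho, p, lcc) == ["a"]

    def test_independent_features_untouched(self):
        rho, p = self._matrices([], ["a", "b", "c"])
        lcc = pd.Series({"a": 0.9, "b": 0.8, "c": 0.7})
        assert prune_correlated(rho, p, lcc) == ["a", "b", "c"]

    def test_order_insensitive_with_distinct_lcc(self):
        rho, p = self._matrices(
            [("a", "b", 0.92), ("c", "d", 0.95)], ["a", "b", "c", "d"]
        )
        lcc = pd.Series({"a": 0.7, "b": 0.95, "c": 0.85, "d": 0.6})
        kept = prune_correlated(rho, p, lcc)
        rev = list(reversed(rho.columns))
        kept_rev = prune_correlated(
            rho.loc[rev, rev], p.loc[rev, rev], lcc
        )
        assert set(kept) == set(kept_rev) == {"b", "c"}

    def test_significance_gate(self):
        rho, p = self._matrices([("a", "b", 0.95)], ["a", "b"])
        p.loc["a", "b"] = p.loc["b", "a"] = 0.5  # correlated but not significant
        lcc = pd.Series({"a": 0.9, "b": 0.8})
        assert prune_correlated(rho, p, lcc) == ["a", "b"]


class TestClusterCorrelations:
    def test_two_perfect_blocks(self):
        block = np.ones((2, 2))
        rho = pd.DataFrame(
            np.block([[block, np.zeros((2, 2))], [np.zeros((2, 2)), block]]),
            index=list("abcd"), columns=list("abcd"),
        )
        ids, order = cluster_correlations(rho, cut_distance=0.5)
        assert ids["a"] == ids["b"]
        assert ids["c"] == ids["d"]
        assert ids["a"] != ids["c"]

    def test_identity_gives_singletons(self):
        rho = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        ids, _ = cluster_correlations(rho, cut_distance=0.5)
        assert ids.nunique() == 5

    def test_planted_21_blocks_recovered(self):
        rng = np.random.default_rng(0)
        sizes = rng.integers(2, 8, size=21)
        n = int(sizes.sum())
        rho = np.eye(n) * 0.0
        start = 0
        for s in sizes:
            rho[start:start + s, start:start + s] = 0.95
            start += s
        np.fill_diagonal(rho, 1.0)
        cols = [f"f{i}" for i in range(n)]
        ids, _ = cluster_correlations(
            pd.DataFrame(rho, index=cols, columns=cols), cut_distance=0.5
        )
        assert ids.nunique() == 21


class TestVolumeDependency:
    def test_linear_feature_flagged(self):
        v = np.linspace(0.5, 5, 20)
        dep = volume_dependency(2.0 * v, v)
        assert dep.flagged
        assert dep.rho == pytest.approx(1.0)
        assert dep.best_model in ("linear", "power")  # 2V fits both exactly

    def test_quadratic_power_recovery(self):
        rng = np.random.default_rng(0)
        v = np.linspace(0.5, 5, 30)
        f = v**2 + rng.normal(0, 0.01, 30)
        dep = volume_dependency(f, v)
        assert dep.best_model == "power"
        assert dep.coefficients[1] == pytest.approx(2.0, abs=0.05)

    def test_independent_feature_not_flagged(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.5, 5, 40)
        dep = volume_dependency(rng.normal(size=40), v)
        assert not dep.flagged

    @pytest.mark.parametrize("form,gen", [
        ("linear", lambda v: 3.0 + 2.0 * v),
        ("log", lambda v: 1.0 + 2.0 * np.log(v)),
        ("power", lambda v: 1.5 * v**1.7),
        ("exponential", lambda v: 0.8 * np.exp(-0.9 * v)),
    ])
    @pytest.mark.parametrize("seed", range(5))
    def test_noiseless_form_wins_aic(self, form, gen, seed):
        rng = np.random.default_rng(seed)
        v = np.sort(rng.uniform(0.5, 4.0, 25))
        dep = volume_dependency(gen(v), v)
        assert dep.best_model == form

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            volume_dependency(np.ones(10), np.linspace(-1, 1, 10))
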