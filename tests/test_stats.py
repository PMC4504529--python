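"""Sign test, Mann-Whitney U and Cohen's kappa against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

import ldctsim as L


def brute_force_sign_p(n_pos: int, n_neg: int) -> float:
    """Enumerate all 2^n equally likely sign patterns; two-sided extremity
    measured by |k - n/2|."""
    n = n_pos + n_neg
    d_obs = abs(n_pos - n / 2)
    extreme = sum(
        math.comb(n, k) for k in range(n + 1) if abs(k - n / 2) >= d_obs - 1e-12
    )
    return extreme / 2**n


class TestSignTest:
    def test_all_ties_vacuous(self):
        with pytest.warns(UserWarning):
            res = L.sign_test([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0
        assert res.n_effective == 0

    def test_five_positive_pairs(self):
        res = L.sign_test([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.p_value == pytest.approx(2 * 0.5**5)
        assert res.n_effective == 5

    def test_ties_are_dropped(self):
        res = L.sign_test([1, 2, 3, 7], [1, 0, 0, 0])
        assert res.n_effective == 3

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=10))
    def test_matches_sign_pattern_enumeration(self, signs):
        diffs = np.array(signs, dtype=float)
        n_pos = int((diffs > 0).sum())
        n_neg = int((diffs < 0).sum())
        if n_pos + n_neg == 0:
            return
        res = L.sign_test(diffs, np.zeros_like(diffs))
        assert res.p_value == pytest.approx(brute_force_sign_p(n_pos, n_neg))

    def test_symmetric_under_sample_swap(self):
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        b = np.array([2.0, 2.0, 2.0, 2.0, 2.0])
        assert L.sign_test(a, b).p_value == L.sign_test(b, a).p_value


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = L.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)

    def test_symmetric_under_label_swap(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        assert L.mann_whitney(x, y).p_value == pytest.approx(
            L.mann_whitney(y, x).p_value
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            L.mann_whitney([], [1.0])

    @settings(deadline=None, max_examples=40)
    @given(
        x=st.lists(st.integers(0, 6), min_size=1, max_size=5),
        y=st.lists(st.integers(0, 6), min_size=1, max_size=5),
    )
    def test_exact_p_matches_assignment_enumeration(self, x, y):
        """Independent oracle: enumerate every group assignment directly."""
        x, y = np.array(x, float), np.array(y, float)
        res = L.mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        ranks = scipy.stats.rankdata(pooled)
        n1 = len(x)
        mu = n1 * len(y) / 2.0

        def u_of(idx):
            return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

        d_obs = abs(u_of(range(n1)) - mu)
        universe = list(itertools.combinations(range(len(pooled)), n1))
        extreme = sum(abs(u_of(c) - mu) >= d_obs - 1e-9 for c in universe)
        assert res.p_value == pytest.approx(extreme / len(universe))

    def test_exact_agrees_with_scipy_without_ties(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=6) + 0.5
        res = L.mann_whitney(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, method="exact")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_large_sample_normal_approximation(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=35) + 0.3
        res = L.mann_whitney(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_tie_correction_in_approximation(self, rng):
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(0, 4, size=30).astype(float)
        res = L.mann_whitney(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestCohenKappa:
    def test_identical_ratings_give_one(self):
        res = L.cohen_kappa([1, 2, 3, 2, 1], [1, 2, 3, 2, 1])
        assert res.kappa == pytest.approx(1.0)
        assert res.band == "almost perfect"

    def test_observed_interobserver_band(self):
        assert L.kappa_band(0.64) == "substantial"

    @pytest.mark.parametrize(
        "kappa,band",
        [(0.0, "no agreement"), (0.15, "slight"), (0.35, "fair"), (0.5, "moderate"),
         (0.61, "substantial"), (0.8, "substantial"), (0.81, "almost perfect"),
         (-0.3, "no agreement")],
    )
    def test_band_edges(self, kappa, band):
        assert L.kappa_band(kappa) == band

    def test_single_category_undefined(self):
        with pytest.warns(UserWarning):
            res = L.cohen_kappa([2, 2, 2], [2, 2, 2])
        assert not res.defined
        assert res.band == "undefined"

    @settings(deadline=None, max_examples=40)
    @given(
        r=st.lists(
            st.tuples(st.integers(1, 4), st.integers(1, 4)), min_size=2, max_size=40
        )
    )
    def test_matches_confusion_matrix_formula_and_sklearn(self, r):
        r1 = np.array([a for a, _ in r])
        r2 = np.array([b for _, b in r])
        cats = np.union1d(r1, r2)
        if len(cats) < 2:
            return
        # direct-formula oracle from the confusion matrix
        table = np.zeros((len(cats), len(cats)))
        for a, b in r:
            table[np.searchsorted(cats, a), np.searchsorted(cats, b)] += 1
        n = table.sum()
        p_o = np.trace(table) / n
        p_e = (table.sum(1) * table.sum(0)).sum() / n**2
        res = L.cohen_kappa(r1, r2)
        if p_e >= 1 - 1e-12:
            assert not res.defined
            return
        assert res.kappa == pytest.approx((p_o - p_e) / (1 - p_e))
        assert res.kappa == pytest.approx(cohen_kappa_score(r1, r2))

    def test_invariant_under_category_relabeling(self):
        r1 = [1, 2, 3, 1, 2, 3, 3]
        r2 = [1, 2, 2, 1, 3, 3, 3]
        relabel = {1: 10, 2: 7, 3: 99}
        a = L.cohen_kappa(r1, r2)
        b = L.cohen_kappa([relabel[v] for v in r1], [relabel[v] for v in r2])
        assert a.kappa == pytest.approx(b.kappa)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.cohen_kappa([1, 2], [1, 2, 3])
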