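"""TOW statistic, optimal weights, and permutation p-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import brute_force_tow
from towgene.tow import (
    BurdenTest,
    TOWTest,
    optimal_weights,
    permutation_indices,
    permutation_pvalue,
    tow_statistic,
)


class TestOptimalWeights:
    def test_hand_computed_single_variant(self, make_resid):
        # y~=(1,-1,2,-2), x~=(1,0,1,0): explicit sums give slope 3/1 = 3
        resid = make_resid([1, -1, 2, -2], [[1], [0], [1], [0]])
        w, informative = optimal_weights(resid)
        # num = sum (y-0)(x-0.5) = 0.5+0.5+1+1 = 3; den = 4*0.25 = 1
        assert w[0] == pytest.approx(3.0)
        assert informative.all()

    def test_standardized_column_weight_is_covariance(self, rng, make_resid):
        y = rng.normal(size=40)
        x = rng.normal(size=40)
        x = (x - x.mean()) / x.std(ddof=1)  # unit sample variance
        resid = make_resid(y, x[:, None])
        w, _ = optimal_weights(resid)
        cov = np.sum((y - y.mean()) * (x - x.mean())) / (len(y) - 1)
        assert w[0] == pytest.approx(cov)

    def test_zero_variance_variant_flagged_zero(self, make_resid):
        resid = make_resid([1.0, 2.0, 3.0], [[5, 1], [5, 2], [5, 0]])
        w, informative = optimal_weights(resid)
        assert w[0] == 0.0 and not informative[0]
        assert informative[1]

    def test_null_weight_shrinks_with_n(self, make_resid):
        rng = np.random.default_rng(99)
        n = 20_000
        y = rng.normal(size=n)
        x = rng.binomial(2, 0.3, size=n).astype(float)
        resid = make_resid(y - y.mean(), (x - x.mean())[:, None])
        w, _ = optimal_weights(resid)
        xc = x - x.mean()
        se = np.std(y) / np.sqrt(xc @ xc)
        assert abs(w[0]) < 3 * se

    def test_empty_subset_rejected(self, make_resid):
        resid = make_resid([1.0, 2.0], [[1], [0]])
        with pytest.raises(ValueError, match="empty"):
            optimal_weights(resid, np.array([], dtype=int))


class TestTowStatistic:
    def test_matches_brute_force_on_randomized_small_instances(self, make_resid):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            M = int(rng.integers(1, 6))
            y = rng.normal(size=n)
            X = rng.binomial(2, 0.3, size=(n, M)).astype(float)
            resid = make_resid(y, X)
            expected, expected_w = brute_force_tow(y, X)
            got = tow_statistic(resid)
            w, _ = optimal_weights(resid)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)
            np.testing.assert_allclose(w, expected_w, rtol=1e-12, atol=1e-12)

    def test_single_variant_closed_form(self, make_resid):
        y = np.array([0.4, -1.2, 2.0, 0.3, -1.5])
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        resid = make_resid(y, x[:, None])
        yc, xc = y - y.mean(), x - x.mean()
        closed = (yc @ xc) ** 2 / (xc @ xc)
        assert tow_statistic(resid) == pytest.approx(closed, rel=1e-10)

    def test_constant_trait_gives_zero(self, make_resid):
        resid = make_resid(np.zeros(5), np.arange(10.0).reshape(5, 2))
        assert tow_statistic(resid) == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_variants_warns_and_zero(self, make_resid):
        resid = make_resid([1.0, -1.0, 0.5], np.ones((3, 2)))
        with pytest.warns(UserWarning, match="no variant varies"):
            assert tow_statistic(resid) == 0.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        y=hnp.arrays(float, 6, elements=st.floats(-5, 5)),
        X=hnp.arrays(float, (6, 3), elements=st.sampled_from([0.0, 1.0, 2.0])),
    )
    def test_nonnegativity_and_decomposition(self, y, X):
        from towgene.adjust import ResidualData

        resid = ResidualData(np.asarray(y), np.asarray(X))
        stat = tow_statistic(resid)
        assert stat >= -1e-10
        # sum-over-variants decomposition
        yc = y - y.mean()
        total = 0.0
        for m in range(3):
            xc = X[:, m] - X[:, m].mean()
            den = xc @ xc
            if den > 0:
                total += (yc @ xc) ** 2 / den
        assert stat == pytest.approx(total, rel=1e-9, abs=1e-9)


class TestPermutationPvalue:
    def test_counting_formula_floor(self, make_resid):
        # strong association: observed beats every permutation => p = 1/(B+1)
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.4, size=100).astype(float)
        y = 5.0 * x + rng.normal(scale=0.1, size=100)
        resid = make_resid(y - y.mean(), (x - x.mean())[:, None])
        res = permutation_pvalue(resid, n_permutations=999, seed=3)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.n_permutations == 999

    def test_determinism_and_scale_invariance(self, make_resid):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.3, size=(60, 4)).astype(float)
        y = rng.normal(size=60)
        resid = make_resid(y, X)
        r1 = permutation_pvalue(resid, n_permutations=499, seed=11)
        r2 = permutation_pvalue(resid, n_permutations=499, seed=11)
        assert r1.p_value == r2.p_value
        scaled = make_resid(3.7 * y, X)
        r3 = permutation_pvalue(scaled, n_permutations=499, seed=11)
        assert r3.p_value == r1.p_value

    def test_zero_permutations_rejected(self, make_resid):
        resid = make_resid([1.0, 2.0, 3.0], [[0], [1], [2]])
        with pytest.raises(ValueError):
            TOWTest(resid).fit(n_permutations=0, seed=1)
        with pytest.raises(ValueError):
            permutation_indices(5, 0, seed=1)

    def test_weights_recomputed_per_permutation(self, make_resid):
        # If weights were frozen at the observed y, every permuted statistic
        # would be the linear form sum_m w_m <y_perm, xc_m>, which can go
        # negative; the correct recomputed statistic never does.
        rng = np.random.default_rng(8)
        X = rng.binomial(2, 0.3, size=(30, 3)).astype(float)
        y = rng.normal(size=30)
        resid = make_resid(y, X)
        test = TOWTest(resid)
        perms = permutation_indices(30, 200, seed=4)
        perm_stats = test._stats_for(test._yc[perms])
        assert (perm_stats >= 0).all()
        # and the permuted statistics vary (not the frozen-weight constant)
        assert np.std(perm_stats) > 0

    def test_shared_permutation_matrix_reused(self, make_resid):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.3, size=(40, 5)).astype(float)
        y = rng.normal(size=40)
        resid = make_resid(y, X)
        perms = permutation_indices(40, 299, seed=9)
        r1 = TOWTest(resid).fit(permutations=perms)
        r2 = TOWTest(resid).fit(permutations=perms)
        assert r1.p_value == r2.p_value

    def test_summary_mentions_key_fields(self, make_resid):
        resid = make_resid([1.0, 0.0, 2.0, -1.0], [[0], [1], [2], [1]])
        res = TOWTest(resid).fit(n_permutations=99, seed=0)
        text = res.summary()
        assert "p-value" in text and "permutations" in text


class TestBurdenComparator:
    def test_burden_collapses_mixed_directions(self, make_resid):
        # equal-and-opposite effects on two variants cancel in the unweighted
        # sum, so TOW's observed statistic is (relatively) far larger
        rng = np.random.default_rng(12)
        x1 = rng.binomial(2, 0.3, 300).astype(float)
        x2 = rng.binomial(2, 0.3, 300).astype(float)
        y = 1.0 * x1 - 1.0 * x2 + rng.normal(size=300)
        X = np.column_stack([x1, x2])
        resid = make_resid(y - y.mean(), X - X.mean(axis=0))
        perms = permutation_indices(300, 499, seed=5)
        p_tow = TOWTest(resid).fit(permutations=perms).p_value
        p_burden = BurdenTest(resid).fit(permutations=perms).p_value
        assert p_tow < p_burden
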