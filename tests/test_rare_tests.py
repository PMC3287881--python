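"""Burden scores, the VT threshold search, and permutation significance,
checked against hand arithmetic and exhaustive-enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raremix.data_model import InputError
from raremix.rare_tests import (
    PermutationContext,
    burden_statistic,
    ft_burden,
    permutation_pvalue,
    rare_gene_test,
    reference_mask,
    vt_statistic,
    we_burden,
    we_weights,
)


class TestFtBurden:
    def test_single_variant_identity(self):
        d = np.array([[0], [1], [2], [0]])
        sc = ft_burden(d, [0.01], T=0.05)
        np.testing.assert_array_equal(sc.scores, [0, 1, 2, 0])
        assert not sc.empty

    def test_strict_threshold_boundary(self):
        """maf == T is excluded: inclusion is strictly below T."""
        d = np.array([[1, 1], [0, 2], [1, 0]])
        sc = ft_burden(d, [0.06, 0.20], T=0.05)
        assert sc.empty
        np.testing.assert_array_equal(sc.scores, [0, 0, 0])
        sc2 = ft_burden(d, [0.05, 0.20], T=0.05)
        assert sc2.empty  # 0.05 is not < 0.05

    def test_elementwise_sum(self):
        d = np.array([[1, 0], [0, 2], [1, 1]])
        sc = ft_burden(d, [0.01, 0.02], T=0.05)
        np.testing.assert_array_equal(sc.scores, [1, 2, 2])

    def test_invalid_threshold(self):
        with pytest.raises(InputError):
            ft_burden(np.zeros((3, 1), dtype=int), [0.0], T=0.0)


class TestWeBurden:
    def test_madsen_browning_weight_arithmetic(self):
        """n_ref=4, count 0 -> q = 1/10, w = sqrt(4 * 0.1 * 0.9) = 0.6."""
        w = we_weights(np.array([0]), n_ref=4)
        np.testing.assert_allclose(w, [0.6])
        # a single-copy carrier contributes 1/0.6
        d = np.array([[0], [0], [0], [0], [1]])
        ref = np.array([True, True, True, True, False])
        sc = we_burden(d, ref)
        np.testing.assert_allclose(sc.scores[-1], 1 / 0.6)
        np.testing.assert_allclose(sc.scores[:-1], 0.0)

    def test_identical_reference_counts_and_column_swap(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(10, 2)).astype(np.int8)
        d[:, 1] = d[:, 0]  # identical columns -> identical counts
        ref = np.arange(10) < 5
        sc = we_burden(d, ref)
        assert sc.weights[0] == sc.weights[1]
        swapped = we_burden(d[:, ::-1], ref)
        np.testing.assert_allclose(sc.scores, swapped.scores)

    def test_all_zero_dosages(self):
        sc = we_burden(np.zeros((6, 3), dtype=np.int8), np.ones(6, dtype=bool))
        np.testing.assert_allclose(sc.scores, 0.0)

    def test_empty_reference_group_rejected(self):
        with pytest.raises(InputError):
            we_weights(np.array([1]), n_ref=0)

    def test_reference_mask_median_policy(self):
        y = np.array([1.0, 5.0, 2.0, 9.0])
        mask = reference_mask(y, "median")
        np.testing.assert_array_equal(mask, [True, False, True, False])
        assert reference_mask(y, "all").all()


class TestBurdenStatistic:
    def test_constant_score_is_zero(self):
        assert burden_statistic(np.zeros(5), np.arange(5.0)) == 0.0

    def test_self_correlation_is_one(self):
        y = np.array([1.0, 2.0, 4.0, 1.0])
        assert burden_statistic(y, y) == pytest.approx(1.0)

    def test_hand_evaluated_correlation(self):
        s = np.array([0, 1, 2, 0], dtype=float)
        y = np.array([1.0, 2.0, 4.0, 1.0])
        # hand arithmetic: cov = 4.5/..., r ~= 0.99339
        sc, yc = s - s.mean(), y - y.mean()
        expect = (sc @ yc) / math.sqrt((sc @ sc) * (yc @ yc))
        assert burden_statistic(s, y) == pytest.approx(expect)
        # 4 / sqrt(2.75 * 6) by hand
        assert expect == pytest.approx(0.984732, abs=5e-6)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.poisson(1, 20).astype(float)
        y = rng.normal(size=20)
        z = burden_statistic(s, y)
        assert burden_statistic(s, 3.0 + 2.5 * y) == pytest.approx(z)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            burden_statistic(np.zeros(4), np.zeros(5))


class TestVtStatistic:
    def test_single_polymorphic_variant(self):
        d = np.array([[0], [1], [2], [0], [1], [0]])
        y = np.array([0.1, 1.0, 2.2, -0.3, 0.8, 0.2])
        z, t_opt = vt_statistic(d, [d.mean() / 2], y)
        assert z == pytest.approx(abs(burden_statistic(d[:, 0], y)))
        assert t_opt == pytest.approx(d.mean() / 2)

    def test_matches_brute_force_enumeration(self):
        """z_max equals the max of |corr| over every candidate threshold."""
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(6, 3)).astype(np.int8)
        mafs = d.sum(axis=0) / 12.0
        y = rng.normal(size=6)
        z, t_opt = vt_statistic(d, mafs, y)
        cands = sorted(set(m for m in mafs if m > 0))
        brute = []
        for t in cands:
            s = d[:, mafs <= t].sum(axis=1)
            brute.append(abs(burden_statistic(s, y)))
        assert z == pytest.approx(max(brute))
        assert t_opt == pytest.approx(cands[int(np.argmax(brute))])

    def test_constant_phenotype_gives_zero(self):
        d = np.array([[0, 1], [1, 0], [2, 1], [0, 0]])
        z, _ = vt_statistic(d, [0.1, 0.2], np.ones(4))
        assert z == 0.0

    def test_all_monomorphic_degenerate(self):
        z, t_opt = vt_statistic(np.zeros((5, 2), dtype=np.int8), [0.0, 0.0],
                                np.arange(5.0))
        assert z == 0.0 and t_opt is None

    def test_ft_at_largest_maf_equals_vt_last_candidate(self):
        """FT with T above every MAF reproduces VT's largest-threshold score."""
        rng = np.random.default_rng(3)
        d = rng.integers(0, 2, size=(8, 3)).astype(np.int8)
        mafs = d.sum(axis=0) / 16.0
        y = rng.normal(size=8)
        s_all = ft_burden(d, mafs, T=0.5).scores  # every maf < 0.5 here
        z_all = abs(burden_statistic(s_all, y))
        z_max, _ = vt_statistic(d, mafs, y)
        assert z_max >= z_all - 1e-12


class TestPermutationPvalue:
    def test_constant_statistic_gives_p_one(self):
        p, _ = permutation_pvalue(lambda y: 1.0, np.arange(6.0), B=50, seed=0)
        assert p == 1.0

    def test_floor_of_estimator(self):
        """Lower bound 1/(B+1) when no permutation ties or exceeds."""
        d = np.array([[0], [0], [1], [2], [2]])
        y = d[:, 0].astype(float)  # perfect association

        def stat(yy):
            return abs(burden_statistic(d[:, 0], yy))

        # not all permutations of y reach |r| = 1, so p is small but > floor
        p, z = permutation_pvalue(stat, y, B=999, seed=1)
        assert z == pytest.approx(1.0)
        assert p >= 1 / 1000

    def test_matches_exhaustive_enumeration(self):
        """With the full set of 5! relabelings as the permutation stream the
        estimator reproduces the exact conditional p; a random stream of the
        same size lands within binomial noise of it."""
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(5, 2)).astype(np.int8)
        mafs = d.sum(axis=0) / 10.0
        y = np.array([0.3, -1.2, 0.8, 2.0, -0.5])
        s = ft_burden(d, mafs, 0.5).scores

        def stat(yy):
            return abs(burden_statistic(s, yy))

        z_obs = stat(y)
        all_perms = np.array(list(itertools.permutations(y)))
        exact_hits = sum(stat(pp) >= z_obs - 1e-12 for pp in all_perms)
        exact_p = exact_hits / math.factorial(5)

        # feed the 119 non-identity orderings as the permutation set
        non_identity = np.array([pp for pp in all_perms
                                 if not np.array_equal(pp, y)])
        ctx = PermutationContext(y, non_identity)
        res = rare_gene_test(d, mafs, y, "ft", T=0.5, ctx=ctx)
        assert res.p_raw == pytest.approx(exact_p)

        p_rand, _ = permutation_pvalue(stat, y, B=119, seed=5)
        assert abs(p_rand - exact_p) <= 3.5 * math.sqrt(exact_p * (1 - exact_p) / 119)

    def test_vectorized_engine_agrees_with_generic(self):
        """The shared-context fast path reproduces the loop implementation."""
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(12, 4)).astype(np.int8)
        mafs = d.sum(axis=0) / 24.0
        y = rng.normal(size=12)
        for method, stat in [
            ("ft", lambda yy: abs(burden_statistic(ft_burden(d, mafs, 0.3).scores, yy))),
            ("vt", lambda yy: vt_statistic(d, mafs, yy)[0]),
        ]:
            seed = 9
            res = rare_gene_test(d, mafs, y, method, T=0.3, B=200, seed=seed)
            # generic path with the same permutation stream
            rng2 = np.random.default_rng(seed)
            from raremix._stats import permutation_matrix

            Yp = permutation_matrix(rng2, y, 200)
            z_obs = stat(y)
            exceed = sum(stat(Yp[b]) >= z_obs - 1e-12 for b in range(200))
            assert res.p_raw == pytest.approx((1 + exceed) / 201)

    def test_we_permutation_recomputes_weights(self):
        """WE under permutation re-estimates reference-group weights: the
        observed statistic must equal a direct recomputation."""
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(10, 3)).astype(np.int8)
        mafs = d.sum(axis=0) / 20.0
        y = rng.normal(size=10)
        res = rare_gene_test(d, mafs, y, "we", B=99, seed=3)
        ref = reference_mask(y, "median")
        sc = we_burden(d, ref)
        assert res.statistic == pytest.approx(abs(burden_statistic(sc.scores, y)))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_p_raw_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(8, 2)).astype(np.int8)
        mafs = d.sum(axis=0) / 16.0
        y = rng.normal(size=8)
        res = rare_gene_test(d, mafs, y, "vt", B=49, seed=seed)
        assert 1 / 50 <= res.p_raw <= 1.0


def test_tests_invariant_to_phenotype_affine_transform():
    """FT, WE and VT p-values are unchanged by y -> a + b*y (b > 0)."""
    rng = np.random.default_rng(8)
    d = rng.integers(0, 3, size=(15, 4)).astype(np.int8)
    mafs = d.sum(axis=0) / 30.0
    y = rng.normal(size=15)
    for method in ("ft", "we", "vt"):
        r1 = rare_gene_test(d, mafs, y, method, T=0.3, B=150, seed=6)
        r2 = rare_gene_test(d, mafs, 10.0 + 0.5 * y, method, T=0.3, B=150, seed=6)
        assert r1.p_raw == r2.p_raw
        assert r1.statistic == pytest.approx(r2.statistic)
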