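"""Single-SNP regression, min-p summary, and the LASSO/Cp gene test,
checked against closed-form OLS oracles and the F = t^2 identity."""

import numpy as np
import pytest
from scipy import stats

from raremix.common_tests import (
    gene_lasso_pvalue,
    gene_minp,
    lasso_cp_path,
    snp_regression,
)


class TestSnpRegression:
    def test_perfect_fit(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = 2.0 * g + 5.0
        res = snp_regression(g, y)
        assert res.slope == pytest.approx(2.0)
        assert res.p < 1e-12

    def test_closed_form_normal_equations(self):
        """Slope and p match the hand-solved OLS on a small fixture."""
        g = np.array([0, 1, 2, 0, 1], dtype=float)
        y = np.array([0.1, 1.2, 1.9, -0.2, 1.1])
        n = 5
        sxx = ((g - g.mean()) ** 2).sum()
        sxy = ((g - g.mean()) * (y - y.mean())).sum()
        beta = sxy / sxx
        rss = ((y - y.mean() - beta * (g - g.mean())) ** 2).sum()
        se = np.sqrt(rss / (n - 2) / sxx)
        p = 2 * stats.t.sf(abs(beta / se), n - 2)
        res = snp_regression(g, y)
        assert res.slope == pytest.approx(beta)
        assert res.se == pytest.approx(se)
        assert res.p == pytest.approx(p)

    def test_monomorphic_flagged_not_raised(self):
        res = snp_regression(np.zeros(6), np.arange(6.0))
        assert res.monomorphic and res.p == 1.0 and res.slope == 0.0

    def test_null_p_uniformity(self):
        """Under no association, regression p-values are ~Uniform(0,1)."""
        rng = np.random.default_rng(0)
        ps = []
        g = rng.integers(0, 3, size=200).astype(float)
        for _ in range(300):
            ps.append(snp_regression(g, rng.normal(size=200)).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001


class TestGeneMinp:
    def test_single_marker_no_correction(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
        y = rng.normal(size=50)
        res = gene_minp(d, [0.3], y, T=0.05, gene_id="G")
        assert res.p_corrected == pytest.approx(res.p_raw)
        assert res.n_markers_used == 1

    def test_bonferroni_arithmetic_and_cap(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(60, 3)).astype(np.int8)
        mafs = d.sum(axis=0) / 120.0
        y = rng.normal(size=60)
        res = gene_minp(d, mafs, y, T=0.05, gene_id="G")
        assert res.p_corrected == pytest.approx(min(1.0, 3 * res.p_raw))

    def test_no_eligible_variants_returns_none(self):
        d = np.array([[0, 1], [1, 0], [0, 0]], dtype=np.int8)
        assert gene_minp(d, [0.01, 0.02], np.arange(3.0), T=0.05) is None

    def test_invariant_to_variant_order(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
        mafs = d.sum(axis=0) / 80.0
        y = rng.normal(size=40)
        r1 = gene_minp(d, mafs, y, T=0.0 + 1e-9)
        perm = [2, 0, 3, 1]
        r2 = gene_minp(d[:, perm], mafs[perm], y, T=0.0 + 1e-9)
        assert r1.p_raw == pytest.approx(r2.p_raw)
        assert r1.p_corrected == pytest.approx(r2.p_corrected)


class TestLassoCp:
    def test_single_strong_variant_selected(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(100, 1)).astype(float)
        y = 1.5 * g[:, 0] + rng.normal(size=100)
        sel = lasso_cp_path(g, y)
        assert list(sel.selected) == [0]
        # Cp of the selected model is below the empty model's Cp
        empty_cp = sel.cp[sel.df == 0]
        best_cp = sel.cp.min()
        assert best_cp < empty_cp.min()

    def test_pure_noise_prefers_empty_model(self):
        """With m=5 null predictors, the empty model wins most draws."""
        rng = np.random.default_rng(5)
        empties = 0
        for _ in range(40):
            X = rng.integers(0, 3, size=(200, 5)).astype(float)
            y = rng.normal(size=200)
            sel = lasso_cp_path(X, y)
            empties += len(sel.selected) == 0
        assert empties > 20

    def test_lars_entry_order_on_orthogonal_design(self):
        """On orthogonal predictors the first path entrant is the one with
        the largest absolute correlation (closed-form LARS behavior)."""
        n = 64
        x1 = np.tile([0, 1], n // 2).astype(float)
        x2 = np.repeat([0, 1], n // 2).astype(float)
        x1c, x2c = x1 - x1.mean(), x2 - x2.mean()
        assert abs(x1c @ x2c) < 1e-9  # orthogonal by construction
        rng = np.random.default_rng(6)
        y = 2.0 * x1 + rng.normal(scale=0.5, size=n)
        X = np.column_stack([x2, x1])  # causal variant second
        sel = lasso_cp_path(X, y)
        first_nonzero = np.flatnonzero((np.abs(sel.coef_path) > 0).any(axis=1))
        entry = np.argmax(np.abs(sel.coef_path[:, 1]) > 0)
        assert entry == 1  # x1 enters first
        assert 1 in sel.selected

    def test_df_equals_nonzero_count(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(80, 4)).astype(float)
        y = X @ [1.0, 0.5, 0.0, 0.0] + rng.normal(size=80)
        sel = lasso_cp_path(X, y)
        nnz = (np.abs(sel.coef_path) > 0).sum(axis=0)
        np.testing.assert_array_equal(sel.df, nnz)

    def test_collinear_columns_degenerate_to_empty(self):
        X = np.ones((30, 2))
        sel = lasso_cp_path(X, np.random.default_rng(8).normal(size=30))
        assert sel.degenerate and len(sel.selected) == 0


class TestGeneLassoPvalue:
    def test_empty_selection_convention(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 3, size=(50, 2)).astype(np.int8)
        y = rng.normal(size=50)
        sel = lasso_cp_path(X.astype(float), y)
        sel.selected = np.array([], dtype=int)
        res = gene_lasso_pvalue(sel, X, y, m_total=7, gene_id="G")
        assert res.p_raw == 1.0 and res.p_corrected == 1.0

    def test_f_equals_t_squared_for_single_variant(self):
        """Single selected variant: refit F-test p equals the squared-t
        regression p of that variant."""
        rng = np.random.default_rng(10)
        g = rng.integers(0, 3, size=(70, 1)).astype(float)
        y = 0.8 * g[:, 0] + rng.normal(size=70)
        sel = lasso_cp_path(g, y)
        assert list(sel.selected) == [0]
        res = gene_lasso_pvalue(sel, g, y, m_total=1)
        single = snp_regression(g[:, 0], y)
        assert res.p_raw == pytest.approx(single.p, rel=1e-9)
        assert res.p_corrected == pytest.approx(single.p, rel=1e-9)

    def test_total_snp_bonferroni_and_joint_signal(self):
        """Two orthogonal causal variants: the joint corrected p with
        m_total = 8 beats either single-variant corrected p."""
        n = 200
        rng = np.random.default_rng(12)
        x1 = np.tile([0, 1], n // 2).astype(float)
        x2 = np.repeat([0, 1], n // 2).astype(float)
        y = 1.0 * x1 + 1.0 * x2 + rng.normal(size=n)
        X = np.column_stack([x1, x2])
        sel = lasso_cp_path(X, y)
        assert set(sel.selected) == {0, 1}
        res = gene_lasso_pvalue(sel, X, y, m_total=8)
        assert res.p_corrected == pytest.approx(min(1.0, 8 * res.p_raw))
        singles = [snp_regression(X[:, j], y).p * 8 for j in range(2)]
        assert res.p_corrected < min(min(singles), 1.0)

    def test_corrected_never_below_raw(self):
        rng = np.random.default_rng(13)
        X = rng.integers(0, 3, size=(60, 3)).astype(float)
        y = rng.normal(size=60)
        sel = lasso_cp_path(X, y)
        res = gene_lasso_pvalue(sel, X, y, m_total=3)
        assert res.p_corrected >= res.p_raw
        assert 0 < res.p_raw <= 1
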