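import numpy as np
import pytest
from scipy import stats

from bsp.core import BspConfig, SpatialDataset
from bsp.scoring import (
    augment_null_genes,
    bsp_scores,
    fit_beta_null,
    gene_weights,
    run_bsp,
    score_pvalues,
)
from conftest import brute_bsp_scores


class TestGeneWeights:
    def test_single_gene_has_weight_one(self, rng):
        assert gene_weights(rng.uniform(0, 1, (20, 1)))[0] == 1.0

    def test_direct_formula(self):
        # variances 1 and 4 -> weights 0.25 and 1
        a = np.repeat([0.0, 2.0], 50)
        b = np.repeat([0.0, 4.0], 50)
        w = gene_weights(np.column_stack([a, b]))
        np.testing.assert_allclose(w, [0.25, 1.0])

    def test_constant_gene_weight_zero(self, rng):
        expr = np.column_stack([rng.uniform(0, 1, 30), np.full(30, 0.5)])
        w = gene_weights(expr)
        assert w[1] == 0.0 and w[0] == 1.0

    def test_all_constant_gives_all_zero(self):
        assert (gene_weights(np.ones((10, 4))) == 0).all()


class TestBspScores:
    def test_constant_gene_scores_zero(self, rng):
        expr = np.column_stack([rng.uniform(0, 1, 40), np.full(40, 3.0)])
        ds = SpatialDataset(coords=rng.uniform(0, 6, (40, 2)), expr=expr)
        table = bsp_scores(ds)
        assert table.score[1] == 0.0

    def test_big_radius_covering_sample_zeroes_everything(self, rng):
        coords = rng.uniform(0, 1, (30, 2))  # diameter < sqrt(2), normalized ~5.5
        ds = SpatialDataset(coords=coords, expr=rng.uniform(0, 1, (30, 5)))
        table = bsp_scores(ds, BspConfig(d1=50.0, d2=100.0))
        assert (table.sigma_D2 == 0).all()
        assert (table.score == 0).all()

    def test_three_spot_line_single_gene(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        ds = SpatialDataset(
            coords=coords,
            expr=np.array([0.0, 1.0, 0.0])[:, None],
            coords_normalized=True,  # keep the hand-set geometry
        )
        table = bsp_scores(ds, BspConfig(d1=1.5, d2=2.5))
        assert table.sigma_D2[0] == 0.0
        assert table.score[0] == 0.0

    def test_single_spot_rejected(self):
        with pytest.raises(ValueError):
            SpatialDataset(coords=np.zeros((1, 2)), expr=np.zeros((1, 1)))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(300 + seed)
        m = int(rng.integers(30, 200))
        n = int(rng.integers(2, 50))
        coords = rng.uniform(0, 10, size=(m, 2))
        expr = rng.gamma(2.0, 2.0, size=(m, n))
        table = bsp_scores(SpatialDataset(coords=coords, expr=expr))
        s1, s2, scores = brute_bsp_scores(coords, expr, 1.0, 3.0)
        np.testing.assert_allclose(table.sigma_D1, s1, rtol=1e-10)
        np.testing.assert_allclose(table.sigma_D2, s2, rtol=1e-10)
        np.testing.assert_allclose(table.score, scores, rtol=1e-10)

    def test_spot_permutation_invariance(self, rng):
        coords = rng.uniform(0, 6, (60, 2))
        expr = rng.uniform(0, 1, (60, 10))
        perm = rng.permutation(60)
        a = bsp_scores(SpatialDataset(coords=coords, expr=expr))
        b = bsp_scores(SpatialDataset(coords=coords[perm], expr=expr[perm]))
        np.testing.assert_allclose(a.score, b.score, rtol=1e-9)


class TestNullAugmentation:
    def test_permutation_preserves_value_multisets(self, rng):
        expr = rng.uniform(0, 1, (25, 3))
        nulls = augment_null_genes(expr, 9, seed=5)
        for k in range(9):
            np.testing.assert_array_equal(np.sort(nulls[:, k]), np.sort(expr[:, k % 3]))

    def test_zero_pool_is_empty(self, rng):
        assert augment_null_genes(rng.uniform(0, 1, (10, 2)), 0).shape == (10, 0)

    def test_seed_reproducibility(self, rng):
        expr = rng.uniform(0, 1, (25, 3))
        a = augment_null_genes(expr, 50, seed=9)
        b = augment_null_genes(expr, 50, seed=9)
        np.testing.assert_array_equal(a, b)
        c = augment_null_genes(expr, 50, seed=10)
        assert not np.array_equal(a, c)


class TestBetaNullFit:
    def test_parameter_recovery(self):
        scores = stats.beta.rvs(2, 5, size=10000, random_state=7)
        fit = fit_beta_null(scores, scale=1.0)
        assert fit.a == pytest.approx(2.0, rel=0.10)
        assert fit.b == pytest.approx(5.0, rel=0.10)

    def test_top_score_has_positive_survival(self, rng):
        scores = rng.gamma(2.0, 1.0, size=500)
        fit = fit_beta_null(scores)
        p = score_pvalues(np.array([scores.max()]), fit)
        assert 0 < p[0] < 1

    def test_fitted_on_flag(self, rng):
        scores = rng.gamma(2.0, 1.0, size=100)
        assert fit_beta_null(scores).fitted_on == "all_genes"
        assert fit_beta_null(scores, fitted_on="generated_nulls").fitted_on == "generated_nulls"

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_null(np.full(100, 0.3))

    def test_too_few_scores_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_beta_null(rng.uniform(0, 1, 5))


class TestScorePvalues:
    def test_monotone_nonincreasing_in_score(self, rng):
        scores = np.sort(rng.gamma(2.0, 1.0, size=200))
        fit = fit_beta_null(scores)
        p = score_pvalues(scores, fit)
        assert (np.diff(p) <= 1e-15).all()
        assert p.argmin() == scores.argmax()

    def test_zero_score_has_p_one(self, rng):
        fit = fit_beta_null(rng.gamma(2.0, 1.0, size=100))
        assert score_pvalues(np.array([0.0]), fit)[0] == 1.0


class TestRunBsp:
    def test_patterned_gene_tops_permuted_nulls(self, rng):
        # one hot-region gene at FC 5 among 499 permuted copies on a 20x20 grid
        side = 20
        xs = np.arange(side, dtype=float)
        coords = np.array([[x, y] for x in xs for y in xs])
        hot = (np.abs(coords[:, 0] - 10) < 3) & (np.abs(coords[:, 1] - 10) < 3)
        base = rng.gamma(2.0, 1.0, size=side * side)
        patterned = base * np.where(hot, 5.0, 1.0)
        nulls = np.column_stack([rng.permutation(patterned) for _ in range(499)])
        ds = SpatialDataset(coords=coords, expr=np.column_stack([patterned, nulls]))
        table = run_bsp(ds, BspConfig(seed=1))
        assert table.score.argmax() == 0
        assert table.p_value[0] < 0.05

    def test_small_gene_set_uses_generated_nulls(self, rng):
        # 28-gene regime: the beta must be fit on generated permutation nulls
        ds = SpatialDataset(coords=rng.uniform(0, 6, (80, 2)), expr=rng.gamma(2, 1, (80, 28)))
        table = run_bsp(ds, BspConfig(null_pool_size=2000, seed=0))
        assert table.attrs["beta_fit"].fitted_on == "generated_nulls"
        assert table.attrs["beta_fit"].n_scores <= 2000
        assert len(table) == 28

    def test_large_gene_set_fits_on_all_genes(self, rng):
        ds = SpatialDataset(coords=rng.uniform(0, 6, (40, 2)), expr=rng.uniform(0, 1, (40, 1200)))
        table = run_bsp(ds)
        assert table.attrs["beta_fit"].fitted_on == "all_genes"

    def test_output_contract(self, rng):
        ds = SpatialDataset(coords=rng.uniform(0, 6, (40, 2)), expr=rng.uniform(0, 1, (40, 30)))
        table = run_bsp(ds)
        assert list(table.columns) == [
            "gene_id", "sigma_D1", "sigma_D2", "weight", "score",
            "p_value", "p_adjusted", "is_svg",
        ]
        assert ((table.p_value >= 0) & (table.p_value <= 1)).all()
        assert ((table.p_adjusted >= table.p_value) | np.isclose(table.p_adjusted, table.p_value)).all()
        assert table.weight.max() == 1.0
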