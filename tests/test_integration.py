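"""Allometry correction, two-block PLS, RV coefficient, integration matrix, Mantel."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cellsym import (
    TwoBlockPLS,
    allometry_correct,
    integration_matrix,
    mantel_test,
    pls_permutation_test,
    rv_coefficient,
    simulate_population,
    two_block_pls,
    unit_shape_blocks,
)
from cellsym.synthetic import PopulationParams, SharedFactor
from conftest import zeroed_params


class TestAllometryCorrection:
    def test_size_orthogonal_shapes_unchanged(self, rng):
        sizes = rng.uniform(1, 2, size=50)
        xc = sizes - sizes.mean()
        shapes = rng.normal(size=(50, 10))
        shapes -= np.outer(xc, (xc @ shapes) / (xc**2).sum())  # exact zero covariance
        out = allometry_correct(shapes, sizes)
        assert np.abs(out - shapes).max() < 1e-9

    def test_recovers_linear_size_effect(self, rng):
        n = 68
        sizes = rng.uniform(1, 3, size=n)
        beta = rng.normal(size=6)
        noise = rng.normal(0, 0.05, size=(n, 6))
        shapes = 0.5 + np.outer(sizes, beta) + noise
        out = allometry_correct(shapes, sizes)
        xc = sizes - sizes.mean()
        # residual slope is zero
        slopes = (xc @ (out - out.mean(axis=0))) / (xc**2).sum()
        assert np.abs(slopes).max() < 1e-9
        # the removed component recovers beta within 2 SE
        fitted = shapes - out + out.mean(axis=0) - shapes.mean(axis=0)
        beta_hat = (xc @ (shapes - shapes.mean(axis=0))) / (xc**2).sum()
        se = np.sqrt((noise.var(axis=0, ddof=1) / (xc**2).sum()))
        assert np.all(np.abs(beta_hat - beta) < 2.5 * se + 1e-3)
        assert np.allclose(fitted, np.outer(xc, beta_hat), atol=1e-9)

    def test_output_mean_is_consensus(self, rng):
        shapes = rng.normal(size=(30, 8))
        sizes = rng.uniform(1, 2, size=30)
        out = allometry_correct(shapes, sizes)
        assert np.allclose(out.mean(axis=0), shapes.mean(axis=0), atol=1e-12)

    def test_output_uncorrelated_with_size(self, rng):
        shapes = rng.normal(size=(40, 8)) + np.outer(rng.uniform(1, 2, 40), rng.normal(size=8))
        sizes = rng.uniform(1, 2, size=40)
        shapes += np.outer(sizes, rng.normal(size=8))
        out = allometry_correct(shapes, sizes)
        xc = sizes - sizes.mean()
        corr = (xc @ (out - out.mean(axis=0))) / (
            np.linalg.norm(xc) * np.linalg.norm(out - out.mean(axis=0), axis=0)
        )
        assert np.abs(corr).max() < 1e-10

    def test_zero_size_variance_warns_identity(self, rng):
        shapes = rng.normal(size=(10, 4))
        with pytest.warns(UserWarning, match="zero size variance"):
            out = allometry_correct(shapes, np.ones(10))
        assert np.array_equal(out, shapes)

    def test_nonpositive_sizes_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            allometry_correct(rng.normal(size=(5, 4)), np.array([1, 2, 0, 1, 1.0]))


class TestTwoBlockPLS:
    def test_identical_blocks_fully_integrated(self, rng):
        x = rng.normal(size=(30, 8))
        pls = two_block_pls(x, x)
        assert pls.correlation_ == pytest.approx(1.0, abs=1e-10)
        assert pls.rv_ == pytest.approx(1.0, abs=1e-12)

    def test_singular_value_trace_identity(self, rng):
        x, y = rng.normal(size=(40, 6)), rng.normal(size=(40, 9))
        pls = two_block_pls(x, y)
        xc, yc = x - x.mean(0), y - y.mean(0)
        cov = xc.T @ yc / 39
        assert (pls.singular_values_**2).sum() == pytest.approx(
            np.trace(cov @ cov.T), rel=1e-10
        )
        assert np.all(np.diff(pls.singular_values_) <= 1e-12)
        assert np.allclose(np.linalg.norm(pls.x_weights_, axis=0), 1.0)

    def test_sw1_maximizes_score_covariance_variational_oracle(self, rng):
        x, y = rng.normal(size=(50, 10)), rng.normal(size=(50, 12))
        pls = two_block_pls(x, y)
        xc, yc = x - x.mean(0), y - y.mean(0)
        sw1_cov = abs(np.cov(pls.x_scores_[:, 0], pls.y_scores_[:, 0])[0, 1])
        best = 0.0
        for _ in range(10_000):
            u = rng.normal(size=10)
            v = rng.normal(size=12)
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            best = max(best, abs(np.cov(xc @ u, yc @ v)[0, 1]))
        assert sw1_cov >= best - 1e-12

    def test_linear_relation_approaches_full_correlation(self, rng):
        x = rng.normal(size=(60, 8))
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        noisy = x @ q + rng.normal(0, 1e-4, size=(60, 8))
        assert two_block_pls(x, noisy).correlation_ > 0.999
        # correlation decays away from 1 as noise grows
        noisier = x @ q + rng.normal(0, 0.5, size=(60, 8))
        assert two_block_pls(x, noisier).correlation_ < two_block_pls(x, noisy).correlation_

    def test_reported_correlation_nonnegative_raw_sign_kept(self, rng):
        x = rng.normal(size=(25, 5))
        y = -x + rng.normal(0, 0.01, size=(25, 5))
        pls = two_block_pls(x, y)
        assert pls.correlation_ >= 0
        assert abs(pls.raw_correlation_) == pytest.approx(pls.correlation_)

    def test_specimen_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="specimens"):
            two_block_pls(rng.normal(size=(10, 4)), rng.normal(size=(11, 4)))

    def test_sklearn_params_interface(self):
        assert TwoBlockPLS().get_params() == {}


class TestRVCoefficient:
    def test_self_rv_is_one(self, rng):
        x = rng.normal(size=(20, 6))
        assert rv_coefficient(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_orthogonal_rotation(self, rng):
        x, y = rng.normal(size=(30, 6)), rng.normal(size=(30, 6))
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        assert rv_coefficient(x @ q, y) == pytest.approx(rv_coefficient(x, y), rel=1e-10)
        assert rv_coefficient(x, y @ q) == pytest.approx(rv_coefficient(x, y), rel=1e-10)

    def test_univariate_blocks_reduce_to_squared_pearson(self, rng):
        x, y = rng.normal(size=(40, 1)), rng.normal(size=(40, 1))
        r = np.corrcoef(x.ravel(), y.ravel())[0, 1]
        assert rv_coefficient(x, y) == pytest.approx(r**2, abs=1e-12)

    def test_zero_variance_block_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            rv_coefficient(np.ones((10, 3)), rng.normal(size=(10, 3)))


class TestPLSPermutation:
    def test_identical_blocks_reach_minimum_p(self, rng):
        x = rng.normal(size=(30, 6))
        assert pls_permutation_test(x, x, n_perm=199, seed=0) == pytest.approx(1 / 200)

    def test_same_seed_reproduces_p(self, rng):
        x, y = rng.normal(size=(25, 5)), rng.normal(size=(25, 5))
        p1 = pls_permutation_test(x, y, n_perm=199, seed=3)
        p2 = pls_permutation_test(x, y, n_perm=199, seed=3)
        assert p1 == p2

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(size=(68, 14))
            y = rng.normal(size=(68, 14))
            if pls_permutation_test(x, y, n_perm=99, seed=int(rng.integers(2**31))) <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


@pytest.fixture(scope="module")
def result(template):
    pop = simulate_population(template, PopulationParams(n_cells=14), seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return integration_matrix(pop, n_perm=49, seed=10)


class TestIntegrationMatrix:
    def test_26_units_and_run_counts(self, template, result):
        assert len(template.analysis_units()) == 26
        runs = result.runs
        within = runs[runs["kind"] == "within"]
        counts = within.groupby(["role_a", "role_b"]).size()
        assert (counts == 4).all()  # four quadrant-level runs per within pair
        assert len(counts) == 21  # 7 roles choose 2

    def test_matrices_symmetric_with_masked_diagonal(self, result):
        m = result.within_pls
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)
        assert np.isnan(np.diag(m.to_numpy())).all()
        assert not np.isnan(np.diag(result.cross_pls.to_numpy())).any()

    def test_values_in_range(self, result):
        for m in (result.within_pls, result.cross_pls):
            v = m.to_numpy()
            assert np.nanmin(v) >= -1 and np.nanmax(v) <= 1
        for m in (result.within_rv, result.cross_rv):
            v = m.to_numpy()
            assert np.nanmin(v) >= 0 and np.nanmax(v) <= 1

    def test_shared_latent_factor_ground_truth(self, template):
        # a latent factor shared by the b1 and b2 roles of each semicell:
        # their within-semicell integration must top every cross-semicell
        # pair, and cross-semicell pairs must mostly stay non-significant
        params = zeroed_params(
            n_cells=40,
            n_replicates=1,
            sd_measurement_error=0.12,
            shared_factors=(SharedFactor(roles=("b1", "b2"), sd=0.6),),
        )
        pop = simulate_population(template, params, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = integration_matrix(pop, n_perm=99, seed=12, allometry="off")
        target = res.within_pls.loc["b1", "b2"]
        assert target > np.nanmax(res.cross_pls.to_numpy())
        cross_runs = res.runs[res.runs["kind"] == "cross"]
        frac_ns = (cross_runs["p"] > 0.05).mean()
        assert frac_ns >= 0.9

    def test_quadrant_relabeling_invariance(self, template):
        # reflecting every cell across the vertical axis relabels quadrants
        # (a<->b, d<->c) but must not change the averaged matrices
        from cellsym.geometry import apply_labeled_reflection
        from cellsym.synthetic import Population

        pop = simulate_population(template, PopulationParams(n_cells=10), seed=13)
        flipped_coords = apply_labeled_reflection(
            pop.coords.reshape(-1, 208, 2), template.vertical_map
        ).reshape(pop.coords.shape)
        flipped = Population(
            coords=flipped_coords, cell_ids=pop.cell_ids, template=template,
            params=pop.params, ledger={},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = integration_matrix(pop, n_perm=0, seed=1)
            b = integration_matrix(flipped, n_perm=0, seed=1)
        assert np.allclose(
            a.within_pls.to_numpy(), b.within_pls.to_numpy(), equal_nan=True, atol=1e-8
        )
        assert np.allclose(
            a.cross_rv.to_numpy(), b.cross_rv.to_numpy(), equal_nan=True, atol=1e-8
        )


class TestMantel:
    @staticmethod
    def _sym(rng, m=7):
        a = rng.normal(size=(m, m))
        a = (a + a.T) / 2
        np.fill_diagonal(a, np.nan)
        return a

    def test_self_and_affine_correlation_one(self, rng):
        a = self._sym(rng)
        r, _ = mantel_test(a, a, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        r, _ = mantel_test(a, 2 * a + 3, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            a, b = self._sym(rng), self._sym(rng)
            _, p = mantel_test(a, b, n_perm=99, seed=int(rng.integers(2**31)))
            if p <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_statistic_matches_scikit_bio(self, rng):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        # build hollow symmetric non-negative matrices (distance-like)
        a, b = np.abs(self._sym(rng)), np.abs(self._sym(rng))
        np.fill_diagonal(a, 0.0)
        np.fill_diagonal(b, 0.0)
        r_ours, _ = mantel_test(a, b, n_perm=0, seed=0)
        r_skbio = skbio_mantel(a, b, method="pearson", permutations=0)[0]
        assert r_ours == pytest.approx(r_skbio, rel=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="square"):
            mantel_test(np.ones((3, 3)), np.ones((4, 4)))
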