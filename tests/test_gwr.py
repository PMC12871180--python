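"""Kernels, local weighted least squares, AICc, bandwidth selection,
global baselines and model metrics."""

import math

import numpy as np
import pytest

import morphgwr as mg
from morphgwr.errors import (
    DegenerateInputError,
    LocalSingularityError,
    ValidationError,
)


def random_table(rng, n=25, p=2, spread=50.0):
    coords = rng.uniform(0, spread, (n, 2))
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    y = rng.normal(size=n)
    return mg.ObservationTable(y=y, X=X, coords=coords)


class TestKernelWeight:
    @pytest.mark.parametrize("family", ["gaussian", "bisquare"])
    def test_unit_weight_at_zero_distance(self, family):
        spec = mg.KernelSpec(family, 10.0)
        assert mg.kernel_weight(0.0, spec) == pytest.approx(1.0)

    def test_bisquare_compact_support(self):
        spec = mg.KernelSpec("bisquare", 10.0)
        assert mg.kernel_weight(10.0, spec) == 0.0
        assert mg.kernel_weight(15.0, spec) == 0.0

    def test_bisquare_half_bandwidth(self):
        spec = mg.KernelSpec("bisquare", 10.0)
        assert mg.kernel_weight(5.0, spec) == pytest.approx(0.5625)

    def test_gaussian_formula(self):
        spec = mg.KernelSpec("gaussian", 7.0)
        d = 3.0
        assert mg.kernel_weight(d, spec) == pytest.approx(math.exp(-9 / 98))

    def test_invalid_bandwidth(self):
        with pytest.raises(ValidationError):
            mg.KernelSpec("gaussian", 0.0)


class TestWeightMatrix:
    def test_self_weight_is_one(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0], [10.0, 0.0]])
        w = mg.weight_matrix(coords, (3.0, 4.0), mg.KernelSpec("gaussian", 5.0))
        assert w[1] == pytest.approx(1.0)

    def test_huge_bandwidth_all_ones(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 100, (30, 2))
        w = mg.weight_matrix(coords, (50, 50), mg.KernelSpec("gaussian", 1e8))
        np.testing.assert_allclose(w, 1.0, atol=1e-6)

    def test_monotone_in_distance(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 100, (50, 2))
        target = (20.0, 30.0)
        for family in ("gaussian", "bisquare"):
            w = mg.weight_matrix(coords, target, mg.KernelSpec(family, 40.0))
            d = np.hypot(coords[:, 0] - target[0], coords[:, 1] - target[1])
            order = np.argsort(d)
            assert np.all(np.diff(w[order]) <= 1e-12)


class TestLocalFit:
    def test_equal_weights_reduce_to_ols(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, n=40)
        beta, _, _ = mg.local_fit(table, 0, mg.KernelSpec("gaussian", 1e8))
        ols = mg.fit_ols(table)
        np.testing.assert_allclose(beta, ols.betas, atol=1e-8)

    def test_noise_free_constant_beta_recovered_everywhere(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 50, (30, 2))
        x = rng.normal(size=30)
        y = 2.0 + 0.5 * x
        table = mg.ObservationTable.from_arrays(y, x, coords)
        for i in (0, 7, 29):
            beta, _, _ = mg.local_fit(table, i, mg.KernelSpec("gaussian", 20.0))
            np.testing.assert_allclose(beta, [2.0, 0.5], atol=1e-8)

    def test_oracle_equivalence_explicit_normal_equations(self):
        # explicit (X'WX)^{-1} X'W y solve on random small instances
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(5, 31))
            p = int(rng.integers(1, 4))
            coords = rng.uniform(0, 20, (n, 2))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]) if p > 1 \
                else np.ones((n, 1))
            y = rng.normal(size=n)
            table = mg.ObservationTable(y=y, X=X, coords=coords)
            i = int(rng.integers(n))
            spec = mg.KernelSpec("gaussian", float(rng.uniform(5, 40)))
            beta, _, _ = mg.local_fit(table, i, spec)
            w = mg.weight_matrix(coords, tuple(coords[i]), spec)
            W = np.diag(w)
            oracle = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
            np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_tiny_bandwidth_raises_localized_error(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n=20, spread=1000.0)
        with pytest.raises(LocalSingularityError) as exc:
            mg.fit_gwr(table, mg.KernelSpec("bisquare", 0.5))
        assert exc.value.location_index >= 0


class TestFitGwr:
    def test_global_limit_matches_ols(self, het_table):
        table, _ = het_table
        diam = np.hypot(*(table.coords.max(0) - table.coords.min(0)))
        fit = mg.fit_gwr(table, mg.KernelSpec("gaussian", 1e6 * diam))
        ols = mg.fit_ols(table)
        np.testing.assert_allclose(fit.betas, np.tile(ols.betas, (table.n, 1)),
                                   atol=1e-6)
        np.testing.assert_allclose(fit.fitted, ols.fitted, atol=1e-6)
        assert abs(fit.aicc - ols.aicc) < 0.1

    def test_fitted_plus_residuals_identity(self, het_table):
        table, _ = het_table
        fit = mg.fit_gwr(table, mg.KernelSpec("gaussian", 40.0))
        np.testing.assert_allclose(fit.fitted + fit.residuals, table.y, atol=1e-12)

    def test_hat_trace_bounds(self, het_table):
        table, _ = het_table
        fit = mg.fit_gwr(table, mg.KernelSpec("gaussian", 40.0))
        assert table.p <= fit.hat_trace <= table.n

    def test_local_r2_at_most_one(self, het_table):
        table, _ = het_table
        fit = mg.fit_gwr(table, mg.KernelSpec("gaussian", 40.0))
        assert np.nanmax(fit.local_r2) <= 1.0 + 1e-12

    def test_slope_surface_sign_recovery(self):
        # moderate bandwidth recovers the sign of a smooth slope field
        fields = {"m": (mg.FieldSpec("constant", 2.0),
                        mg.FieldSpec("zero-mean-sinusoid", 1.0, 192.0))}
        coords, scores, resp, truth = mg.simulate_cell_table(
            n_cells=300, shape=(384, 384), beta_fields=fields,
            noise_sd=0.1, seed=6,
        )
        table = mg.ObservationTable.from_arrays(resp["m"], scores, coords)
        fit = mg.fit_gwr(table, mg.KernelSpec("gaussian", 30.0))
        _, b1_true = truth.beta_at_centroids("m")
        strong = np.abs(b1_true) > 0.3  # sign is meaningful away from zeros
        agree = np.mean(np.sign(fit.betas[strong, 1]) == np.sign(b1_true[strong]))
        assert agree > 0.9


class TestAicc:
    def test_closed_form_arithmetic(self):
        n, rss, trs = 100, 100.0, 3.0
        sigma = math.sqrt(rss / n)
        expected = (2 * n * math.log(sigma) + n * math.log(2 * math.pi)
                    + n * (n + trs) / (n - 2 - trs))
        assert mg.aicc(n, rss, trs) == pytest.approx(expected)

    def test_monotone_in_rss(self):
        vals = [mg.aicc(50, rss, 4.0) for rss in (1.0, 5.0, 25.0, 125.0)]
        assert np.all(np.diff(vals) > 0)

    def test_saturation_error(self):
        with pytest.raises(ValidationError):
            mg.aicc(10, 1.0, 9.0)


class TestSelectBandwidth:
    def test_degenerate_interval_flagged(self, het_table):
        table, _ = het_table
        res = mg.select_bandwidth(table, b_min=50.0, b_max=50.0)
        assert res.bandwidth == 50.0
        assert res.at_boundary

    def test_constant_beta_prefers_global_limit(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 200, (150, 2))
        x = rng.normal(size=150)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.3, 150)
        table = mg.ObservationTable.from_arrays(y, x, coords)
        res = mg.select_bandwidth(table)
        assert res.at_boundary
        assert res.bandwidth == pytest.approx(res.bounds[1], rel=0.05)

    def test_heterogeneous_beta_prefers_small_bandwidth(self, het_table):
        table, _ = het_table
        res = mg.select_bandwidth(table)
        # far below the global limit
        assert res.bandwidth < 0.3 * res.bounds[1]

    def test_selected_aicc_beats_endpoints(self, het_table):
        table, _ = het_table
        res = mg.select_bandwidth(table)
        for b in res.bounds:
            aicc_b = mg.fit_gwr(table, mg.KernelSpec("gaussian", b)).aicc
            assert res.aicc <= aicc_b + 1e-6


class TestGlobalFits:
    def test_exact_linear_zero_residuals(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 10, (20, 2))
        x = rng.normal(size=20)
        table = mg.ObservationTable.from_arrays(3.0 - 1.2 * x, x, coords)
        fit = mg.fit_ols(table)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)
        # residual orthogonality to design columns
        assert np.all(np.abs(table.X.T @ fit.residuals) < 1e-8)

    def test_ridge_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, n=50)
        np.testing.assert_allclose(
            mg.fit_ridge(table, 0.0).betas, mg.fit_ols(table).betas, atol=1e-8
        )

    def test_ridge_infinite_penalty_shrinks_to_mean(self):
        rng = np.random.default_rng(10)
        table = random_table(rng, n=50)
        fit = mg.fit_ridge(table, 1e12)
        assert abs(fit.betas[1]) < 1e-6
        assert fit.fitted == pytest.approx(table.y.mean(), abs=1e-6)

    def test_negative_penalty_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValidationError):
            mg.fit_ridge(random_table(rng), -1.0)


class TestModelMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        m = mg.model_metrics(y, y)
        assert m == {"r2": 1.0, "mae": 0.0, "mse": 0.0}

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = mg.model_metrics(y, np.full(4, y.mean()))
        assert m["r2"] == pytest.approx(0.0)

    def test_hand_arithmetic_oracle(self):
        m = mg.model_metrics(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 1.0]))
        assert m["mae"] == pytest.approx(1 / 3)
        assert m["mse"] == pytest.approx(1 / 3)
        assert m["r2"] == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            mg.model_metrics(np.ones(5), np.zeros(5))


class TestResidualAutocorrelation:
    def test_gwr_whitens_residuals(self):
        fields = {"m": (mg.FieldSpec("gaussian-bump", 1.0, 128.0, offset=4.0),
                        mg.FieldSpec("zero-mean-sinusoid", 1.0, 256.0))}
        coords, scores, resp, _ = mg.simulate_cell_table(
            n_cells=300, shape=(512, 512), beta_fields=fields,
            noise_sd=0.3, seed=21,
        )
        table = mg.ObservationTable.from_arrays(resp["m"], scores, coords)
        graph = mg.build_graph(table.coords)
        ols = mg.fit_ols(table)
        sel = mg.select_bandwidth(table)
        fit = mg.fit_gwr(table, mg.KernelSpec("gaussian", sel.bandwidth))
        i_ols = mg.morans_i(ols.residuals, graph)
        i_gwr = mg.morans_i(fit.residuals, graph)
        assert abs(i_gwr) < abs(i_ols)

    def test_degenerate_residuals_flagged(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 30, (20, 2))
        graph = mg.build_graph(coords)
        with pytest.raises(DegenerateInputError):
            mg.residual_autocorrelation(np.zeros(20), graph, n_perm=99)
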