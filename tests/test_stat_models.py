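"""AT/AR statistics and their Gaussian/Gamma models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from scfia.stat_models import (
    ARModel,
    ATModel,
    DegenerateModelError,
    ScfiaModels,
    ar_density,
    at_density,
    compute_ar,
    compute_at,
    fit_ar_model,
    fit_at_model,
    load_models,
    save_models,
)
from scfia.warp import fit_gwarp, identity_warp

from conftest import make_interval, random_trace


def _feature(apex, width=5):
    t = np.arange(apex - width, apex + width + 1.0)
    y = 10.0 * np.exp(-0.5 * ((t - apex) / 2.0) ** 2)
    return make_interval(t, y)


class TestComputeAt:
    def test_identity_warp_apex_difference(self):
        assert compute_at(_feature(100.0), _feature(103.0), identity_warp()) == pytest.approx(3.0)

    def test_exact_warp_gives_zero(self):
        m = fit_gwarp([0.0, 10.0], [5.0, 25.0], degree=1)  # t2 = 2 t1 + 5
        assert compute_at(_feature(10.0), _feature(25.0), m) == pytest.approx(0.0)

    def test_antisymmetric_under_linear_warp_inversion(self):
        # forward residual equals minus the residual computed with runs
        # swapped and the line inverted (algebraic oracle on t2 = a t1 + b)
        a, b = 1.5, 20.0
        fwd = fit_gwarp([0.0, 100.0], [b, 100.0 * a + b], degree=1)
        inv = fit_gwarp([b, 100.0 * a + b], [0.0, 100.0], degree=1)
        f1, f2 = _feature(40.0), _feature(86.0)
        res_fwd = compute_at(f1, f2, fwd)
        res_inv = compute_at(f2, f1, inv)
        assert res_fwd == pytest.approx(-a * res_inv, abs=1e-9)

    def test_midpoint_landmark(self):
        f1 = _feature(100.0)
        f2 = _feature(103.0)
        assert compute_at(f1, f2, identity_warp(), landmark="midpoint") == pytest.approx(3.0)


class TestComputeAr:
    def test_identical_traces_give_one(self):
        f = _feature(50.0)
        assert compute_ar(f, f) == pytest.approx(1.0)

    def test_fifty_fold_scaling_preserves_unity(self):
        t, y = random_trace(np.random.default_rng(0))
        f1 = make_interval(t, y)
        f2 = make_interval(t, 50.0 * y)
        assert compute_ar(f1, f2) == pytest.approx(1.0, abs=1e-12)

    def test_matches_least_squares_oracle_on_fixed_vectors(self):
        f1 = make_interval(np.arange(5.0), [1.0, 2.0, 3.0, 4.0, 5.0])
        f2 = make_interval(np.arange(10.0, 15.0), [1.0, 4.0, 9.0, 5.0, 2.0])
        n_grid = 7
        y1 = np.interp(np.linspace(0, 4, n_grid), np.arange(5.0), f1.intensities)
        y2 = np.interp(np.linspace(10, 14, n_grid), np.arange(10.0, 15.0), f2.intensities)
        X = np.column_stack([np.ones(n_grid), y1])
        beta, *_ = np.linalg.lstsq(X, y2, rcond=None)
        ss_res = float(np.sum((y2 - X @ beta) ** 2))
        ss_tot = float(np.sum((y2 - y2.mean()) ** 2))
        expected = 1.0 - ss_res / ss_tot
        assert compute_ar(f1, f2, n_grid=n_grid) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_target_gives_zero(self):
        f1 = _feature(50.0)
        f2 = make_interval(np.arange(5.0), np.full(5, 3.0))
        assert compute_ar(f1, f2) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetric_and_equals_squared_pearson(self, seed):
        rng = np.random.default_rng(seed)
        f1 = make_interval(*random_trace(rng))
        f2 = make_interval(*random_trace(rng))
        fwd = compute_ar(f1, f2)
        rev = compute_ar(f2, f1)
        assert fwd == pytest.approx(rev, abs=1e-9)
        g1 = np.interp(np.linspace(f1.start_time, f1.end_time, 50), f1.times, f1.intensities)
        g2 = np.interp(np.linspace(f2.start_time, f2.end_time, 50), f2.times, f2.intensities)
        r = np.corrcoef(g1, g2)[0, 1]
        assert fwd == pytest.approx(r * r, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           scale=st.floats(0.01, 50.0), offset=st.floats(-10.0, 100.0))
    def test_invariant_to_affine_intensity_transforms(self, seed, scale, offset):
        rng = np.random.default_rng(seed)
        t, y = random_trace(rng)
        f1 = make_interval(t, y)
        f2 = make_interval(*random_trace(rng))
        base = compute_ar(f1, f2)
        transformed = compute_ar(make_interval(t, scale * y + offset), f2)
        assert transformed == pytest.approx(base, abs=1e-9)


class TestFitAtModel:
    def test_hand_computed_example(self):
        m = fit_at_model([-1.0, 0.0, 1.0])
        assert (m.mu, m.sigma) == (0.0, 1.0)

    def test_translation_equivariance(self):
        base = fit_at_model([-1.0, 0.5, 2.0])
        shifted = fit_at_model([-1.0 + 7.0, 0.5 + 7.0, 2.0 + 7.0])
        assert shifted.mu == pytest.approx(base.mu + 7.0)
        assert shifted.sigma == pytest.approx(base.sigma)

    def test_monte_carlo_recovery_at_training_size(self):
        rng = np.random.default_rng(270)
        m = fit_at_model(rng.normal(0.0, 5.0, 270))
        assert abs(m.mu) <= 1.0
        assert m.sigma == pytest.approx(5.0, rel=0.15)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateModelError):
            fit_at_model(np.full(10, 3.0))


class TestFitArModel:
    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, 0.05, 270)
        m = fit_ar_model(1.0 - x)
        assert m.k == pytest.approx(2.0, rel=0.30)
        assert m.k * m.theta == pytest.approx(0.10, rel=0.15)

    def test_all_perfect_correlations_degenerate(self):
        with pytest.raises(DegenerateModelError):
            fit_ar_model(np.ones(20))

    def test_fitted_density_integrates_to_one(self):
        rng = np.random.default_rng(4)
        m = fit_ar_model(1.0 - rng.gamma(2.0, 0.05, 100))
        total, _ = integrate.quad(
            lambda x: stats.gamma.pdf(x, a=m.k, scale=m.theta), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestDensities:
    def test_gaussian_maximum_at_mu(self):
        m = ATModel(mu=2.0, sigma=3.0)
        assert at_density(m, 2.0) == pytest.approx(1.0 / (3.0 * np.sqrt(2 * np.pi)))

    def test_gaussian_symmetry(self):
        m = ATModel(mu=1.0, sigma=2.0)
        assert at_density(m, 1.0 + 0.7) == pytest.approx(at_density(m, 1.0 - 0.7))

    def test_gaussian_matches_reference_pdf(self):
        m = ATModel(mu=-3.0, sigma=4.5)
        x = np.random.default_rng(0).normal(0, 10, 100)
        np.testing.assert_allclose(at_density(m, x), stats.norm.pdf(x, -3.0, 4.5), atol=1e-12)

    def test_gamma_exponential_special_case(self):
        m = ARModel(k=1.0, theta=0.2)
        x = 0.13
        assert ar_density(m, 1.0 - x) == pytest.approx(np.exp(-x / 0.2) / 0.2, rel=1e-12)

    def test_gamma_mode_at_k_minus_one_theta(self):
        m = ARModel(k=3.0, theta=0.05)
        xs = np.linspace(1e-4, 1.0, 20001)
        dens = stats.gamma.pdf(xs, a=m.k, scale=m.theta)
        assert xs[np.argmax(dens)] == pytest.approx((m.k - 1) * m.theta, abs=1e-3)

    def test_gamma_matches_reference_pdf(self):
        m = ARModel(k=2.5, theta=0.08)
        ar = np.random.default_rng(1).uniform(0, 1, 100)
        expected = stats.gamma.pdf(np.clip(1 - ar, m.x_floor, None), a=2.5, scale=0.08)
        np.testing.assert_allclose(ar_density(m, ar), expected, atol=1e-10)

    def test_floor_applied_near_perfect_correlation(self):
        m = ARModel(k=2.0, theta=0.05, x_floor=1e-6)
        assert ar_density(m, 1.0) == pytest.approx(
            stats.gamma.pdf(1e-6, a=2.0, scale=0.05))


def test_models_round_trip_through_yaml(tmp_path):
    models = ScfiaModels(
        warp=fit_gwarp([0.0, 10.0, 20.0], [1.0, 21.5, 41.9], degree=2),
        at_model=ATModel(mu=0.123456789012345, sigma=4.98765),
        ar_model=ARModel(k=2.345, theta=0.0567, x_floor=1e-6),
    )
    path = tmp_path / "models.yaml"
    save_models(models, path)
    back = load_models(path)
    np.testing.assert_allclose(back.warp.coefficients, models.warp.coefficients, rtol=1e-15)
    assert back.at_model.mu == models.at_model.mu
    assert back.at_model.sigma == models.at_model.sigma
    assert back.ar_model.k == models.ar_model.k
    assert back.ar_model.theta == models.ar_model.theta
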