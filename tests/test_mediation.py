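"""Mediation effect estimation: point estimates, bootstrap, sensitivity."""

import numpy as np
import pytest

from loopmed import (
    fit_mediator_model,
    fit_outcome_model,
    fit_total_effect,
    mediate,
    sensitivity,
    sobel_ci,
    sobel_se,
)


def noiseless_triad(a=2.0, b=3.0, c_prime=1.0, reps=5):
    """Deterministic data with exact coefficients: the mediator deviates
    from a*x by a component exactly orthogonal to x in-sample."""
    x = np.tile([-1.5, -0.5, 0.5, 1.5], reps)
    u = np.tile([1.0, -1.0, -1.0, 1.0], reps)
    m = 1.0 + a * x + u
    y = 2.0 + c_prime * x + b * m
    return x, m, y


class TestModelFits:
    def test_total_effect_exact_line(self):
        x = np.arange(8.0)
        beta1, c = fit_total_effect(x, 5 * x)
        assert c == pytest.approx(5.0) and beta1 == pytest.approx(0.0)
        _, c0 = fit_total_effect(x, np.full(8, 3.0))
        assert c0 == pytest.approx(0.0)

    def test_total_effect_closed_form(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        _, c = fit_total_effect(x, y)
        assert c == pytest.approx(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))

    def test_mediator_linear_slope(self):
        x = np.arange(10.0)
        model = fit_mediator_model(x, 2 * x, "linear")
        assert model.coef[1] == pytest.approx(2.0)

    def test_spline_fits_cubic_exactly(self):
        x = np.linspace(-1, 1, 100)
        model = fit_mediator_model(x, x**3, "spline")
        rmse = np.sqrt(np.mean((model.predict(x) - x**3) ** 2))
        assert rmse < 0.05

    def test_spline_nests_linear(self):
        x = np.linspace(0, 1, 50)
        m = 3.0 + 0.7 * x
        model = fit_mediator_model(x, m, "spline")
        assert np.allclose(model.predict(x), m, atol=1e-8)

    def test_outcome_model_coefficients(self, rng):
        x = rng.normal(size=40)
        m = rng.normal(size=40)
        y = 3 * m + 1 * x
        model = fit_outcome_model(x, m, y, "linear")
        assert model.coef[1] == pytest.approx(1.0, abs=1e-10)  # c'
        assert model.coef[2] == pytest.approx(3.0, abs=1e-10)  # b

    def test_outcome_only_mediator(self, rng):
        x, m = rng.normal(size=30), rng.normal(size=30)
        model = fit_outcome_model(x, m, 2 * m, "linear")
        assert model.coef[1] == pytest.approx(0.0, abs=1e-10)

    def test_outcome_matches_normal_equations(self, rng):
        x, m = rng.normal(size=60), rng.normal(size=60)
        y = rng.normal(size=60)
        design = np.column_stack([np.ones(60), x, m])
        expected = np.linalg.solve(design.T @ design, design.T @ y)
        model = fit_outcome_model(x, m, y, "linear")
        assert np.allclose(model.coef, expected, atol=1e-10)

    def test_collinear_mediator_raises(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError):
            fit_outcome_model(x, 2 * x, x, "linear")


class TestMediate:
    def test_noiseless_exact_effects(self):
        x, m, y = noiseless_triad(a=2, b=3, c_prime=1)
        r = mediate(x, m, y, seed=0, n_boot=200)
        assert r.acme == pytest.approx(6.0, abs=1e-9)
        assert r.ade == pytest.approx(1.0, abs=1e-9)
        assert r.te == pytest.approx(7.0, abs=1e-9)

    def test_effect_decomposition_identity(self, rng):
        """te = acme + ade and c = a*b + c' to 1e-10 on random data."""
        for _ in range(50):
            n = int(rng.integers(10, 60))
            x = rng.normal(size=n)
            m = rng.normal(size=n) + rng.uniform(-2, 2) * x
            y = rng.normal(size=n) + rng.uniform(-2, 2) * x + rng.uniform(-2, 2) * m
            r = mediate(x, m, y, seed=1, n_boot=100)
            assert abs(r.te - (r.acme + r.ade)) < 1e-10
            assert abs(r.c - (r.a * r.b + r.c_prime)) < 1e-10

    def test_null_mediator_calibrated(self, rng):
        """With b = 0 (mediator pure noise) the ACME interval covers 0 and
        acme_p > 0.05 in >= 90% of simulations."""
        ok = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(size=100)
            m = rng.normal(size=100)
            y = 0.5 * x + rng.normal(size=100)
            r = mediate(x, m, y, n_boot=500, seed=int(rng.integers(2**31)))
            ok += (r.acme_ci[0] <= 0 <= r.acme_ci[1]) and (r.acme_p > 0.05)
        assert ok / n_sim >= 0.90

    def test_bootstrap_reproducible_under_seed(self, rng):
        x = rng.normal(size=40)
        m = 0.5 * x + rng.normal(size=40)
        y = 0.5 * m + rng.normal(size=40)
        r1 = mediate(x, m, y, n_boot=300, seed=123)
        r2 = mediate(x, m, y, n_boot=300, seed=123)
        assert r1.acme_ci == r2.acme_ci
        assert (r1.acme_p, r1.ade_p, r1.te_p) == (r2.acme_p, r2.ade_p, r2.te_p)

    def test_point_estimates_invariant_to_sample_order(self, rng):
        x = rng.normal(size=50)
        m = 0.6 * x + rng.normal(size=50)
        y = 0.7 * m + 0.2 * x + rng.normal(size=50)
        perm = rng.permutation(50)
        r1 = mediate(x, m, y, seed=5, n_boot=200)
        r2 = mediate(x[perm], m[perm], y[perm], seed=5, n_boot=200)
        for attr in ("acme", "ade", "te", "a", "b", "c_prime", "sobel_se"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr), abs=1e-10)

    def test_spline_route_near_linear_truth(self, rng):
        """On linear data the spline route agrees with the linear one."""
        x = rng.normal(size=150)
        m = 0.8 * x + 0.5 * rng.normal(size=150)
        y = 0.7 * m + 0.3 * x + 0.5 * rng.normal(size=150)
        lin = mediate(x, m, y, seed=3, n_boot=100)
        spl = mediate(x, m, y, kind_m="spline", kind_y="spline", seed=3, n_boot=100)
        assert spl.acme == pytest.approx(lin.acme, abs=0.15)
        assert spl.te == pytest.approx(spl.acme + spl.ade, abs=1e-8)

    def test_mediate_validates_inputs(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError):
            mediate(x, x, x, n_boot=50, seed=0)
        with pytest.raises(ValueError):
            mediate(x, x[:10], x, seed=0)


class TestSobel:
    def test_arithmetic(self):
        assert sobel_se(2, 3, 0.1, 0.2) == pytest.approx(0.5)
        assert sobel_se(2, 3, 0, 0) == 0.0

    def test_agrees_with_bootstrap_sd(self, rng):
        x = rng.normal(size=1000)
        m = 0.5 * x + rng.normal(size=1000)
        y = 0.5 * m + 0.2 * x + rng.normal(size=1000)
        r = mediate(x, m, y, n_boot=1000, seed=8)
        model_m = fit_mediator_model(x, m, "linear")
        model_y = fit_outcome_model(x, m, y, "linear")
        se = sobel_se(
            model_m.coef[1], model_y.coef[2], model_m.coef_se[1], model_y.coef_se[2]
        )
        boot_sd = (r.acme_ci[1] - r.acme_ci[0]) / (2 * 1.959964)
        assert se == pytest.approx(boot_sd, rel=0.15)

    def test_ci_arithmetic_and_nesting(self):
        lo, hi = sobel_ci(6.0, 0.5, 0.95)
        assert lo == pytest.approx(6 - 1.959964 * 0.5, abs=1e-5)
        assert hi == pytest.approx(6 + 1.959964 * 0.5, abs=1e-5)
        assert sobel_ci(1.0, 0.0, 0.95) == (1.0, 1.0)
        lo90, hi90 = sobel_ci(6.0, 0.5, 0.90)
        assert lo < lo90 < hi90 < hi


class TestSensitivity:
    def test_rho_zero_recovers_ignorability_estimate(self, rng):
        x = rng.normal(size=200)
        m = 0.5 * x + rng.normal(size=200)
        y = 0.6 * m + 0.3 * x + rng.normal(size=200)
        r = mediate(x, m, y, seed=2, n_boot=100)
        curve = sensitivity(x, m, y)
        mid = np.argmin(np.abs(curve.rho_grid))
        assert curve.rho_grid[mid] == pytest.approx(0.0)
        assert curve.acme_at_rho[mid] == pytest.approx(r.acme, abs=1e-8)

    def test_monotone_in_rho(self, rng):
        for _ in range(20):
            x = rng.normal(size=80)
            m = rng.uniform(-1, 1) * x + rng.normal(size=80)
            y = rng.uniform(-1, 1) * m + rng.uniform(-1, 1) * x + rng.normal(size=80)
            curve = sensitivity(x, m, y)
            diffs = np.diff(curve.acme_at_rho)
            assert np.all(diffs <= 1e-12) or np.all(diffs >= -1e-12)

    def test_recovers_planted_confounding(self, rng):
        """Errors of the mediator and outcome correlated at 0.5 with no true
        mediation: the ACME crosses zero near rho = 0.5."""
        zeros = []
        for _ in range(10):
            n = 500
            x = rng.normal(size=n)
            e2 = rng.normal(size=n)
            e3 = 0.5 * e2 + np.sqrt(1 - 0.25) * rng.normal(size=n)
            m = 0.8 * x + e2
            y = 0.4 * x + e3  # no b*m term: observed mediation is spurious
            curve = sensitivity(x, m, y)
            assert curve.rho_zero is not None
            zeros.append(curve.rho_zero)
        assert abs(np.mean(zeros) - 0.5) < 0.15

    def test_spline_models_unsupported(self, rng):
        x = rng.normal(size=30)
        r2_grid = np.linspace(-2, 2, 5)
        with pytest.raises(ValueError):
            sensitivity(x, x + rng.normal(size=30), rng.normal(size=30), r2_grid)
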