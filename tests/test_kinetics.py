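"""Pulse-response kinetics: sibling subtraction, polynomial input, both
fitting methods, and the closed-form 4-ODE Heaviside-pulse solutions."""

import numpy as np
import pytest

from bmpdiversity.errors import DegenerateSolutionError, InsufficientDataError
from bmpdiversity.kinetics import (
    InducedSeries,
    Method1Fit,
    Method2Params,
    PSmadPolyInput,
    PulsePair,
    eval_method2_analytic,
    fit_gene_method2,
    fit_method1,
    fit_psmad_method2,
    fit_psmad_polynomial,
    simulate_induction,
    subtract_sibling,
    summarize_repeats,
)
from bmpdiversity.kinetics import _induction_exact
from bmpdiversity.reference import method1_repeat_fits_as_method1
from bmpdiversity.synthetic import SyntheticDesign, default_truth, gen_pulse_experiment

from conftest import method2_ode_oracle

TIMES = 60.0 * np.array([-30, -20, -10, 0, 10, 20, 35, 55, 80, 110]) + 1800.0

PSMAD_BEST_FIT = dict(k1=0.1429, k2=0.000900, k3=0.954, dPe=-76.19, dPo=264.1)


class TestSubtractSibling:
    def test_identical_arms_zero(self):
        pair = PulsePair("g", 1, TIMES, np.full(10, 5.0), np.full(10, 5.0))
        np.testing.assert_array_equal(subtract_sibling(pair).values, np.zeros(10))

    def test_linearity(self, rng):
        base = rng.normal(100, 10, 10)
        pulse = rng.normal(50, 5, 10)
        pair = PulsePair("g", 1, TIMES, base, base + pulse)
        np.testing.assert_allclose(subtract_sibling(pair).values, pulse, rtol=1e-12)

    def test_subtract_then_average_matches_brute_force(self, rng):
        pairs = [
            PulsePair("g", r, TIMES, rng.normal(100, 10, 10), rng.normal(150, 10, 10))
            for r in (1, 2, 3)
        ]
        mean_sub = np.mean([subtract_sibling(p).values for p in pairs], axis=0)
        brute = sum(p.injected - p.uninjected for p in pairs) / 3.0
        np.testing.assert_allclose(mean_sub, brute, rtol=1e-12)


class TestPolynomialInput:
    def test_exact_quintic_recovery(self):
        true = np.array([1e-16, -3e-12, 2e-9, 1e-5, 0.05, 12.0])
        vals = np.polyval(true, TIMES)
        poly = fit_psmad_polynomial(InducedSeries("psmad", 1, TIMES, vals))
        np.testing.assert_allclose(poly.coefficients, true, rtol=1e-8)

    def test_constant_series(self):
        poly = fit_psmad_polynomial(InducedSeries("psmad", 1, TIMES, np.full(10, 4.5)))
        np.testing.assert_allclose(np.polyval(poly.coefficients, TIMES), 4.5, atol=1e-8)

    def test_normal_equations_residual_orthogonality(self, rng):
        vals = rng.normal(100, 30, 10)
        poly = fit_psmad_polynomial(InducedSeries("psmad", 1, TIMES, vals))
        resid = vals - np.polyval(poly.coefficients, TIMES)
        # scale columns as polyfit does, then residuals _|_ column space
        V = np.vander(TIMES, 6)
        V = V / np.linalg.norm(V, axis=0)
        assert np.max(np.abs(V.T @ resid)) < 1e-6 * np.linalg.norm(vals)

    def test_clamped_outside_window(self):
        poly = PSmadPolyInput(np.array([0, 0, 0, 0, 1.0, 0.0]), window=(0.0, 100.0))
        assert poly(150.0) == poly(100.0)
        assert poly(-50.0) == poly(0.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_psmad_polynomial(InducedSeries("p", 1, TIMES[:5], np.ones(5)))


class TestSimulateInduction:
    def test_constant_input_closed_form(self):
        poly = PSmadPolyInput([0, 0, 0, 0, 0, 500.0], window=(0.0, 10000.0))
        t = np.linspace(0, 8000, 30)
        out = simulate_induction(poly, 0.0004, 0.0008, 0.0, t)
        expected = 250.0 * (1.0 - np.exp(-0.0008 * t))
        np.testing.assert_allclose(out, expected, rtol=1e-7, atol=1e-7)
        assert expected[-1] == pytest.approx(250.0, rel=0.01)

    def test_zero_sigma_pure_decay(self):
        poly = PSmadPolyInput([0, 0, 0, 0, 0, 500.0], window=(0.0, 10000.0))
        t = np.linspace(0, 5000, 20)
        out = simulate_induction(poly, 0.0, 0.002, 80.0, t)
        np.testing.assert_allclose(out, 80.0 * np.exp(-0.002 * t), rtol=1e-7)

    def test_agrees_with_rk4_oracle(self, rng):
        coeffs = rng.normal(0, 1, 6) * np.array([1e-16, 1e-12, 1e-9, 1e-5, 1e-2, 10])
        poly = PSmadPolyInput(coeffs, window=(float(TIMES[0]), float(TIMES[-1])))
        sigma, lam, To0 = 0.0004, 0.0008, -50.0
        out = simulate_induction(poly, sigma, lam, To0, TIMES)
        # independent fixed-step RK4 at two resolutions (Richardson check)
        def rk4(n_steps):
            ts = np.linspace(TIMES[0], TIMES[-1], n_steps + 1)
            h = ts[1] - ts[0]
            y = To0
            ys = [y]
            f = lambda t, y: sigma * poly(t) - lam * y
            for t in ts[:-1]:
                k1 = f(t, y)
                k2 = f(t + h / 2, y + h * k1 / 2)
                k3 = f(t + h / 2, y + h * k2 / 2)
                k4 = f(t + h, y + h * k3)
                y = y + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
                ys.append(y)
            return np.interp(TIMES, ts, ys)

        fine = rk4(4096)
        scale = np.max(np.abs(fine))
        assert np.max(np.abs(rk4(2048) - fine)) / scale < 1e-6
        assert np.max(np.abs(out - fine)) / scale < 1e-6

    def test_exact_forward_model_matches_adaptive_solver(self, rng):
        coeffs = rng.normal(0, 1, 6) * np.array([1e-16, 1e-12, 1e-9, 1e-5, 1e-2, 10])
        poly = PSmadPolyInput(coeffs, window=(float(TIMES[0]), float(TIMES[-1])))
        for sigma, lam, To0 in [(0.0004, 0.0008, 0.0), (1e-5, 1e-5, 100.0),
                                (0.05, 0.1, -100.0)]:
            a = _induction_exact(poly, sigma, lam, To0, TIMES)
            b = simulate_induction(poly, sigma, lam, To0, TIMES)
            assert np.max(np.abs(a - b)) <= 1e-8 * max(1.0, np.max(np.abs(b)))


@pytest.fixture(scope="module")
def zero_noise_setup():
    design = SyntheticDesign(noise_sd_counts=0.0, noise_sd_intensity=0.0, seed=7)
    truth = default_truth(design)
    exp = gen_pulse_experiment(truth, design)
    H = subtract_sibling(exp.psmad[0])
    poly = fit_psmad_polynomial(H)
    return truth, exp, poly


@pytest.fixture(scope="module")
def zero_noise_experiment():
    design = SyntheticDesign(noise_sd_counts=0.0, noise_sd_intensity=0.0, seed=3)
    truth = default_truth(design)
    return truth, gen_pulse_experiment(truth, design)


class TestFitMethod1:

    def test_noiseless_self_consistency_recovery(self, zero_noise_setup):
        _, _, poly = zero_noise_setup
        sigma, lam, To0 = 0.0004, 0.0008, -50.0
        L = InducedSeries(
            "syn", 1, TIMES, simulate_induction(poly, sigma, lam, To0, TIMES)
        )
        fit = fit_method1(L, poly)
        assert fit.sigma == pytest.approx(sigma, rel=0.05)
        assert fit.lam == pytest.approx(lam, rel=0.05)
        assert fit.To0 == pytest.approx(To0, rel=0.05)
        assert fit.r2 >= 0.999

    def test_zero_response_pins_sigma_at_lower_bound(self, zero_noise_setup):
        _, _, poly = zero_noise_setup
        fit = fit_method1(InducedSeries("null", 1, TIMES, np.zeros(10)), poly)
        assert fit.sigma == pytest.approx(1e-5, rel=0.05)

    def test_perfect_fit_r2_is_one(self, zero_noise_setup):
        _, _, poly = zero_noise_setup
        L = InducedSeries(
            "syn", 1, TIMES, simulate_induction(poly, 0.0003, 0.0007, 10.0, TIMES)
        )
        fit = fit_method1(L, poly)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_variance_reports_missing_r2(self, zero_noise_setup):
        _, _, poly = zero_noise_setup
        fit = fit_method1(InducedSeries("flat", 1, TIMES, np.full(10, 7.0)), poly)
        assert np.isnan(fit.r2)


class TestSummarizeRepeats:
    def test_reference_bambia_row(self):
        # bambia per-repeat sigma {0.000414, 0.000344, 0.000640}:
        # mean 0.00047, SD 0.00015; lambda mean 0.00083 at 5 decimals
        out = summarize_repeats(method1_repeat_fits_as_method1())
        row = out[out.gene == "bambia"].iloc[0]
        assert round(row.sigma_mean, 5) == 0.00047
        assert round(row.sigma_sd, 5) == 0.00015
        assert round(row.lambda_mean, 5) == 0.00083

    def test_identical_repeats_zero_sd(self):
        fits = [
            Method1Fit(0.0004, 0.0008, -20.0, 0.0, 1.0, True, gene="g", repeat=r)
            for r in (1, 2, 3)
        ]
        out = summarize_repeats(fits)
        assert out.sigma_sd.iloc[0] == 0.0
        assert out.To0_sd.iloc[0] == 0.0

    def test_single_repeat_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_repeats(
                [Method1Fit(1e-4, 1e-4, 0.0, 0.0, 1.0, True, gene="g", repeat=1)]
            )


class TestMethod2ClosedForm:
    def test_initial_conditions(self):
        p = Method2Params(**PSMAD_BEST_FIT, k4=0.001, k5=0.0005,
                          sigma=3e-4, lam=7e-4, dTe=100.0, dTo=-40.0)
        Pe0, Po0, Te0, To0 = eval_method2_analytic(p, 0.0)
        assert Pe0 == pytest.approx(p.dPe + p.k1 / p.k2, rel=1e-12)
        assert Po0 == pytest.approx(p.dPo, rel=1e-12)
        assert Te0 == pytest.approx(p.dTe + p.k1 * p.k4 / (p.k2 * p.k5), rel=1e-12)
        assert To0 == pytest.approx(p.dTo, rel=1e-12)

    def test_po_mid_pulse_best_fit_arithmetic(self):
        # with dPo = 0: Po(900) = (k3/k2)(1 - exp(-0.81)) ~ 588.4 a.u.
        p = Method2Params(k1=0.1429, k2=0.000900, k3=0.954, dPe=0.0, dPo=0.0)
        _, Po, _, _ = eval_method2_analytic(p, 900.0)
        assert Po == pytest.approx((0.954 / 0.0009) * (1 - np.exp(-0.81)), rel=1e-12)
        assert Po == pytest.approx(588.45, abs=0.01)

    def test_continuity_across_pulse_end(self):
        p = Method2Params(**PSMAD_BEST_FIT, k4=0.001, k5=0.0005,
                          sigma=3e-4, lam=7e-4, dTe=100.0, dTo=-40.0)
        eps = 1e-6
        left = np.array(eval_method2_analytic(p, p.t_L - eps))
        right = np.array(eval_method2_analytic(p, p.t_L + eps))
        np.testing.assert_allclose(left, right, rtol=1e-6)

    def test_matches_numerical_integration_random_parameters(self):
        rng = np.random.default_rng(42)
        t = np.linspace(7.0, 3 * 1800.0, 100)  # avoid exact t=0 and t=t_L
        for _ in range(20):
            p = Method2Params(
                k1=rng.uniform(0.01, 0.5),
                k2=rng.uniform(3e-4, 3e-3),
                k3=rng.uniform(0.1, 2.0),
                k4=rng.uniform(1e-4, 5e-3),
                k5=rng.uniform(1e-4, 5e-3),
                sigma=rng.uniform(1e-5, 1e-3),
                lam=rng.uniform(1e-5, 3e-3),
                dPe=rng.uniform(-100, 100),
                dPo=rng.uniform(0, 300),
                dTe=rng.uniform(-200, 600),
                dTo=rng.uniform(-100, 100),
            )
            try:
                p.validate()
            except DegenerateSolutionError:
                continue
            ana = np.array(eval_method2_analytic(p, t))
            num = method2_ode_oracle(p, t)
            scale = np.max(np.abs(num), axis=1, keepdims=True)
            assert np.max(np.abs(ana - num) / scale) < 1e-6

    def test_degenerate_combinations_rejected(self):
        with pytest.raises(DegenerateSolutionError):
            eval_method2_analytic(
                Method2Params(k2=0.001, lam=0.001, k5=0.0005), 100.0
            )
        with pytest.raises(DegenerateSolutionError):
            eval_method2_analytic(
                Method2Params(k2=0.001, lam=0.002, k5=0.001), 100.0
            )


class TestMethod2Fitting:
    def test_psmad_round_trip(self, zero_noise_experiment):
        truth, exp = zero_noise_experiment
        fit = fit_psmad_method2(exp.psmad[0])
        for name, true in PSMAD_BEST_FIT.items():
            assert getattr(fit, name if name != "dPe" else "dPe") == pytest.approx(
                true, rel=0.01
            ), name

    def test_k3_zero_for_identical_arms(self):
        base_p = Method2Params(k1=0.1429, k2=0.0009, k3=0.0, dPe=-76.19, dPo=0.0)
        Pe, Po, _, _ = eval_method2_analytic(base_p, TIMES)
        pair = PulsePair("psmad", 1, TIMES, Pe, Pe + Po)
        fit = fit_psmad_method2(pair)
        assert abs(fit.k3) < 1e-6

    def test_psmad_descent_from_initial_guess(self, rng):
        truth_p = Method2Params(**PSMAD_BEST_FIT)
        Pe, Po, _, _ = eval_method2_analytic(truth_p, TIMES)
        noisy = PulsePair(
            "psmad", 1, TIMES,
            Pe + rng.normal(0, 20, 10), Pe + Po + rng.normal(0, 20, 10),
        )
        fit = fit_psmad_method2(noisy)
        p0 = Method2Params(k1=0.0, k2=0.00167, k3=0.0, dPe=0.0, dPo=0.0)
        Pe0, Po0, _, _ = eval_method2_analytic(p0, TIMES)
        ssd0 = np.sum((noisy.uninjected - Pe0) ** 2) + np.sum(
            (noisy.injected - Pe0 - Po0) ** 2
        )
        Pe1, Po1, _, _ = eval_method2_analytic(fit, TIMES)
        ssd1 = np.sum((noisy.uninjected - Pe1) ** 2) + np.sum(
            (noisy.injected - Pe1 - Po1) ** 2
        )
        assert ssd1 <= ssd0

    def test_gene_round_trip(self, zero_noise_experiment):
        truth, exp = zero_noise_experiment
        psmad = fit_psmad_method2(exp.psmad[0])
        fit = fit_gene_method2(exp.genes["bambia"][0], psmad)
        g = truth.kinetics["bambia"]
        assert fit.k4 == pytest.approx(g.k4, rel=0.02)
        assert fit.k5 == pytest.approx(g.k5, rel=0.02)
        assert fit.sigma == pytest.approx(g.sigma, rel=0.02)
        assert fit.lam == pytest.approx(g.lam, rel=0.02)
        assert fit.dTe == pytest.approx(g.dTe, rel=0.02)
        assert fit.dTo == pytest.approx(g.dTo, rel=0.02)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_null_endogenous_channel(self):
        p = Method2Params(**PSMAD_BEST_FIT, k4=0.0, k5=0.0005,
                          sigma=3e-4, lam=7e-4, dTe=0.0, dTo=10.0)
        _, _, Te, _ = eval_method2_analytic(p, TIMES)
        np.testing.assert_allclose(Te, 0.0, atol=1e-9)

    def test_negative_lambda_round_trips_through_fit(self):
        # unconstrained fits admit negative decay constants
        p = Method2Params(**PSMAD_BEST_FIT, k4=0.0005, k5=0.0008,
                          sigma=0.000048, lam=-0.000191, dTe=-310.9, dTo=-40.27)
        _, _, Te, To = eval_method2_analytic(p, TIMES)
        pair = PulsePair("crabp2b", 1, TIMES, Te, Te + To)
        psmad = Method2Params(**PSMAD_BEST_FIT)
        fit = fit_gene_method2(pair, psmad)
        assert fit.lam == pytest.approx(-0.000191, rel=0.02)
        assert fit.lam < 0
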