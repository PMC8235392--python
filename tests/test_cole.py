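"""Cole model evaluation, circle-fit initialization, and fitting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thawspec as ts
from thawspec.cole import fit_objective

from conftest import make_sample


class TestColeImpedance:
    def test_low_frequency_limit_is_r0(self, base_params):
        z = ts.cole_impedance(base_params, np.array([1e-9]))
        assert z[0] == pytest.approx(100.0, abs=1e-6)

    def test_closed_form_at_omega_tau_one(self):
        # alpha = 1, omega tau = 1: Z = 50 + 50/(1+j) = 75 - 25j
        p = ts.ColeParameters(100.0, 50.0, 1e-5, 1.0)
        f = 1.0 / (2 * np.pi * p.tau_s)
        z = ts.cole_impedance(p, np.array([f]))
        assert z[0] == pytest.approx(75.0 - 25.0j, abs=1e-9)

    def test_high_frequency_limit_is_rinf(self, base_params):
        z = ts.cole_impedance(base_params, np.array([1e15]))
        assert z[0] == pytest.approx(50.0, abs=1e-6)

    def test_real_part_decreasing_imag_nonpositive(self, default_grid):
        p = ts.ColeParameters(100.0, 50.0, 1e-5, 0.8)
        z = ts.cole_impedance(p, default_grid)
        assert np.all(np.diff(z.real) < 0)
        assert np.all(z.imag <= 0)

    def test_depression_angle_of_cole_arc(self):
        # circle through dense noiseless alpha=0.8 points must be depressed
        # below the real axis by (1 - alpha) * pi / 2
        alpha = 0.8
        p = ts.ColeParameters(100.0, 50.0, 1e-5, alpha)
        f = np.geomspace(1e-2, 1e12, 4001)
        z = ts.cole_impedance(p, f)
        x, y = z.real, -z.imag
        A = np.column_stack([x, y, np.ones_like(x)])
        sol, *_ = np.linalg.lstsq(A, x * x + y * y, rcond=None)
        a, b = sol[0] / 2, sol[1] / 2
        r = math.sqrt(sol[2] + a * a + b * b)
        theta = math.atan2(-b, math.sqrt(r * r - b * b))
        assert theta == pytest.approx((1 - alpha) * math.pi / 2, abs=1e-3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ts.ValidationError):
            ts.ColeParameters(50.0, 100.0, 1e-5, 0.8)  # R0 < Rinf
        with pytest.raises(ts.ValidationError):
            ts.ColeParameters(100.0, 50.0, -1e-5, 0.8)
        with pytest.raises(ts.ValidationError):
            ts.ColeParameters(100.0, 50.0, 1e-5, 1.2)


class TestInit:
    def test_noiseless_init_within_5pct(self, default_grid):
        truth = ts.ColeParameters(100.0, 50.0, 1e-5, 1.0)
        init, fallback = ts.init_cole_fit(make_sample(truth, default_grid))
        assert not fallback
        assert init.r0_ohm == pytest.approx(100.0, rel=0.05)
        assert init.rinf_ohm == pytest.approx(50.0, rel=0.05)
        assert init.tau_s == pytest.approx(1e-5, rel=0.05)

    def test_alpha_estimate_from_depression_angle(self, default_grid):
        truth = ts.ColeParameters(100.0, 50.0, 1e-5, 0.7)
        init, fallback = ts.init_cole_fit(make_sample(truth, default_grid))
        assert not fallback
        assert init.alpha == pytest.approx(0.7, abs=0.1)

    def test_degenerate_spectrum_falls_back(self, default_grid):
        s = ts.ImpedanceSample(
            "d", "fast_thaw", 0.0, 4.0, default_grid,
            np.full(36, 80.0), np.zeros(36),
        )
        init, fallback = ts.init_cole_fit(s)
        assert fallback
        assert init.alpha == 0.8


class TestFit:
    BOX = list(
        itertools.product([50.0, 5000.0], [0.2, 0.9], [1e-7, 1e-5, 1e-3], [0.5, 1.0])
    )

    @pytest.mark.parametrize("r0,ratio,tau,alpha", BOX)
    def test_exact_recovery_on_noiseless_data(self, default_grid, r0, ratio, tau, alpha):
        truth = ts.ColeParameters(r0, r0 * ratio, tau, alpha)
        fit = ts.fit_cole(make_sample(truth, default_grid))
        assert fit.converged
        assert fit.params.r0_ohm == pytest.approx(truth.r0_ohm, rel=1e-6)
        assert fit.params.rinf_ohm == pytest.approx(truth.rinf_ohm, rel=1e-6)
        assert fit.params.tau_s == pytest.approx(truth.tau_s, rel=1e-6)
        assert fit.params.alpha == pytest.approx(truth.alpha, rel=1e-6)

    def test_noisy_recovery_median_error(self, default_grid):
        truth = ts.ColeParameters(100.0, 50.0, 1e-5, 0.85)
        rng = np.random.default_rng(7)
        errs_r0, errs_rinf, errs_py = [], [], []
        for _ in range(60):
            s = make_sample(truth, default_grid, noise_sd=0.01, rng=rng)
            fit = ts.fit_cole(s)
            errs_r0.append(abs(fit.params.r0_ohm - 100.0) / 100.0)
            errs_rinf.append(abs(fit.params.rinf_ohm - 50.0) / 50.0)
            errs_py.append(abs(ts.py_parameter(fit.params) - 50.0))
        assert np.median(errs_r0) < 0.05
        assert np.median(errs_rinf) < 0.05
        assert np.median(errs_py) < 1.0

    def test_no_dispersion_input_yields_zero_py(self, default_grid):
        s = ts.ImpedanceSample(
            "d", "fast_thaw", 0.0, 4.0, default_grid,
            np.full(36, 80.0), np.zeros(36),
        )
        fit = ts.fit_cole(s)
        assert (not fit.converged) or ts.py_parameter(fit.params) < 0.5

    def test_fit_objective_not_worse_than_init(self, default_grid):
        truth = ts.ColeParameters(220.0, 90.0, 3e-6, 0.75)
        rng = np.random.default_rng(3)
        s = make_sample(truth, default_grid, noise_sd=0.02, rng=rng)
        init, _ = ts.init_cole_fit(s)
        fit = ts.fit_cole(s, init=init)
        assert fit_objective(s, fit.params) <= fit_objective(s, init) + 1e-12

    def test_too_few_frequencies_rejected(self, base_params):
        g = ts.FrequencyGrid((10.0, 100.0, 1000.0, 10000.0))
        s = make_sample(base_params, g)
        with pytest.raises(ts.ValidationError):
            ts.fit_cole(s)


class TestPy:
    def test_direct_substitution(self):
        assert ts.py_parameter(ts.ColeParameters(100.0, 50.0, 1e-5, 0.8)) == 50.0

    def test_zero_when_r0_equals_rinf(self):
        assert ts.py_parameter(ts.ColeParameters(70.0, 70.0, 1e-5, 0.8)) == 0.0

    def test_roundtrip_through_fit(self, default_grid):
        # ground-truth Py = 16.0 with 1% noise recovers within +-1.0
        rinf = 50.0
        r0 = rinf / (1 - 0.16)
        truth = ts.ColeParameters(r0, rinf, 1e-5, 0.85)
        assert ts.py_parameter(truth) == pytest.approx(16.0, abs=1e-9)
        rng = np.random.default_rng(5)
        py = [
            ts.py_parameter(ts.fit_cole(make_sample(truth, default_grid, noise_sd=0.01, rng=rng)).params)
            for _ in range(20)
        ]
        assert np.median(np.abs(np.array(py) - 16.0)) < 1.0

    @given(
        rinf=st.floats(10.0, 1000.0),
        disp_hi=st.floats(1.0, 1000.0),
        shrink=st.floats(0.01, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_damage_response(self, rinf, disp_hi, shrink):
        """Shrinking the dispersion R0 - Rinf at fixed Rinf strictly lowers Py."""
        big = ts.ColeParameters(rinf + disp_hi, rinf, 1e-5, 0.8)
        small = ts.ColeParameters(rinf + disp_hi * shrink, rinf, 1e-5, 0.8)
        assert ts.py_parameter(small) < ts.py_parameter(big)
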