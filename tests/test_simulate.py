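"""Thermal model, damage dynamics, state mapping, noise model, calibration."""

import numpy as np
import pytest

import thawspec as ts
from thawspec.simulate import (
    K_FAST,
    K_SLOW,
    DamageRates,
    _py_of_damage,
    time_in_band,
)


class TestThermal:
    def test_newton_heating_limit(self):
        cfg = ts.ThermalConfig(k_rate=K_FAST, latent_boost=1.0)
        s = ts.simulate_temperature(cfg, dt=1.0)
        analytic = cfg.t_env - (cfg.t_env - cfg.t_start) * np.exp(-cfg.k_rate * s.time_s)
        assert np.max(np.abs(s.temperature_C - analytic)) < 0.1

    def test_latent_heat_plateau(self):
        s = ts.simulate_temperature(ts.ThermalConfig(k_rate=K_FAST), dt=1.0)
        rate = np.diff(s.temperature_C) / np.diff(s.time_s)
        T = s.temperature_C[1:]
        in_band = np.abs(rate[(T >= -12) & (T <= -1.5)]).mean()
        ref = np.abs(rate[(T >= -40) & (T <= -20)]).mean()
        assert in_band < ref / 3.0

    def test_fast_thaws_before_slow(self):
        fast = ts.simulate_temperature(ts.ThermalConfig(k_rate=10 * K_SLOW), dt=2.0)
        slow = ts.simulate_temperature(ts.ThermalConfig(k_rate=K_SLOW), dt=2.0)
        assert fast.time_s[-1] < slow.time_s[-1]

    def test_strictly_increasing_and_stops_at_target(self):
        s = ts.simulate_temperature(ts.ThermalConfig(k_rate=K_FAST), dt=5.0, t_stop_C=4.0)
        assert np.all(np.diff(s.temperature_C) > 0)
        assert s.temperature_C[-1] >= 4.0
        assert s.temperature_C[-2] < 4.0

    def test_unstable_dt_rejected(self):
        with pytest.raises(ts.StabilityError):
            ts.simulate_temperature(ts.ThermalConfig(k_rate=K_FAST), dt=1e4)

    def test_ice_fraction_ramp(self):
        cfg = ts.ThermalConfig()
        assert cfg.ice_fraction(-20.0) == 1.0
        assert cfg.ice_fraction(0.0) == 0.0
        band = np.linspace(-12, -1.5, 50)
        vals = [cfg.ice_fraction(t) for t in band]
        assert all(v2 <= v1 for v1, v2 in zip(vals, vals[1:]))


class TestDamage:
    def test_zero_rates_identity(self):
        cfg = ts.ThermalConfig(k_rate=K_FAST)
        s = ts.simulate_temperature(cfg, dt=5.0)
        d, d_store = ts.damage_trajectory(s, cfg, DamageRates(0.0, 0.0), storage_s=3600.0)
        assert np.all(d == 0.0) and d_store == 0.0

    def test_slow_trajectory_accrues_more_at_equal_rates(self):
        rate = DamageRates(r_transition=1e-5)
        cfg_f = ts.ThermalConfig(k_rate=K_FAST)
        cfg_s = ts.ThermalConfig(k_rate=K_SLOW)
        sf = ts.simulate_temperature(cfg_f, dt=2.0)
        ss = ts.simulate_temperature(cfg_s, dt=20.0)
        df, _ = ts.damage_trajectory(sf, cfg_f, rate)
        ds, _ = ts.damage_trajectory(ss, cfg_s, rate)
        assert ds[-1] > df[-1]
        assert time_in_band(ss, cfg_s) > time_in_band(sf, cfg_f)

    def test_storage_extension_raises_damage(self):
        cfg = ts.ThermalConfig(k_rate=K_FAST)
        s = ts.simulate_temperature(cfg, dt=5.0)
        _, d_store = ts.damage_trajectory(
            s, cfg, DamageRates(1e-5, 1e-5), storage_s=16 * 3600.0
        )
        d, _ = ts.damage_trajectory(s, cfg, DamageRates(1e-5, 0.0))
        assert d_store > d[-1]

    def test_negative_rates_rejected(self):
        with pytest.raises(ts.ValidationError):
            DamageRates(-1e-5)


class TestStateToCole:
    def test_identity_state(self, base_params):
        out = ts.state_to_cole(ts.TissueState(4.0, 0.0, 0.0), base_params)
        assert out.r0_ohm == pytest.approx(base_params.r0_ohm, rel=1e-12)
        assert out.rinf_ohm == pytest.approx(base_params.rinf_ohm, rel=1e-12)

    def test_full_damage_removes_beta_dispersion(self, base_params):
        out = ts.state_to_cole(ts.TissueState(4.0, 0.0, 1.0), base_params)
        assert ts.py_parameter(out) == 0.0

    def test_py_linear_in_dispersion(self, base_params):
        """Halving the surviving membranes halves the dispersion magnitude."""
        half = ts.state_to_cole(ts.TissueState(4.0, 0.0, 0.5), base_params)
        full = ts.state_to_cole(ts.TissueState(4.0, 0.0, 0.0), base_params)
        assert (half.r0_ohm - half.rinf_ohm) == pytest.approx(
            (full.r0_ohm - full.rinf_ohm) / 2
        )

    def test_warming_and_melting_lower_resistance(self, base_params):
        cold = ts.state_to_cole(ts.TissueState(0.0, 0.0, 0.0), base_params)
        warm = ts.state_to_cole(ts.TissueState(4.0, 0.0, 0.0), base_params)
        frozen = ts.state_to_cole(ts.TissueState(-20.0, 1.0, 0.0), base_params)
        assert cold.rinf_ohm > warm.rinf_ohm
        assert frozen.rinf_ohm > 10 * warm.rinf_ohm


class TestSynthesize:
    def test_zero_noise_is_exact_forward_model(self, default_grid, base_params):
        rng = np.random.default_rng(0)
        s = ts.synthesize_spectrum(base_params, default_grid, 0.0, rng)
        z = ts.cole_impedance(base_params, default_grid)
        np.testing.assert_array_equal(s.resistance_ohm, z.real)
        np.testing.assert_array_equal(s.reactance_ohm, z.imag)

    def test_seeded_determinism(self, default_grid, base_params):
        s1 = ts.synthesize_spectrum(base_params, default_grid, 0.01, np.random.default_rng(42))
        s2 = ts.synthesize_spectrum(base_params, default_grid, 0.01, np.random.default_rng(42))
        np.testing.assert_array_equal(s1.resistance_ohm, s2.resistance_ohm)
        np.testing.assert_array_equal(s1.reactance_ohm, s2.reactance_ohm)

    def test_noise_rms_matches_model(self, default_grid, base_params):
        """Relative complex deviation has RMS ~ noise_sd * sqrt(2) per point."""
        rng = np.random.default_rng(1)
        z = ts.cole_impedance(base_params, default_grid)
        devs = []
        for _ in range(400):
            s = ts.synthesize_spectrum(base_params, default_grid, 0.01, rng)
            zn = s.resistance_ohm + 1j * s.reactance_ohm
            devs.append(np.abs((zn - z) / z) ** 2)
        rms = np.sqrt(np.mean(devs))
        assert rms == pytest.approx(0.01 * np.sqrt(2), rel=0.1)


class TestCalibration:
    def test_inverse_identities(self, base_params):
        py_base = ts.py_parameter(base_params)
        dist = ts.calibrate_to_py((py_base * 0.999, 1e-4), base_params)
        assert dist.mu == pytest.approx(0.0, abs=0.02)
        dist = ts.calibrate_to_py((0.05, 1e-4), base_params)
        assert dist.mu == pytest.approx(1.0, abs=0.02)

    def test_infeasible_target_raises(self, base_params):
        with pytest.raises(ts.CalibrationError):
            ts.calibrate_to_py((ts.py_parameter(base_params) + 5.0, 1.0), base_params)

    @pytest.mark.parametrize("target", [(16.1, 3.90), (10.2, 3.35)])
    def test_monte_carlo_verification(self, target):
        base = ts.SimulatorConfig().base_params
        dist = ts.calibrate_to_py(target, base)
        rng = np.random.default_rng(9)
        py = _py_of_damage(dist.draw(2000, rng), base)
        assert py.mean() == pytest.approx(target[0], rel=0.05)
        assert py.std(ddof=1) == pytest.approx(target[1], rel=0.05)


class TestCohort:
    def test_seeded_determinism_through_csv(self, tmp_path):
        cfg = ts.SimulatorConfig(n_fast=2, n_slow=2, seed=21)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ts.write_spectra_csv(ts.generate_cohort(cfg), p1)
        ts.write_spectra_csv(ts.generate_cohort(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_ground_truth_py_near_targets(self, default_cohort):
        tf = ts.truth_frame(default_cohort)
        at4 = tf[(tf.stage == "thaw") & (tf.temperature_C > 3.9)]
        means = at4.groupby("treatment")["true_Py"].mean()
        # n=10 draws from the calibrated distributions: allow sampling noise
        assert means["fast_thaw"] == pytest.approx(16.1, abs=3.0)
        assert means["slow_thaw"] == pytest.approx(10.2, abs=3.0)
        assert means["fast_thaw"] > means["slow_thaw"]

    def test_magnitude_monotone_nonincreasing_along_thaw(self):
        cfg = ts.SimulatorConfig(n_fast=2, n_slow=2, seed=5, noise_sd=0.0,
                                 include_frozen_range=True)
        cohort = ts.generate_cohort(cfg)
        for tr in cohort:
            mags = np.array(
                [np.abs(s.impedance) for s in tr.thaw_samples]
            )  # (n_meas, 36)
            assert np.all(np.diff(mags, axis=0) <= 1e-9)

    def test_infeasible_config_raises_calibration_error(self):
        with pytest.raises(ts.CalibrationError):
            ts.generate_cohort(
                ts.SimulatorConfig(py_targets={"fast_thaw": (24.9, 0.1),
                                               "slow_thaw": (30.0, 1.0)})
            )
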