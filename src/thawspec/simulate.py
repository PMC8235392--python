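"""Synthetic freeze-thaw cohort generator.

The generator produces everything the analysis pipeline consumes, with the
statistical structure the analysis assumes:

* a lumped (zero-dimensional) core-temperature model with an apparent
  heat-capacity bump across the ice-melting band, reproducing the
  latent-heat plateau of real thawing curves;
* a scalar membrane-damage state per sample that accrues while the core
  is inside the melting band and, much more slowly, during post-thaw
  chilled storage;
* a mapping from thermal/damage state to Cole parameters (warming and
  melting lower the electrolyte resistance, membrane destruction shrinks
  the beta dispersion);
* multiplicative complex Gaussian measurement noise on the forward
  spectra.

Group damage distributions are calibrated so that the ground-truth Py at
4 degC matches configurable mean/SD targets per group (defaults follow
the published fast/slow summaries at the end of thawing), and next-day
targets likewise.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares

from .cole import ColeParameters, cole_impedance, py_parameter
from .errors import CalibrationError, StabilityError, ValidationError
from .io import Cohort, DripLossRecord, FrequencyGrid, ImpedanceSample, ThawTrajectory

#: default lumped heat-transfer rate constants, 1/s (water bath vs still air;
#: roughly 3 h vs 30 h to bring a 180 g piece from -75 degC to a 4 degC core)
K_FAST = 5e-4
K_SLOW = 5e-5

#: measurement schedule above freezing, degC
MEASUREMENT_TEMPS = tuple(np.arange(0.0, 4.01, 0.5))

#: optional frozen-range schedule (impedance-vs-temperature plots)
FROZEN_RANGE_TEMPS = (-60.0, -50.0, -40.0, -30.0, -25.0, -20.0, -15.0, -12.0,
                      -10.0, -8.0, -6.0, -4.0, -2.0)


@dataclass(frozen=True)
class ThermalConfig:
    """Lumped thermal model of one sample during thawing.

    dT/dt = k_rate * (t_env - T) / c_app(T), where the apparent heat
    capacity c_app is 1 outside the melting band [melt_lo, melt_hi] and
    rises to ``latent_boost`` (Gaussian bump) inside it, standing in for
    the latent heat of fusion.
    """

    t_env: float = 10.0
    k_rate: float = K_FAST
    t_start: float = -75.0
    melt_lo: float = -12.0
    melt_hi: float = -1.5
    latent_boost: float = 8.0

    def __post_init__(self) -> None:
        if not (self.t_env > self.melt_hi > self.melt_lo > self.t_start):
            raise ValidationError("need t_env > melt_hi > melt_lo > t_start")
        if self.k_rate <= 0:
            raise ValidationError("k_rate must be positive")
        if self.latent_boost < 1:
            raise ValidationError("latent_boost must be >= 1")

    def apparent_heat_capacity(self, T: float) -> float:
        mid = 0.5 * (self.melt_lo + self.melt_hi)
        sigma = (self.melt_hi - self.melt_lo) / 4.0
        return 1.0 + (self.latent_boost - 1.0) * math.exp(-0.5 * ((T - mid) / sigma) ** 2)

    def ice_fraction(self, T: float) -> float:
        """Smooth melt ramp: 1 below the band, 0 above, an integrated
        Gaussian (normal CDF, renormalized to hit 0/1 at the band edges)
        across it."""
        if T <= self.melt_lo:
            return 1.0
        if T >= self.melt_hi:
            return 0.0
        mid = 0.5 * (self.melt_lo + self.melt_hi)
        sigma = (self.melt_hi - self.melt_lo) / 6.0
        lo = sps.norm.cdf((self.melt_lo - mid) / sigma)
        hi = sps.norm.cdf((self.melt_hi - mid) / sigma)
        raw = sps.norm.cdf((T - mid) / sigma)
        return float(1.0 - (raw - lo) / (hi - lo))


@dataclass(frozen=True)
class TemperatureSeries:
    time_s: np.ndarray
    temperature_C: np.ndarray


@dataclass(frozen=True)
class TissueState:
    temperature_C: float
    ice_fraction: float
    damage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ice_fraction <= 1.0):
            raise ValidationError("ice_fraction must be in [0, 1]")
        if not (0.0 <= self.damage <= 1.0):
            raise ValidationError("damage must be in [0, 1]")


@dataclass(frozen=True)
class DamageRates:
    """Membrane-damage accrual rates, fraction per second."""

    r_transition: float
    r_storage: float = 0.0

    def __post_init__(self) -> None:
        if self.r_transition < 0 or self.r_storage < 0:
            raise ValidationError("damage rates must be non-negative")


def simulate_temperature(config: ThermalConfig, dt: float, t_stop_C: float = 4.0,
                         max_steps: int = 5_000_000) -> TemperatureSeries:
    """Explicit Euler integration of the lumped thawing model.

    The series is strictly increasing in T and ends at the first step with
    T >= t_stop_C.  In the latent-heat-free limit (latent_boost = 1) the
    trajectory is exact Newton heating,
    T(t) = t_env - (t_env - t_start) exp(-k t), up to the Euler error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_stop_C > config.t_env:
        raise ValueError("t_stop_C must not exceed t_env")
    if config.k_rate * dt >= 1.0:
        raise StabilityError(
            f"k_rate*dt = {config.k_rate * dt:.3g} >= 1; choose a smaller dt"
        )
    T = config.t_start
    times = [0.0]
    temps = [T]
    t = 0.0
    for _ in range(max_steps):
        if T >= t_stop_C:
            return TemperatureSeries(np.asarray(times), np.asarray(temps))
        step = dt * config.k_rate * (config.t_env - T) / config.apparent_heat_capacity(T)
        if not math.isfinite(step) or step <= 0:
            raise StabilityError("non-finite or non-positive step; choose a smaller dt")
        T += step
        t += dt
        times.append(t)
        temps.append(T)
    raise StabilityError("t_stop_C not reached within max_steps; t_stop too close to t_env?")


def damage_trajectory(
    series: TemperatureSeries,
    config: ThermalConfig,
    rates: DamageRates,
    storage_s: float = 0.0,
    d0: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Damage along a thawing trajectory plus its post-storage value.

    Damage accrues at ``rates.r_transition`` per second while the core is
    inside the melting band (so a slow trajectory, spending longer in the
    band, ends up more damaged at equal rates) and at ``rates.r_storage``
    per second for ``storage_s`` seconds of chilled storage afterwards;
    clipped to [0, 1].
    """
    temps = series.temperature_C
    dts = np.diff(series.time_s, prepend=series.time_s[0])
    in_band = (temps >= config.melt_lo) & (temps <= config.melt_hi)
    d = d0 + np.cumsum(rates.r_transition * dts * in_band)
    d = np.clip(d, 0.0, 1.0)
    d_storage = float(np.clip(d[-1] + rates.r_storage * storage_s, 0.0, 1.0))
    return d, d_storage


def time_in_band(series: TemperatureSeries, config: ThermalConfig) -> float:
    temps = series.temperature_C
    dts = np.diff(series.time_s, prepend=series.time_s[0])
    return float(np.sum(dts[(temps >= config.melt_lo) & (temps <= config.melt_hi)]))


# ---------------------------------------------------------------------------
# state -> Cole parameters

#: relative drop in electrolyte resistance per degC of warming
TEMP_COEFF = 0.02
#: residual conductance of frozen tissue (caps the ice factor at 51x)
ICE_EPS = 0.02
#: the linear ionic-mobility law describes the liquid/mushy regime only;
#: below the melt band the remaining temperature dependence is carried by
#: the ice factor, so the law's argument is floored here
TEMP_LAW_MIN_C = -12.0


def state_to_cole(state: TissueState, base: ColeParameters) -> ColeParameters:
    """Map a tissue state to Cole parameters, relative to the intact
    (damage 0, ice 0) state at 4 degC.

    * ``Rinf`` scales with ionic mobility, factor ``1/(1 + 0.02 (T - 4))``
      (with T floored at the top of the frozen regime, where the linear
      electrolyte law stops applying), and with the frozen-tissue factor
      ``(1 + eps) / (1 - ice + eps)`` which is exactly 1 when melted.
    * the dispersion magnitude ``R0 - Rinf`` shrinks linearly with damage:
      fully destroyed membranes (damage = 1) give R0 = Rinf, i.e. Py = 0.
    """
    t_eff = max(state.temperature_C, TEMP_LAW_MIN_C)
    f_temp = 1.0 / (1.0 + TEMP_COEFF * (t_eff - 4.0))
    f_ice = (1.0 + ICE_EPS) / (1.0 - state.ice_fraction + ICE_EPS)
    rinf = base.rinf_ohm * f_temp * f_ice
    dispersion = (base.r0_ohm - base.rinf_ohm) * (1.0 - state.damage)
    return ColeParameters(rinf + dispersion, rinf, base.tau_s, base.alpha)


def synthesize_spectrum(
    params: ColeParameters,
    grid: FrequencyGrid,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    sample_id: str = "synthetic",
    treatment: str = "fast_thaw",
    time_s: float | None = None,
    temperature_C: float = 4.0,
    max_resample_rounds: int = 100,
) -> ImpedanceSample:
    """Forward spectrum with multiplicative complex Gaussian noise.

    Z_k -> Z_k * (1 + noise_sd * (g1 + j g2)); frequencies whose noisy
    resistance is non-positive are redrawn (warned about if >1 % of points
    needed redrawing).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    z = cole_impedance(params, grid)
    n = len(grid)
    if noise_sd == 0:
        r, x = z.real.copy(), z.imag.copy()
    else:
        g = rng.standard_normal((2, n))
        zn = z * (1.0 + noise_sd * (g[0] + 1j * g[1]))
        r, x = zn.real, zn.imag
        resampled = 0
        for _ in range(max_resample_rounds):
            bad = r <= 0
            if not bad.any():
                break
            k = int(bad.sum())
            resampled += k
            g = rng.standard_normal((2, k))
            zb = z[bad] * (1.0 + noise_sd * (g[0] + 1j * g[1]))
            r[bad], x[bad] = zb.real, zb.imag
        else:
            raise ValidationError("could not draw positive resistances; noise_sd too large")
        if resampled > 0.01 * n:
            import warnings

            warnings.warn(f"{resampled}/{n} noisy points resampled for positivity")
    return ImpedanceSample(
        sample_id=sample_id,
        treatment=treatment,
        time_s=time_s,
        temperature_C=temperature_C,
        grid=grid,
        resistance_ohm=r,
        reactance_ohm=x,
    )


# ---------------------------------------------------------------------------
# calibration of damage distributions to Py targets


def _py_of_damage(d, base: ColeParameters):
    """Ground-truth Py at 4 degC (ice 0) as a function of damage."""
    disp = (base.r0_ohm - base.rinf_ohm) * (1.0 - np.asarray(d, dtype=float))
    return 100.0 * disp / (base.rinf_ohm + disp)


def _damage_of_py(py: float, base: ColeParameters) -> float:
    q = py / 100.0
    disp0 = base.r0_ohm - base.rinf_ohm
    return 1.0 - (q / (1.0 - q)) * base.rinf_ohm / disp0


@dataclass(frozen=True)
class DamageDistribution:
    """Truncated Gaussian on [0, 1] for per-sample damage."""

    mu: float
    sigma: float

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a, b = (0.0 - self.mu) / self.sigma, (1.0 - self.mu) / self.sigma
        return sps.truncnorm.rvs(a, b, loc=self.mu, scale=self.sigma, size=n, random_state=rng)


def calibrate_to_py(
    py_target: tuple[float, float], base: ColeParameters
) -> DamageDistribution:
    """Damage-distribution parameters whose induced ground-truth Py at
    4 degC has the requested (mean, sd).

    The forward map Py(damage) is mildly nonlinear and damage is truncated
    to [0, 1], so the truncated-Gaussian parameters are found by matching
    the first two moments of Py under the truncated density (deterministic
    quadrature + least squares), not by a naive linearization.
    """
    mean, sd = py_target
    py_base = py_parameter(base)
    if not (0.0 < mean < py_base):
        raise CalibrationError(
            f"target mean Py {mean} outside the achievable range (0, {py_base:.4g})"
        )
    if sd < 0:
        raise CalibrationError("target sd must be non-negative")

    d_grid = np.linspace(0.0, 1.0, 2001)
    py_grid = _py_of_damage(d_grid, base)

    def moments(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        w = sps.norm.pdf((d_grid - mu) / sigma)
        w_sum = np.trapezoid(w, d_grid)
        if w_sum <= 0:
            return np.array([1e6, 1e6])
        m1 = np.trapezoid(w * py_grid, d_grid) / w_sum
        m2 = np.trapezoid(w * py_grid**2, d_grid) / w_sum
        return m1, math.sqrt(max(m2 - m1 * m1, 0.0))

    mu0 = float(np.clip(_damage_of_py(mean, base), 0.0, 1.0))
    slope = abs(
        _py_of_damage(min(mu0 + 1e-4, 1.0), base) - _py_of_damage(max(mu0 - 1e-4, 0.0), base)
    ) / 2e-4
    sigma0 = max(sd / max(slope, 1e-9), 1e-4)
    scale = max(sd, 0.5)

    def resid(x):
        m, s = moments(x)
        return np.array([(m - mean) / scale, (s - sd) / scale])

    sol = least_squares(
        resid,
        x0=np.array([mu0, math.log(sigma0)]),
        bounds=([-2.0, math.log(1e-5)], [4.0, math.log(4.0)]),
        xtol=1e-13,
        ftol=1e-13,
        gtol=1e-13,
    )
    m, s = moments(sol.x)
    if abs(m - mean) > 0.05 * max(mean, 1.0):
        raise CalibrationError(
            f"target (mean={mean}, sd={sd}) not achievable within [0, 1] damage; "
            f"best mean {m:.3g}"
        )
    return DamageDistribution(mu=float(sol.x[0]), sigma=float(math.exp(sol.x[1])))


# ---------------------------------------------------------------------------
# cohort generation


def _default_base_params() -> ColeParameters:
    # intact tissue at 4 degC: Py(base) = 25
    return ColeParameters(r0_ohm=200.0 / 3.0, rinf_ohm=50.0, tau_s=1e-5, alpha=0.85)


@dataclass(frozen=True)
class SimulatorConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults are the experiment's conditions: 10 fast- plus 10 slow-thawed
    samples, 36 log-spaced frequencies from 10 Hz to 510 kHz, measurements
    at each 0.5 degC from 0 to 4 degC plus a next-day measurement, group
    Py distributions at 4 degC and next day set to the published
    summaries, and 1 % relative complex measurement noise.
    """

    n_fast: int = 10
    n_slow: int = 10
    grid: FrequencyGrid = field(default_factory=FrequencyGrid.default)
    base_params: ColeParameters = field(default_factory=_default_base_params)
    py_targets: dict = field(
        default_factory=lambda: {"fast_thaw": (16.1, 3.90), "slow_thaw": (10.2, 3.35)}
    )
    next_day_py_targets: dict = field(
        default_factory=lambda: {"fast_thaw": (4.65, 1.85), "slow_thaw": (3.41, 3.27)}
    )
    noise_sd: float = 0.01
    seed: int = 0
    k_fast: float = K_FAST
    k_slow: float = K_SLOW
    #: relative spread of per-sample heat-transfer rates (sample geometry)
    k_jitter_sd: float = 0.10
    #: per-group shift of the characteristic time (fast 1-s/2, slow 1+s/2)
    tau_group_shift: float = 0.2
    #: per-sample lognormal jitter of tau and of the overall ohm scale
    tau_jitter_sd: float = 0.08
    scale_jitter_sd: float = 0.05
    alpha_jitter_sd: float = 0.015
    #: drip-loss sampling (equal group means by default)
    drip_loss_mean_pct: float = 8.0
    drip_loss_sd_pct: float = 1.5
    include_frozen_range: bool = False

    def __post_init__(self) -> None:
        if self.n_fast < 1 or self.n_slow < 1:
            raise ValidationError("cohort sizes must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        for targets in (self.py_targets, self.next_day_py_targets):
            for mean, sd in targets.values():
                if not (0 < mean < 100):
                    raise ValidationError("Py targets must lie in (0, 100)")


def generate_cohort(config: SimulatorConfig) -> Cohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``.

    Per physical sample: thermal trajectory -> damage trajectory (endpoint
    drawn from the group's calibrated distribution, accrued over the
    sample's own time in the melting band) -> per-measurement Cole
    parameters -> noisy spectra at 0, 0.5, ..., 4 degC plus next day.  A
    pre-freeze reference spectrum (damage 0 at 4 degC) is attached per
    trajectory, and per-measurement ground truth is kept in
    ``cohort.metadata["truth"]``.
    """
    rng = np.random.default_rng(config.seed)
    base = config.base_params

    calib = {g: calibrate_to_py(t, base) for g, t in config.py_targets.items()}
    calib_nd = {g: calibrate_to_py(t, base) for g, t in config.next_day_py_targets.items()}

    truth: list[dict] = []
    trajectories: dict[str, ThawTrajectory] = {}

    groups = [("fast_thaw", "F", config.n_fast, config.k_fast, 1.0 - config.tau_group_shift / 2),
              ("slow_thaw", "S", config.n_slow, config.k_slow, 1.0 + config.tau_group_shift / 2)]
    for group, prefix, n, k_group, tau_factor in groups:
        for i in range(n):
            sid = f"{prefix}{i + 1:02d}"
            k = k_group * math.exp(rng.normal(0.0, config.k_jitter_sd))
            thermal = ThermalConfig(k_rate=k, t_start=float(rng.uniform(-85.0, -68.0)))
            series = simulate_temperature(thermal, dt=0.005 / k, t_stop_C=4.0)

            d4 = float(calib[group].draw(1, rng)[0])
            dnd = max(float(calib_nd[group].draw(1, rng)[0]), d4)
            band_s = time_in_band(series, thermal)
            rates = DamageRates(r_transition=d4 / band_s if band_s > 0 else 0.0)
            damage_series, _ = damage_trajectory(series, thermal, rates)

            scale = math.exp(rng.normal(0.0, config.scale_jitter_sd))
            tau_i = base.tau_s * tau_factor * math.exp(rng.normal(0.0, config.tau_jitter_sd))
            alpha_i = float(np.clip(base.alpha + rng.normal(0.0, config.alpha_jitter_sd), 0.5, 1.0))
            base_i = ColeParameters(
                r0_ohm=base.r0_ohm * scale, rinf_ohm=base.rinf_ohm * scale,
                tau_s=tau_i, alpha=alpha_i,
            )

            schedule = list(MEASUREMENT_TEMPS)
            if config.include_frozen_range:
                schedule = [t for t in FROZEN_RANGE_TEMPS if t > thermal.t_start] + schedule

            samples: list[ImpedanceSample] = []

            def record(state: TissueState, spectrum_time, label_temp, tag) -> ImpedanceSample:
                params_t = state_to_cole(state, base_i)
                s = synthesize_spectrum(
                    params_t, config.grid, config.noise_sd, rng,
                    sample_id=sid,
                    treatment="fresh" if tag == "fresh" else group,
                    time_s=spectrum_time, temperature_C=label_temp,
                )
                truth.append(
                    {
                        "sample_id": sid, "treatment": group, "stage": tag,
                        "temperature_C": label_temp,
                        "true_R0_ohm": params_t.r0_ohm, "true_Rinf_ohm": params_t.rinf_ohm,
                        "true_tau_s": params_t.tau_s, "true_alpha": params_t.alpha,
                        "true_Py": py_parameter(params_t), "damage": state.damage,
                    }
                )
                return s

            fresh = record(TissueState(4.0, 0.0, 0.0), None, 4.0, "fresh")

            for target in schedule:
                idx = int(np.searchsorted(series.temperature_C, target))
                idx = min(idx, len(series.temperature_C) - 1)
                T = float(series.temperature_C[idx])
                state = TissueState(T, thermal.ice_fraction(T), float(damage_series[idx]))
                samples.append(record(state, float(series.time_s[idx]), T, "thaw"))

            t_next = float(rng.uniform(2.0, 4.0))
            samples.append(record(TissueState(t_next, 0.0, dnd), None, t_next, "next_day"))

            initial_w = float(np.clip(rng.normal(180.0, 30.0), 80.0, None))
            loss_pct = float(np.clip(
                rng.normal(config.drip_loss_mean_pct, config.drip_loss_sd_pct), 0.1, 60.0))
            drip = DripLossRecord(
                initial_weight_g=initial_w,
                final_weight_g=initial_w * (1.0 - loss_pct / 100.0),
                storage_hours=float(rng.uniform(16.0, 26.0)),
            )
            trajectories[sid] = ThawTrajectory(
                sample_id=sid, treatment=group, samples=samples,
                fresh_ref=fresh, drip=drip,
            )

    metadata = {
        "seed": config.seed,
        "n_fast": config.n_fast,
        "n_slow": config.n_slow,
        "noise_sd": config.noise_sd,
        "py_targets": {k: list(v) for k, v in config.py_targets.items()},
        "next_day_py_targets": {k: list(v) for k, v in config.next_day_py_targets.items()},
        "truth": truth,
    }
    return Cohort(trajectories=trajectories, metadata=metadata)


def truth_frame(cohort: Cohort):
    """Ground-truth sidecar as a DataFrame (empty if absent)."""
    import pandas as pd

    return pd.DataFrame(cohort.metadata.get("truth", []))
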