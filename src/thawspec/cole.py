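"""Cole relaxation model: evaluation, fitting, and the Py statistic.

Tissue impedance around the beta dispersion is described by the
single-dispersion Cole equation

    Z(omega) = Rinf + (R0 - Rinf) / (1 + (j omega tau)^alpha)

with zero-frequency resistance ``R0``, infinite-frequency resistance
``Rinf``, characteristic time ``tau`` and broadening exponent
``alpha in (0, 1]``.  In the complex plane the locus of (R, -X) is a
circular arc whose centre is depressed below the real axis by the angle
``(1 - alpha) * pi / 2``.

The membrane-integrity statistic derived from a fitted spectrum is

    Py = (R0 - Rinf) * 100 / R0      (percent)

i.e. the relative size of the beta dispersion: intact cell membranes make
low-frequency current detour around cells (large ``R0``) while at high
frequency membrane capacitance is short-circuited (``Rinf``); membrane
destruction collapses the difference and drives Py toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ValidationError
from .io import Cohort, FrequencyGrid, ImpedanceSample


@dataclass(frozen=True)
class ColeParameters:
    """Parameters of one Cole dispersion.

    Invariants: ``r0_ohm >= rinf_ohm > 0``, ``tau_s > 0``,
    ``0 < alpha <= 1``.  Equality ``r0 == rinf`` is the degenerate
    no-dispersion limit (Py = 0), reachable when membranes are fully
    destroyed, and is deliberately constructible.
    """

    r0_ohm: float
    rinf_ohm: float
    tau_s: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.r0_ohm >= self.rinf_ohm > 0):
            raise ValidationError("need R0 >= Rinf > 0")
        if not self.tau_s > 0:
            raise ValidationError("need tau > 0")
        if not (0 < self.alpha <= 1):
            raise ValidationError("need 0 < alpha <= 1")


@dataclass(frozen=True)
class ColeFitResult:
    params: ColeParameters
    residual_rms_ohm: float
    converged: bool
    n_iter: int
    init_fallback: bool = False


class ColeInit(NamedTuple):
    params: ColeParameters
    fallback: bool


def cole_impedance(params: ColeParameters, grid: FrequencyGrid | np.ndarray) -> np.ndarray:
    """Complex impedance of the Cole model on a frequency grid (Hz)."""
    f = grid.as_array() if isinstance(grid, FrequencyGrid) else np.asarray(grid, dtype=float)
    omega_tau = 2.0 * np.pi * f * params.tau_s
    # (j w tau)^alpha on the principal branch, w tau > 0
    u = np.exp(params.alpha * (np.log(omega_tau) + 1j * np.pi / 2.0))
    return params.rinf_ohm + (params.r0_ohm - params.rinf_ohm) / (1.0 + u)


def py_parameter(params: ColeParameters) -> float:
    """Py = (R0 - Rinf) * 100 / R0, percent; in [0, 100)."""
    return py_from_resistances(params.r0_ohm, params.rinf_ohm)


def py_from_resistances(r0_ohm: float, rinf_ohm: float) -> float:
    if r0_ohm <= 0:
        raise ValidationError("R0 must be positive")
    return (r0_ohm - rinf_ohm) * 100.0 / r0_ohm


# ---------------------------------------------------------------------------
# initialization: algebraic circle fit in the (R, -X) plane

_FALLBACK_ALPHA = 0.8


def _fallback_init(sample: ImpedanceSample) -> ColeInit:
    r = sample.resistance_ohm
    f = sample.grid.as_array()
    r0 = float(np.max(r))
    rinf = float(np.min(r))
    if r0 == rinf:
        rinf = 0.999 * r0
    tau = 1.0 / (2.0 * np.pi * float(np.median(f)))
    return ColeInit(ColeParameters(r0, rinf, tau, _FALLBACK_ALPHA), True)


def init_cole_fit(sample: ImpedanceSample) -> ColeInit:
    """Starting parameters from an algebraic (Kasa) circle fit.

    Points (R, -X) of a Cole spectrum lie on a circular arc; the two
    real-axis intercepts of the least-squares circle estimate R0 (larger)
    and Rinf (smaller), the depression angle of its centre gives alpha
    via ``alpha = 1 - 2*theta/pi`` (clipped to [0.3, 1]), and tau comes
    from the frequency of maximal -X (``omega * tau = 1`` at the apex),
    refined by parabolic interpolation in log-frequency.

    Degenerate inputs (collinear or constant points) fall back to
    ``R0 = max R``, ``Rinf = min R``, ``tau = 1/(2 pi median f)``,
    ``alpha = 0.8`` with ``fallback=True``.
    """
    if len(sample.grid) < 5:
        raise ValidationError("need at least 5 distinct frequencies")
    x = sample.resistance_ohm.astype(float)
    y = -sample.reactance_ohm.astype(float)

    # x^2 + y^2 = 2 a x + 2 b y + c  ->  centre (a, b), r^2 = c + a^2 + b^2
    A = np.column_stack([x, y, np.ones_like(x)])
    rhs = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        return _fallback_init(sample)
    a, b = sol[0] / 2.0, sol[1] / 2.0
    r_sq = sol[2] + a * a + b * b
    half_chord_sq = r_sq - b * b
    if not np.isfinite(half_chord_sq) or half_chord_sq <= 0:
        return _fallback_init(sample)
    half_chord = math.sqrt(half_chord_sq)
    r0 = a + half_chord
    rinf = a - half_chord
    if not (r0 > 0) or r0 <= rinf:
        return _fallback_init(sample)
    rinf = max(rinf, 1e-6 * r0)

    # depression angle of the centre, seen from an intercept
    theta = math.atan2(-b, half_chord)
    alpha = float(np.clip(1.0 - 2.0 * theta / math.pi, 0.3, 1.0))

    # apex of -X: omega tau = 1; parabolic refinement on log-omega
    k = int(np.argmax(y))
    ln_w = np.log(2.0 * np.pi * sample.grid.as_array())
    if 0 < k < len(y) - 1 and y[k] > 0:
        y0, y1, y2 = y[k - 1], y[k], y[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper maximum
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            ln_peak = ln_w[k] + shift * (ln_w[min(k + 1, len(y) - 1)] - ln_w[k - 1]) / 2.0
        else:
            ln_peak = ln_w[k]
    else:
        ln_peak = ln_w[k]
    if y[k] <= 0:
        return _fallback_init(sample)
    tau = float(np.exp(-ln_peak))
    return ColeInit(ColeParameters(float(r0), float(rinf), tau, alpha), False)


# ---------------------------------------------------------------------------
# complex nonlinear least squares

_LN_TAU_LO, _LN_TAU_HI = math.log(1e-12), math.log(1e6)


def _pack(params: ColeParameters) -> np.ndarray:
    return np.array(
        [
            params.rinf_ohm,
            params.r0_ohm - params.rinf_ohm,
            math.log(params.tau_s),
            params.alpha,
        ]
    )


def _unpack(x: np.ndarray) -> ColeParameters:
    rinf, dr, ln_tau, alpha = x
    rinf = max(float(rinf), 1e-300)
    dr = max(float(dr), 0.0)
    alpha = float(np.clip(alpha, 1e-6, 1.0))
    return ColeParameters(rinf + dr, rinf, math.exp(float(ln_tau)), alpha)


def fit_cole(sample: ImpedanceSample, init: ColeParameters | None = None) -> ColeFitResult:
    """Fit the Cole model to one spectrum by relative complex least squares.

    Minimizes ``sum_k |Z_meas(f_k) - Z_model(f_k)|^2 / |Z_meas(f_k)|^2``
    over (R0, Rinf, tau, alpha) with an analytic Jacobian, trust-region
    reflective steps and bounds ``R0 >= Rinf > 0``, ``tau > 0``,
    ``alpha in (0, 1]``.  The 1/|Z|^2 weighting keeps the fit balanced
    across spectra spanning orders of magnitude from 10 Hz to 510 kHz.

    Non-convergence is reported through ``converged=False``, never raised.
    """
    if len(sample.grid) < 5:
        raise ValidationError("need at least 5 distinct frequencies")
    fallback = False
    if init is None:
        init, fallback = init_cole_fit(sample)

    f = sample.grid.as_array()
    z_meas = sample.impedance
    w = 1.0 / np.abs(z_meas)
    ln_wt = np.log(2.0 * np.pi * f)
    n = f.size

    def model_and_parts(x):
        rinf, dr, ln_tau, alpha = x
        u = np.exp(alpha * ((ln_wt + ln_tau) + 1j * np.pi / 2.0))
        g = 1.0 / (1.0 + u)
        z = rinf + dr * g
        return z, u, g

    def residuals(x):
        z, _, _ = model_and_parts(x)
        d = (z_meas - z) * w
        return np.concatenate([d.real, d.imag])

    def jacobian(x):
        rinf, dr, ln_tau, alpha = x
        z, u, g = model_and_parts(x)
        dz_drinf = np.ones(n, dtype=complex)
        dz_ddr = g
        common = -dr * g * g * u
        dz_dlntau = common * alpha
        dz_dalpha = common * ((ln_wt + ln_tau) + 1j * np.pi / 2.0)
        cols = [dz_drinf, dz_ddr, dz_dlntau, dz_dalpha]
        J = np.empty((2 * n, 4))
        for j, dz in enumerate(cols):
            d = -dz * w  # residual = (z_meas - z) * w
            J[:n, j] = d.real
            J[n:, j] = d.imag
        return J

    x0 = _pack(init)
    lb = np.array([1e-12, 0.0, _LN_TAU_LO, 1e-6])
    ub = np.array([np.inf, np.inf, _LN_TAU_HI, 1.0])
    x0 = np.clip(x0, lb, ub)

    res = least_squares(
        residuals,
        x0,
        jac=jacobian,
        bounds=(lb, ub),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=500,
    )
    params = _unpack(res.x)
    z_fit = cole_impedance(params, sample.grid)
    residual_rms = float(np.sqrt(np.mean(np.abs(z_meas - z_fit) ** 2)))
    converged = bool(res.success)
    return ColeFitResult(
        params=params,
        residual_rms_ohm=residual_rms,
        converged=converged,
        n_iter=int(res.nfev),
        init_fallback=fallback,
    )


def fit_objective(sample: ImpedanceSample, params: ColeParameters) -> float:
    """The weighted sum of squares minimized by :func:`fit_cole`."""
    z_meas = sample.impedance
    z = cole_impedance(params, sample.grid)
    return float(np.sum(np.abs(z_meas - z) ** 2 / np.abs(z_meas) ** 2))


def fit_cohort(cohort: Cohort, include_fresh: bool = True) -> pd.DataFrame:
    """Fit every measurement of a cohort; one row per spectrum.

    Columns: sample_id, treatment, time_s, temperature_C, next_day,
    R0_ohm, Rinf_ohm, tau_s, alpha, Py, residual_rms_ohm, converged.
    """
    rows = []

    def add(sample: ImpedanceSample, treatment: str) -> None:
        fit = fit_cole(sample)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "treatment": treatment,
                "time_s": np.nan if sample.time_s is None else sample.time_s,
                "temperature_C": sample.temperature_C,
                "next_day": sample.is_next_day,
                "R0_ohm": fit.params.r0_ohm,
                "Rinf_ohm": fit.params.rinf_ohm,
                "tau_s": fit.params.tau_s,
                "alpha": fit.params.alpha,
                "Py": py_parameter(fit.params),
                "residual_rms_ohm": fit.residual_rms_ohm,
                "converged": fit.converged,
            }
        )

    for tr in sorted(cohort, key=lambda t: t.sample_id):
        if include_fresh and tr.fresh_ref is not None:
            add(tr.fresh_ref, "fresh")
        for s in tr.thaw_samples:
            add(s, tr.treatment)
        for s in tr.next_day_samples:
            add(s, tr.treatment)
    return pd.DataFrame(rows)
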