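"""Scalar impedance descriptors: magnitude/phase, relative change,
fresh-vs-thawed indices, and the impedance change rate (ICR).

Freeze-thaw damage shows up in all of these: membrane destruction lowers
|Z| (mainly at low frequency), shrinks the capacitive reactance, and the
sample geometry cancels out of the ratio-type indices, which is why the
indices rather than raw ohm values feed the downstream comparison and
classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ThawTrajectory


@dataclass(frozen=True)
class ReferencePair:
    """Reference (day-0) and later impedance magnitudes, ohm."""

    z_ref: float
    z_obs: float

    def __post_init__(self) -> None:
        if not self.z_ref > 0:
            raise ValueError("z_ref must be positive")
        if self.z_obs < 0:
            raise ValueError("z_obs must be non-negative")


@dataclass(frozen=True)
class FreshThawPair:
    """Paired unfrozen (fresh) and frozen-thawed R/X, scalar or per frequency."""

    r_un: np.ndarray | float
    x_un: np.ndarray | float
    r_ft: np.ndarray | float
    x_ft: np.ndarray | float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.r_un) <= 0) or np.any(np.asarray(self.r_ft) <= 0):
            raise ValueError("resistances must be strictly positive")


def magnitude_phase(r, x):
    """|Z| = sqrt(R^2 + X^2) and phase = arctan(X/R) in degrees.

    Sign of the phase follows the reactance (capacitive X < 0 gives a
    negative phase angle).  Vectorized; r = x = 0 is a domain error.
    """
    r = np.asarray(r, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any((r == 0) & (x == 0)):
        raise ValueError("magnitude_phase undefined at r = x = 0")
    mag = np.hypot(r, x)
    phase = np.degrees(np.arctan2(x, r))
    if mag.ndim == 0:
        return float(mag), float(phase)
    return mag, phase


def relative_change(pair: ReferencePair, mode: str = "corrected") -> float:
    """Relative impedance change during storage, percent.

    ``corrected`` (default) returns ``100 * (z_ref - z_obs) / z_ref`` so a
    drop in impedance is a positive change bounded by 100 % at total loss.
    ``as_printed`` returns ``100 * (z_ref + z_obs) / z_ref``, the
    plus-sign variant found in print, kept for comparability.
    """
    if mode == "corrected":
        return 100.0 * (pair.z_ref - pair.z_obs) / pair.z_ref
    if mode == "as_printed":
        return 100.0 * (pair.z_ref + pair.z_obs) / pair.z_ref
    raise ValueError(f"unknown mode {mode!r}")


def freshness_index(pair: FreshThawPair):
    """Fresh-vs-thawed indices R_index = (Run - Rft)/Run, X_index likewise.

    Both are dimensionless ratios, invariant under a common scale factor,
    so sample-geometry differences cancel.  Where ``x_un == 0`` the X
    index is undefined and returned as NaN.
    """
    r_un = np.asarray(pair.r_un, dtype=float)
    x_un = np.asarray(pair.x_un, dtype=float)
    r_ft = np.asarray(pair.r_ft, dtype=float)
    x_ft = np.asarray(pair.x_ft, dtype=float)
    r_index = (r_un - r_ft) / r_un
    with np.errstate(divide="ignore", invalid="ignore"):
        x_index = np.where(x_un != 0, (x_un - x_ft) / np.where(x_un != 0, x_un, 1.0), np.nan)
    if r_index.ndim == 0:
        return float(r_index), float(x_index)
    return r_index, x_index


@dataclass(frozen=True)
class ICRResult:
    """Impedance change rate along a trajectory.

    One value per consecutive measurement pair:
    ``ICR_k = (|Z|_{k-1} - |Z|_k) / (|Z|_{k-1} * delta_axis_k)`` in
    fraction per second (axis="time") or per degC (axis="temperature").
    Pairs with a zero axis increment are skipped and listed in
    ``skipped_pairs``; ``axis_values`` holds the right endpoint of each
    used pair.
    """

    values: np.ndarray
    axis_values: np.ndarray
    skipped_pairs: tuple[int, ...]


def impedance_change_rate(
    trajectory: ThawTrajectory, frequency_Hz: float, axis: str = "temperature"
) -> ICRResult:
    """Normalized backward-difference rate of |Z| decline at one frequency.

    A sudden ICR spike marks the ice-water phase change, where latent heat
    uptake stalls warming while the impedance collapses.
    """
    if axis not in ("time", "temperature"):
        raise ValueError(f"unknown axis {axis!r}")
    samples = trajectory.thaw_samples
    if len(samples) < 2:
        raise ValueError("need at least 2 time-stamped measurements")
    idx = samples[0].grid.index_of(frequency_Hz)
    mags = np.array(
        [math.hypot(s.resistance_ohm[idx], s.reactance_ohm[idx]) for s in samples]
    )
    ax = np.array(
        [s.time_s if axis == "time" else s.temperature_C for s in samples], dtype=float
    )
    values, axis_out, skipped = [], [], []
    for k in range(1, len(samples)):
        d = ax[k] - ax[k - 1]
        if d == 0:
            skipped.append(k - 1)
            continue
        if d < 0:
            raise ValueError(f"axis values decrease at pair {k - 1}")
        values.append((mags[k - 1] - mags[k]) / (mags[k - 1] * d))
        axis_out.append(ax[k])
    return ICRResult(np.array(values), np.array(axis_out), tuple(skipped))
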