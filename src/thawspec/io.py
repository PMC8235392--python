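"""Data model and CSV ingestion for multi-frequency impedance trajectories.

One *measurement* is a full impedance spectrum (resistance R and signed
reactance X at each stimulus frequency) taken at a known core temperature,
optionally time-stamped relative to the start of thawing.  Measurements of
one physical sample form a :class:`ThawTrajectory`; trajectories of a whole
experiment form a :class:`Cohort`.

CSV layout (one row per sample x frequency), comma separated, UTF-8::

    sample_id,treatment,time_s,temperature_C,frequency_Hz,resistance_ohm,reactance_ohm

Conventions
-----------
* capacitive reactance is stored *negative*; plots conventionally show |X|.
* a row with ``treatment == "fresh"`` is the pre-freeze reference
  measurement of that sample (time_s empty).
* a row with a thaw treatment but empty ``time_s`` is the "next day"
  measurement, taken after >16 h of chilled storage (core temperature
  between 2 and 4 degC).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import GridError, SchemaError, ValidationError

TREATMENTS = ("fresh", "fast_thaw", "slow_thaw")
THAW_TREATMENTS = ("fast_thaw", "slow_thaw")

CSV_COLUMNS = [
    "sample_id",
    "treatment",
    "time_s",
    "temperature_C",
    "frequency_Hz",
    "resistance_ohm",
    "reactance_ohm",
]

#: temperature matching tolerance, degC (half of the 0.5 degC measurement step)
DEFAULT_TEMPERATURE_TOL = 0.25

#: tolerated backwards temperature jitter within a trajectory, degC
TEMPERATURE_JITTER_TOL = 0.5


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing, strictly positive stimulus frequencies in Hz."""

    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValidationError("frequency grid must be a non-empty 1-D sequence")
        if not np.all(f > 0):
            raise ValidationError("frequencies must be strictly positive")
        if not np.all(np.diff(f) > 0):
            raise ValidationError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", tuple(float(x) for x in f))

    @classmethod
    def default(cls, n: int = 36, f_min: float = 10.0, f_max: float = 510_000.0) -> "FrequencyGrid":
        """The measurement grid: 36 log-spaced points from 10 Hz to 510 kHz."""
        return cls(tuple(np.geomspace(f_min, f_max, n)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)

    def index_of(self, frequency_Hz: float, rtol: float = 1e-9) -> int:
        """Index of an on-grid frequency; LookupError if absent."""
        f = self.as_array()
        i = int(np.argmin(np.abs(f - frequency_Hz)))
        if not math.isclose(f[i], frequency_Hz, rel_tol=rtol, abs_tol=0.0):
            raise LookupError(f"frequency {frequency_Hz} Hz is not on the grid")
        return i

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class ImpedanceSample:
    """One complex impedance spectrum with its measurement context."""

    sample_id: str
    treatment: str
    time_s: float | None
    temperature_C: float
    grid: FrequencyGrid
    resistance_ohm: np.ndarray
    reactance_ohm: np.ndarray

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        self.resistance_ohm = np.asarray(self.resistance_ohm, dtype=float)
        self.reactance_ohm = np.asarray(self.reactance_ohm, dtype=float)
        n = len(self.grid)
        if self.resistance_ohm.shape != (n,) or self.reactance_ohm.shape != (n,):
            raise ValidationError(
                f"sample {self.sample_id}: R/X arrays must match the grid length {n}"
            )
        if not np.all(self.resistance_ohm > 0):
            raise ValidationError(
                f"sample {self.sample_id}: resistance must be strictly positive"
            )
        if self.time_s is not None:
            self.time_s = float(self.time_s)

    @property
    def impedance(self) -> np.ndarray:
        """Complex impedance Z = R + jX per frequency."""
        return self.resistance_ohm + 1j * self.reactance_ohm

    @property
    def is_next_day(self) -> bool:
        """Stored >16 h after thawing: thaw-treated but without a thaw clock."""
        return self.treatment in THAW_TREATMENTS and self.time_s is None


@dataclass
class DripLossRecord:
    """Weights before/after chilled storage, for drip (thaw) loss."""

    initial_weight_g: float
    final_weight_g: float
    storage_hours: float

    def __post_init__(self) -> None:
        if not (0 < self.final_weight_g <= self.initial_weight_g):
            raise ValidationError("need 0 < final_weight_g <= initial_weight_g")
        if self.storage_hours <= 0:
            raise ValidationError("storage_hours must be positive")


@dataclass
class ThawTrajectory:
    """All measurements of one physical sample, ordered along thawing.

    ``samples`` holds the thawing series (time-stamped, non-decreasing
    times and, within +-0.5 degC jitter, non-decreasing temperatures)
    followed by any next-day measurements.  The pre-freeze reference
    spectrum, when present, lives in ``fresh_ref``.
    """

    sample_id: str
    treatment: str
    samples: list[ImpedanceSample]
    fresh_ref: ImpedanceSample | None = None
    drip: DripLossRecord | None = None

    def __post_init__(self) -> None:
        if self.treatment not in THAW_TREATMENTS:
            raise ValidationError(
                f"trajectory treatment must be one of {THAW_TREATMENTS}"
            )
        for s in self.samples:
            if s.sample_id != self.sample_id:
                raise ValidationError(
                    f"trajectory {self.sample_id}: sample with foreign id {s.sample_id}"
                )
        timed = [s for s in self.samples if s.time_s is not None]
        times = [s.time_s for s in timed]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(f"trajectory {self.sample_id}: times must be non-decreasing")
        temps = [s.temperature_C for s in timed]
        if any(t2 < t1 - TEMPERATURE_JITTER_TOL for t1, t2 in zip(temps, temps[1:])):
            raise ValidationError(
                f"trajectory {self.sample_id}: temperatures decrease beyond tolerance"
            )

    @property
    def thaw_samples(self) -> list[ImpedanceSample]:
        return [s for s in self.samples if s.time_s is not None]

    @property
    def next_day_samples(self) -> list[ImpedanceSample]:
        return [s for s in self.samples if s.is_next_day]


@dataclass
class Cohort:
    """A set of trajectories with unique sample ids plus free-form metadata."""

    trajectories: dict[str, ThawTrajectory] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, tr in self.trajectories.items():
            if tr.sample_id != sid:
                raise ValidationError(f"cohort key {sid!r} != trajectory id {tr.sample_id!r}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories.values())

    def by_treatment(self, treatment: str) -> list[ThawTrajectory]:
        return [t for t in self if t.treatment == treatment]


# ---------------------------------------------------------------------------
# CSV I/O


def _format_float(x: float) -> str:
    return f"{x:.12g}"


def write_spectra_csv(cohort: Cohort, path) -> int:
    """Write a cohort to CSV (one row per sample x frequency).

    Returns the number of data rows written.  Row order is deterministic:
    sample ids sorted, fresh reference first, then the thaw series in time
    order, then next-day measurements, frequencies ascending.
    """
    rows: list[str] = []

    def emit(s: ImpedanceSample) -> None:
        t = "" if s.time_s is None else _format_float(s.time_s)
        for f, r, x in zip(s.grid.frequencies, s.resistance_ohm, s.reactance_ohm):
            rows.append(
                f"{s.sample_id},{s.treatment},{t},{_format_float(s.temperature_C)},"
                f"{_format_float(f)},{_format_float(r)},{_format_float(x)}"
            )

    for sid in sorted(cohort.trajectories):
        tr = cohort.trajectories[sid]
        if tr.fresh_ref is not None:
            emit(tr.fresh_ref)
        for s in tr.thaw_samples:
            emit(s)
        for s in tr.next_day_samples:
            emit(s)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for row in rows:
            fh.write(row + "\n")
    return len(rows)


def read_spectra_csv(path, grid_policy: str = "strict") -> Cohort:
    """Read a spectra CSV into a :class:`Cohort`.

    grid_policy
        ``"strict"``: every measurement must share one frequency grid
        (:class:`~thawspec.errors.GridError` otherwise);
        ``"infer"``: per-measurement grids are accepted.
    """
    if grid_policy not in ("strict", "infer"):
        raise ValueError(f"unknown grid_policy {grid_policy!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (no header row)") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    if len(df):
        bad = df.index[~(df["resistance_ohm"] > 0)]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValidationError(
                f"{path}: non-positive resistance at CSV line {int(bad[0]) + 2}"
            )
        bad_t = df.index[~df["treatment"].isin(TREATMENTS)]
        if len(bad_t):
            raise ValidationError(
                f"{path}: unknown treatment at CSV line {int(bad_t[0]) + 2}"
            )

    trajectories: dict[str, ThawTrajectory] = {}
    grids: dict[tuple, FrequencyGrid] = {}
    reference_grid: FrequencyGrid | None = None

    for sid, sdf in df.groupby("sample_id", sort=True):
        fresh_ref = None
        timed: list[ImpedanceSample] = []
        next_day: list[ImpedanceSample] = []
        treatments = set(sdf["treatment"]) - {"fresh"}
        if len(treatments) != 1:
            raise ValidationError(
                f"{path}: sample {sid!r} must carry exactly one thaw treatment, got {sorted(treatments)}"
            )
        treatment = treatments.pop()

        key_time = sdf["time_s"].fillna(np.inf)
        for (t_key, temp, treat), mdf in sdf.groupby(
            [key_time, "temperature_C", "treatment"], sort=True
        ):
            mdf = mdf.sort_values("frequency_Hz")
            f_key = tuple(mdf["frequency_Hz"].to_numpy())
            grid = grids.setdefault(f_key, FrequencyGrid(f_key))
            if grid_policy == "strict":
                if reference_grid is None:
                    reference_grid = grid
                elif grid is not reference_grid:
                    raise GridError(
                        f"{path}: sample {sid!r} uses a different frequency grid "
                        "(grid_policy='strict')"
                    )
            sample = ImpedanceSample(
                sample_id=str(sid),
                treatment=str(treat),
                time_s=None if not np.isfinite(t_key) else float(t_key),
                temperature_C=float(temp),
                grid=grid,
                resistance_ohm=mdf["resistance_ohm"].to_numpy(),
                reactance_ohm=mdf["reactance_ohm"].to_numpy(),
            )
            if sample.treatment == "fresh":
                fresh_ref = sample
            elif sample.time_s is None:
                next_day.append(sample)
            else:
                timed.append(sample)

        timed.sort(key=lambda s: s.time_s)
        trajectories[str(sid)] = ThawTrajectory(
            sample_id=str(sid),
            treatment=treatment,
            samples=timed + next_day,
            fresh_ref=fresh_ref,
        )
    return Cohort(trajectories=trajectories)


DRIP_COLUMNS = ["sample_id", "treatment", "initial_weight_g", "final_weight_g", "storage_hours"]


def write_drip_csv(cohort: Cohort, path) -> int:
    """Write per-sample drip-loss records; returns row count."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(DRIP_COLUMNS) + "\n")
        for sid in sorted(cohort.trajectories):
            tr = cohort.trajectories[sid]
            if tr.drip is None:
                continue
            d = tr.drip
            fh.write(
                f"{sid},{tr.treatment},{_format_float(d.initial_weight_g)},"
                f"{_format_float(d.final_weight_g)},{_format_float(d.storage_hours)}\n"
            )
            n += 1
    return n


def read_drip_csv(path) -> dict[str, DripLossRecord]:
    df = pd.read_csv(path)
    missing = [c for c in DRIP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return {
        str(r.sample_id): DripLossRecord(
            float(r.initial_weight_g), float(r.final_weight_g), float(r.storage_hours)
        )
        for r in df.itertuples()
    }


def write_metadata_json(cohort: Cohort, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cohort.metadata, fh, indent=2, sort_keys=True, default=str)


def select_at_temperature(
    cohort: Cohort,
    temperature_C: float,
    tol: float = DEFAULT_TEMPERATURE_TOL,
    include_next_day: bool = False,
) -> list[ImpedanceSample]:
    """For each trajectory, the measurement nearest ``temperature_C``.

    Returns at most one sample per trajectory and never one farther than
    ``tol`` degC from the target; trajectories with no admissible
    measurement are silently omitted.  Next-day measurements are excluded
    unless ``include_next_day`` is set.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    out: list[ImpedanceSample] = []
    for tr in cohort:
        pool = tr.thaw_samples + (tr.next_day_samples if include_next_day else [])
        if not pool:
            continue
        best = min(pool, key=lambda s: abs(s.temperature_C - temperature_C))
        if abs(best.temperature_C - temperature_C) <= tol:
            out.append(best)
    return out
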