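"""Orchestration: simulate -> fit -> metrics -> compare -> classify -> report.

Each stage writes its artifacts before the next starts; a run manifest
records every artifact with a SHA-256 checksum so that a rerun with the
same configuration and seed can be audited for bit-identical outputs.
All randomness derives from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .cole import fit_cohort
from .errors import DependencyError, ThawspecError
from .lstm import LSTMConfig, spectrum_dataset, train_classifier
from .metrics import FreshThawPair, freshness_index, impedance_change_rate, magnitude_phase
from .simulate import MEASUREMENT_TEMPS, SimulatorConfig, generate_cohort, truth_frame
from .stats import (
    comparison_rows_to_frame,
    comparison_table,
    drip_loss_percent,
    py_mapping_from_fits,
    two_sample_t,
)

logger = logging.getLogger("thawspec")

ALL_STAGES = ("simulate", "fit", "metrics", "compare", "classify", "report")


@dataclass
class PipelineConfig:
    output_dir: str | Path = "thawspec_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    input_spectra: str | Path | None = None  # alternative to the simulate stage
    input_drip: str | Path | None = None
    simulator: SimulatorConfig | None = None
    lstm: LSTMConfig | None = None
    icr_frequency_Hz: float = 10.0
    drip_normalize_hours: float = 20.0


@dataclass
class RunManifest:
    seed: int
    stages: list = field(default_factory=list)  # {name, status, outputs{path: sha256}}

    @property
    def succeeded(self) -> bool:
        return all(s["status"] == "succeeded" for s in self.stages)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _child_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(seed)
    return int(ss.spawn(index + 1)[index].generate_state(1)[0] % (2**31))


def _write_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def validate_stage_plan(config: PipelineConfig) -> None:
    """Fail fast if a stage lacks its inputs (before anything executes)."""
    stages = config.stages
    have_spectra = "simulate" in stages or config.input_spectra is not None
    for stage in ("fit", "metrics", "classify"):
        if stage in stages and not have_spectra:
            raise DependencyError(
                f"stage {stage!r} requires the simulate stage or input_spectra"
            )
    if "compare" in stages and "fit" not in stages and not have_spectra:
        raise DependencyError("stage 'compare' requires Cole fits, hence spectra")
    if "compare" in stages and "fit" not in stages:
        raise DependencyError("stage 'compare' requires the fit stage")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the configured stages in dependency order.

    Returns the manifest; a stage failure is recorded there (with the
    downstream stages marked skipped) rather than raised, except for plan
    validation errors which are raised before any stage executes.
    """
    validate_stage_plan(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)

    state: dict = {}
    failed = False
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        entry = {"name": stage, "status": "skipped", "outputs": {}}
        manifest.stages.append(entry)
        if failed:
            continue
        try:
            logger.info("stage %s: starting", stage)
            outputs = _STAGE_FUNCS[stage](config, out, state)
            entry["outputs"] = {str(p): _sha256(p) for p in outputs}
            entry["status"] = "succeeded"
            logger.info("stage %s: succeeded (%d artifacts)", stage, len(outputs))
        except ThawspecError as exc:
            entry["status"] = "failed"
            entry["error"] = str(exc)
            logger.error("stage %s failed: %s", stage, exc)
            failed = True

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    sim = config.simulator or SimulatorConfig(seed=_child_seed(config.seed, 0))
    cohort = generate_cohort(sim)
    state["cohort"] = cohort
    spectra = out / "spectra.csv"
    tio.write_spectra_csv(cohort, spectra)
    drip = out / "drip.csv"
    tio.write_drip_csv(cohort, drip)
    truth = out / "truth.csv"
    _write_frame(truth_frame(cohort), truth)
    meta = out / "cohort_metadata.json"
    tio.write_metadata_json(
        tio.Cohort(cohort.trajectories, {k: v for k, v in cohort.metadata.items() if k != "truth"}),
        meta,
    )
    return [spectra, drip, truth, meta]


def _load_cohort(config: PipelineConfig, out: Path, state: dict) -> tio.Cohort:
    if "cohort" in state:
        return state["cohort"]
    path = config.input_spectra or (out / "spectra.csv")
    cohort = tio.read_spectra_csv(path)
    if config.input_drip:
        for sid, rec in tio.read_drip_csv(config.input_drip).items():
            if sid in cohort.trajectories:
                cohort.trajectories[sid].drip = rec
    state["cohort"] = cohort
    return cohort


def _stage_fit(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort = _load_cohort(config, out, state)
    fits = fit_cohort(cohort)
    state["fits"] = fits
    path = out / "cole_fits.csv"
    _write_frame(fits, path)
    return [path]


def _stage_metrics(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort = _load_cohort(config, out, state)
    rows = []
    for tr in sorted(cohort, key=lambda t: t.sample_id):
        icr_by_freq = {}
        if len(tr.thaw_samples) >= 2:
            for f in tr.thaw_samples[0].grid.frequencies:
                res = impedance_change_rate(tr, f, axis="temperature")
                icr_by_freq[f] = res
        for k, s in enumerate(tr.thaw_samples + tr.next_day_samples):
            mag, phase = magnitude_phase(s.resistance_ohm, s.reactance_ohm)
            if tr.fresh_ref is not None:
                r_idx, x_idx = freshness_index(
                    FreshThawPair(
                        tr.fresh_ref.resistance_ohm,
                        tr.fresh_ref.reactance_ohm,
                        s.resistance_ohm,
                        s.reactance_ohm,
                    )
                )
            else:
                r_idx = x_idx = np.full(len(s.grid), np.nan)
            for j, f in enumerate(s.grid.frequencies):
                icr = np.nan
                res = icr_by_freq.get(f)
                if res is not None and s.time_s is not None and k >= 1:
                    hit = np.flatnonzero(np.isclose(res.axis_values, s.temperature_C))
                    if hit.size:
                        icr = float(res.values[hit[0]])
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "treatment": tr.treatment,
                        "temperature_C": s.temperature_C,
                        "next_day": s.is_next_day,
                        "frequency_Hz": f,
                        "magnitude_ohm": np.atleast_1d(mag)[j],
                        "phase_deg": np.atleast_1d(phase)[j],
                        "R_index": np.atleast_1d(r_idx)[j],
                        "X_index": np.atleast_1d(x_idx)[j],
                        "icr_per_degC": icr,
                    }
                )
    path = out / "metrics.csv"
    _write_frame(pd.DataFrame(rows), path)
    return [path]


def _stage_compare(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    fits = state["fits"]
    mapping = py_mapping_from_fits(fits, MEASUREMENT_TEMPS)
    rows = comparison_table(mapping, MEASUREMENT_TEMPS)
    state["comparison"] = rows
    path = out / "py_comparison.csv"
    _write_frame(comparison_rows_to_frame(rows), path)
    return [path]


def _stage_classify(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort = _load_cohort(config, out, state)
    base_cfg = config.lstm or LSTMConfig()
    outputs = []
    state["classify"] = {}
    for channel_index, channel in enumerate(("X", "R")):
        cfg = dataclasses.replace(
            base_cfg,
            input_channel=channel,
            seed=_child_seed(config.seed, 1 + channel_index),
        )
        X, labels, groups = spectrum_dataset(cohort, channel=channel)
        model, report = train_classifier(X, labels, cfg)
        model_path = out / f"model_{channel}.json"
        model_path.write_text(model.to_json())
        probs = model.predict_proba(X)
        pred = pd.DataFrame(
            {
                "sample_id": groups,
                "label": labels,
                "p_fast_thaw": probs[:, model.classes.index("fast_thaw")],
                "p_slow_thaw": probs[:, model.classes.index("slow_thaw")],
            }
        )
        pred_path = out / f"predictions_{channel}.csv"
        _write_frame(pred, pred_path)
        state["classify"][channel] = {
            "test_accuracy": report.test_accuracy,
            "test_loss": report.test_loss,
            "epochs_run": len(report.history),
            "best_epoch": report.best_epoch,
        }
        outputs += [model_path, pred_path]
    return outputs


def _stage_report(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    cohort = _load_cohort(config, out, state)
    summary: dict = {"seed": config.seed, "n_trajectories": len(cohort)}
    if "comparison" in state:
        summary["py_comparison"] = [
            {
                "temperature": r.temperature_label,
                "p_value": r.p_value,
                "fast_mean": None if r.fast is None else r.fast.mean,
                "slow_mean": None if r.slow is None else r.slow.mean,
            }
            for r in state["comparison"]
        ]
    if "classify" in state:
        summary["classifier"] = state["classify"]
    drip = {"fast_thaw": [], "slow_thaw": []}
    for tr in cohort:
        if tr.drip is not None:
            drip[tr.treatment].append(
                drip_loss_percent(tr.drip, normalize_hours=config.drip_normalize_hours)
            )
    if all(len(v) >= 2 for v in drip.values()):
        t, p = two_sample_t(drip["fast_thaw"], drip["slow_thaw"])
        summary["drip_loss"] = {
            "fast_mean_pct": float(np.mean(drip["fast_thaw"])),
            "slow_mean_pct": float(np.mean(drip["slow_thaw"])),
            "normalized_to_hours": config.drip_normalize_hours,
            "t": t,
            "p_value": p,
        }
    path = out / "report.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "metrics": _stage_metrics,
    "compare": _stage_compare,
    "classify": _stage_classify,
    "report": _stage_report,
}
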