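"""Full-pipeline report runner: ranges -> mechanisms -> timecourse."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import SessionData
from .mechanisms import classify_mechanism
from .range_analysis import adaptation_metric, range_contrast, tuning_ranges
from .timecourse import average_curves, crossval_context_models, fit_exponential, trial_error_curve

__all__ = ["AnalysisConfig", "run_full_report", "REPORT_LABELS"]

log = logging.getLogger(__name__)

REPORT_LABELS = {
    "dra": "dynamic range adaptation",
    "speed_gain": "speed gain",
    "reaiming": "re-aiming",
    "null": "no adaptation",
}


@dataclass
class AnalysisConfig:
    min_elevation_deg: float = 30.0
    min_denominator_hz: float = 2.0
    modulation_min_hz: float = 4.0
    mirrored_azimuth_tol_deg: float = 15.0
    permutation_resamples: int = 10_000
    seed: int = 0
    timecourse: bool = True
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        for name in ("min_elevation_deg", "min_denominator_hz", "modulation_min_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "statistic"):  # TestResult
        return {
            "statistic_name": obj.statistic_name,
            "statistic": obj.statistic,
            "n": obj.n,
            "p": obj.p,
            "method_notes": obj.method_notes,
            **{k: _jsonable(v) for k, v in getattr(obj, "extra", {}).items()},
        }
    return obj


def run_full_report(
    sessions: list[SessionData], config: AnalysisConfig | None = None
) -> dict:
    """Run the analysis pipeline over sessions and return a JSON-safe bundle.

    The bundle carries, per session: the range contrast, the completeness
    summary, the mechanism call, and (pooled) the averaged timecourse with
    its exponential fit.  Every random element is controlled by the config
    seed, which is recorded in the output.
    """
    config = config or AnalysisConfig()
    bundle: dict = {"seed": config.seed, "sessions": {}}
    curves = []
    for s in sessions:
        table = tuning_ranges(s)
        contrast = range_contrast(table)
        _, completeness = adaptation_metric(
            table, config.min_elevation_deg, config.min_denominator_hz
        )
        call = classify_mechanism(s)
        entry = {
            "n_units": int(len(table)),
            "range_contrast": _jsonable(contrast),
            "completeness": _jsonable(completeness),
            "mechanism": REPORT_LABELS[call.label],
            "mechanism_features": _jsonable(call.features),
        }
        if config.timecourse:
            try:
                models = crossval_context_models(s)
                curves.append(trial_error_curve(s, models))
            except Exception as exc:  # noqa: BLE001 - stage context, keep going
                log.warning("timecourse skipped for %s: %s", s.session_id, exc)
                entry["timecourse_error"] = str(exc)
        bundle["sessions"][s.session_id] = entry
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            table.to_csv(out / f"{s.session_id}_ranges.csv", float_format="%.10g")
    if curves:
        avg = average_curves(curves)
        bundle["timecourse"] = {
            "curve_offsets": [int(i) for i in avg.index],
            "err_2d_model": [None if np.isnan(v) else float(v) for v in avg["err_2d_model"]],
            "err_3d_model": [None if np.isnan(v) else float(v) for v in avg["err_3d_model"]],
        }
        try:
            ef = fit_exponential(avg)
            bundle["timecourse"]["exp_fit"] = {
                "a": ef.a, "b": ef.b, "c": ef.c, "r2": ef.r2, "ci": _jsonable(ef.ci),
            }
        except (ValueError, RuntimeError) as exc:
            bundle["timecourse"]["exp_fit_error"] = str(exc)
        if config.out_dir is not None:
            avg.to_csv(Path(config.out_dir) / "timecourse.csv", float_format="%.10g")
    if config.out_dir is not None:
        with open(Path(config.out_dir) / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle
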