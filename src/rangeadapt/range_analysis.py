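"""Per-unit tuning ranges across contexts and the completeness metric.

For each unit the trial- and time-averaged rate f(nD, d) is computed per
context and target (successful trials only).  Tuning ranges are max - min of
f over a target set: the *planar* ranges use the 8 directions common to both
contexts (set C), the *full* ranges use a context's entire target set (A,
the 26 3D targets; B, the 16 2D targets):

    rho_3D      = range of f(3, d) over C        rho_3D^full = ... over A
    rho_2D      = range of f(2, d) over C        rho_2D^full = ... over B

The completeness-of-adaptation metric locates the 2D planar range between
the 3D planar range (no adaptation, 0) and the 3D full range (complete, 1):

    Adaptation = (rho_2D - rho_3D) / (rho_3D^full - rho_3D)

Units whose preferred direction lies near the plane make the denominator
ill-conditioned, so the summary includes only units with |elevation| above
30 degrees and a denominator above 2 Hz (both thresholds configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SessionData, canonical_targets
from .stats import (
    DegenerateInputError,
    TestResult,
    sign_test,
    wilcoxon_signed_rank,
)
from .tuning import fit_linear

__all__ = [
    "CoverageError",
    "tuning_ranges",
    "range_contrast",
    "adaptation_metric",
    "modulation_filter",
]

log = logging.getLogger(__name__)


class CoverageError(ValueError):
    """A context is missing successful trials for required targets."""


def _context_target_means(
    session: SessionData, context_dim: int
) -> tuple[pd.DataFrame, list[str]]:
    """Trial-averaged rates: DataFrame indexed by target_id, one column per
    unit.  Only successful trials enter the averages."""
    trials = [
        t for t in session.trials_in_context(context_dim) if t.success
    ]
    if not trials:
        raise CoverageError(f"no successful trials in the {context_dim}D context")
    rows = []
    for t in trials:
        row = {"target_id": t.target_id}
        row.update(t.rates)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.groupby("target_id").mean(), [c for c in df.columns if c != "target_id"]


def _common_target_ids(session: SessionData) -> tuple[list[str], list[str]]:
    """(3D ids, 2D ids) of the common directions, matched by angle."""
    t3, t2 = canonical_targets(3), canonical_targets(2)
    pairs = t2.common_with(t3)
    ids2 = [a for a, _ in pairs]
    ids3 = [b for _, b in pairs]
    present3 = {t.target_id for t in session.trials_in_context(3)}
    present2 = {t.target_id for t in session.trials_in_context(2)}
    if present3 and not set(ids3) <= present3:
        # session may use external target ids; fall back to ids present in both
        shared = sorted(present3 & present2)
        if len(shared) >= 2:
            return shared, shared
    return ids3, ids2


def tuning_ranges(session: SessionData) -> pd.DataFrame:
    """Per-unit planar and full tuning ranges per context.

    Returns a DataFrame indexed by unit_id with columns rho_2d, rho_3d,
    rho_2d_full, rho_3d_full, diff_planar, azimuth_deg, elevation_deg (the
    last two from a linear fit to the 3D-context target means).  Units with
    missing rates in either context are dropped with a warning.
    """
    f3, _ = _context_target_means(session, 3)
    f2, _ = _context_target_means(session, 2)
    ids3, ids2 = _common_target_ids(session)
    missing = [t for t in ids3 if t not in f3.index]
    missing += [t for t in ids2 if t not in f2.index]
    # full-range coverage: when the session uses the canonical geometry,
    # every target of each context must carry at least one successful trial
    for f, ctx in ((f3, 3), (f2, 2)):
        canon = set(canonical_targets(ctx).ids)
        if set(f.index) <= canon:
            missing += sorted(canon - set(f.index))
    if missing:
        raise CoverageError(f"missing successful trials for targets {missing}")
    t3 = canonical_targets(3)
    dir_lookup = {tid: t3.direction_of(tid) for tid in t3.ids}

    records = []
    for uid in session.unit_ids:
        if uid not in f3.columns or uid not in f2.columns:
            log.warning("unit %s missing from a context; dropped from range table", uid)
            continue
        r3 = f3[uid]
        r2 = f2[uid]
        if r3.isna().any() or r2.isna().any():
            log.warning("unit %s has missing rates; dropped from range table", uid)
            continue
        rho_3d = float(r3.loc[ids3].max() - r3.loc[ids3].min())
        rho_2d = float(r2.loc[ids2].max() - r2.loc[ids2].min())
        rho_3d_full = float(r3.max() - r3.min())
        rho_2d_full = float(r2.max() - r2.min())
        if all(tid in dir_lookup for tid in f3.index):
            obs = [(dir_lookup[tid], float(r3.loc[tid])) for tid in f3.index]
            fit = fit_linear(obs)
            az, el = np.degrees(np.arctan2(fit.p[1], fit.p[0])), np.degrees(
                np.arcsin(np.clip(fit.p[2], -1.0, 1.0))
            )
        else:
            az = el = np.nan
        records.append(
            {
                "unit_id": uid,
                "rho_2d": rho_2d,
                "rho_3d": rho_3d,
                "rho_2d_full": rho_2d_full,
                "rho_3d_full": rho_3d_full,
                "diff_planar": rho_2d - rho_3d,
                "azimuth_deg": float(az),
                "elevation_deg": float(el),
            }
        )
    return pd.DataFrame.from_records(records).set_index("unit_id")


def _paired_tests(diffs: np.ndarray) -> dict:
    out: dict[str, object] = {}
    try:
        out["wilcoxon"] = wilcoxon_signed_rank(diffs)
        out["sign"] = sign_test(diffs)
        out["degenerate"] = False
    except DegenerateInputError:
        out["wilcoxon"] = out["sign"] = None
        out["degenerate"] = True
    return out


def range_contrast(table: pd.DataFrame) -> dict:
    """Summary of planar-range differences: mean, SE, counts, paired tests."""
    if len(table) == 0:
        raise ValueError("empty range table")
    diffs = table["diff_planar"].to_numpy()
    n = len(diffs)
    summary = {
        "n_units": n,
        "mean_diff_hz": float(np.mean(diffs)),
        "se_diff_hz": float(np.std(diffs, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "n_increased": int(np.sum(diffs > 0)),
    }
    summary.update(_paired_tests(diffs))
    return summary


def adaptation_metric(
    table: pd.DataFrame,
    min_elevation_deg: float = 30.0,
    min_denominator_hz: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Completeness metric per unit, with inclusion filter and summary.

    Returns (records, summary).  ``records`` has one row per unit with the
    metric, the inclusion flag and the reason for exclusion; the summary
    (mean, SE, paired tests against zero) is over included units only.
    """
    denom = table["rho_3d_full"] - table["rho_3d"]
    metric = (table["rho_2d"] - table["rho_3d"]) / denom.where(denom != 0)
    reasons = []
    included = []
    for uid in table.index:
        el = abs(table.loc[uid, "elevation_deg"])
        d = denom.loc[uid]
        if not el > min_elevation_deg:
            included.append(False)
            reasons.append(f"|elevation| {el:.1f} <= {min_elevation_deg}")
        elif not d > min_denominator_hz:
            included.append(False)
            reasons.append(f"denominator {d:.2f} Hz <= {min_denominator_hz}")
        else:
            included.append(True)
            reasons.append("")
    records = pd.DataFrame(
        {"metric": metric, "included": included, "reason": reasons}, index=table.index
    )
    vals = records.loc[records["included"], "metric"].to_numpy()
    summary: dict[str, object] = {"n_included": int(len(vals))}
    if len(vals):
        summary["mean"] = float(np.mean(vals))
        summary["se"] = (
            float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        )
        summary.update(_paired_tests(vals))
    return records, summary


def modulation_filter(
    session: SessionData, min_depth_hz: float = 4.0
) -> list[str]:
    """Units whose fitted cosine depth reaches the threshold in at least one
    context (exclusion requires the depth to be below threshold in both)."""
    f3, _ = _context_target_means(session, 3)
    f2, _ = _context_target_means(session, 2)
    t3, t2 = canonical_targets(3), canonical_targets(2)
    keep = []
    for uid in session.unit_ids:
        depths = []
        for f, ts, planar in ((f3, t3, False), (f2, t2, True)):
            if uid not in f.columns:
                continue
            obs = [
                (ts.direction_of(tid), float(f.loc[tid, uid]))
                for tid in f.index
                if tid in ts.ids
            ]
            if len(obs) >= 4:
                depths.append(fit_linear(obs, planar=planar).m)
        if not depths or max(depths) >= min_depth_hz:
            keep.append(uid)
    return keep
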