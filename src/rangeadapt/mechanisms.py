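"""Discrimination of candidate mechanisms for context-dependent tuning.

Three analyses separate the competing explanations of planar tuning-range
changes between the 3D and 2D contexts:

* dose-response: the ratio rho_3D/rho_2D regressed (weighted) against the
  elevation angle of each unit's preferred direction.  Dynamic range
  adaptation predicts ratio = cos(phi) (slope 1, intercept 0 under the
  cosine transform); a pure speed gain predicts a constant ratio 1/g.
* optimal re-aiming: a log-linear tuning model fit on the 3D block predicts,
  for each common target, the aim point on the unit sphere that moves the
  cursor closest to the target in one decoder time-step.  Comparing the
  predicted re-aiming tuning range with the model's planar range gives a
  per-unit predicted sign of the range change, tabulated against the
  observed sign: re-aiming is the only mechanism that predicts decreases.
* mirrored pairs: units with nearly identical planar preferred directions
  but opposite-sign elevations; re-aiming predicts their planar rates move
  in opposite directions across contexts, adaptation predicts both increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core_io import (
    TARGET_DISTANCE_MM,
    DecoderSpec,
    SessionData,
    UnitTuning,
    canonical_targets,
    direction_from_angles,
)
from .range_analysis import tuning_ranges, _common_target_ids
from .stats import TestResult, mann_whitney_u, weighted_linregress
from .tuning import LogLinearFit, fit_loglinear

__all__ = [
    "dose_response",
    "dose_response_weights",
    "optimal_reaiming_point",
    "default_aim_table",
    "reaiming_prediction",
    "mirrored_pair_analysis",
    "classify_mechanism",
]


# ---------------------------------------------------------------------------
# Dose-response regression
# ---------------------------------------------------------------------------

def dose_response(
    table: pd.DataFrame,
    transform: str = "abs",
    weights: np.ndarray | None = None,
) -> tuple[TestResult, pd.DataFrame]:
    """Weighted regression of rho_3D/rho_2D on |phi| or cos(phi).

    ``table`` is the per-unit range table.  Returns the fit result (slope
    statistic, F and p in ``extra``) and the fitted points.
    """
    if transform not in ("abs", "cos"):
        raise ValueError("transform must be 'abs' or 'cos'")
    ok = table["rho_2d"] > 0
    if ok.sum() < 3:
        raise ValueError("need at least 3 units with positive 2D range")
    sub = table.loc[ok]
    ratio = (sub["rho_3d"] / sub["rho_2d"]).to_numpy()
    phi = np.abs(sub["elevation_deg"].to_numpy())
    x = phi if transform == "abs" else np.cos(np.radians(phi))
    w = np.ones(len(sub)) if weights is None else np.asarray(weights, float)[ok.to_numpy()]
    res = weighted_linregress(x, ratio, w)
    points = pd.DataFrame(
        {"ratio": ratio, "phi_deg": phi, "x": x, "weight": w}, index=sub.index
    )
    return res, points


def dose_response_weights(session: SessionData, table: pd.DataFrame) -> np.ndarray:
    """Delta-method inverse-variance weights for the range ratio.

    Var(rho) is approximated by the summed squared standard errors of the
    target means at the extreme targets; Var(R) for R = rho3/rho2 follows by
    the delta method.  Down-weights ratios with small, noisy denominators.
    """
    ids3, ids2 = _common_target_ids(session)
    per_target: dict[tuple[int, str], dict[str, tuple[float, int]]] = {}
    for ctx, ids in ((3, ids3), (2, ids2)):
        for t in session.trials_in_context(ctx):
            if not t.success or t.target_id not in ids:
                continue
            bucket = per_target.setdefault((ctx, t.target_id), {})
            for uid, r in t.rates.items():
                s, n, s2 = bucket.get(uid, (0.0, 0, 0.0))
                bucket[uid] = (s + r, n + 1, s2 + r * r)
    weights = []
    for uid in table.index:
        var = {3: [], 2: []}
        means = {3: [], 2: []}
        for ctx, ids in ((3, ids3), (2, ids2)):
            for tid in ids:
                s, n, s2 = per_target.get((ctx, tid), {}).get(uid, (0.0, 0, 0.0))
                if n < 2:
                    var[ctx].append(np.nan)
                    means[ctx].append(np.nan)
                    continue
                mu = s / n
                v = max(s2 / n - mu * mu, 0.0) * n / (n - 1)
                var[ctx].append(v / n)
                means[ctx].append(mu)
        w = 1.0
        try:
            rho2 = table.loc[uid, "rho_2d"]
            rho3 = table.loc[uid, "rho_3d"]
            v3 = var[3][int(np.nanargmax(means[3]))] + var[3][int(np.nanargmin(means[3]))]
            v2 = var[2][int(np.nanargmax(means[2]))] + var[2][int(np.nanargmin(means[2]))]
            if rho2 > 0:
                ratio = rho3 / rho2
                var_ratio = (v3 + ratio**2 * v2) / rho2**2
                w = 1.0 / max(var_ratio, 1e-12)
        except (ValueError, KeyError):
            w = 0.0
        weights.append(w)
    return np.asarray(weights)


# ---------------------------------------------------------------------------
# Optimal re-aiming
# ---------------------------------------------------------------------------

def _one_step_objective(
    rate_fn,
    units: list[UnitTuning],
    spec: DecoderSpec,
    target_dir: np.ndarray,
    n_dims: int,
    zero_z: bool,
):
    """Vectorized objective ||85 d - dt ks (nD/N) sum_i p_i u_i(d*)|| over a
    (G, 3) grid of candidate aim points."""
    b0 = np.array([u.b0 for u in units])
    m = np.array([u.m for u in units])
    P = np.array([u.p for u in units])
    N = len(units)
    scale = spec.dt_s * spec.ks * n_dims / N
    goal = TARGET_DISTANCE_MM * np.asarray(target_dir, float)

    def J(grid: np.ndarray) -> np.ndarray:
        rates = rate_fn(np.atleast_2d(grid))        # (G, N)
        u = (rates - b0) / m
        disp = scale * (u @ P)                       # (G, 3)
        if zero_z:
            disp = disp.copy()
            disp[:, 2] = 0.0
        return np.linalg.norm(goal - disp, axis=1)

    return J


def _optimize_on_sphere(J, target_dir: np.ndarray, coarse_deg: float = 5.0, n_starts: int = 8):
    az = np.arange(-180.0, 180.0, coarse_deg)
    el = np.arange(-90.0, 90.0 + coarse_deg, coarse_deg)
    AZ, EL = np.meshgrid(az, el, indexing="ij")
    azf, elf = AZ.ravel(), EL.ravel()
    grid = np.column_stack(
        [
            np.cos(np.radians(elf)) * np.cos(np.radians(azf)),
            np.cos(np.radians(elf)) * np.sin(np.radians(azf)),
            np.sin(np.radians(elf)),
        ]
    )
    vals = J(grid)
    order = np.argsort(vals)
    starts = []
    for idx in order:
        cand = (azf[idx], elf[idx])
        if all(
            math.hypot(
                (cand[0] - s[0] + 180.0) % 360.0 - 180.0, cand[1] - s[1]
            ) > 2.0 * coarse_deg
            for s in starts
        ):
            starts.append(cand)
        if len(starts) >= n_starts:
            break

    def f(x):
        return float(J(direction_from_angles(x[0], x[1])[None, :])[0])

    best = None
    converged = False
    for s in starts:
        res = minimize(f, np.array(s), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
        cand_val = float(res.fun)
        cand_dir = direction_from_angles(res.x[0], res.x[1])
        if res.success:
            converged = True
        if (
            best is None
            or cand_val < best[0] - 1e-12
            or (
                abs(cand_val - best[0]) <= 1e-12
                and np.dot(cand_dir, target_dir) > np.dot(best[1], target_dir)
            )
        ):
            best = (cand_val, cand_dir)
    # grid fallback if local refinement somehow regressed
    gbest = float(vals[order[0]])
    if best is None or gbest < best[0]:
        best = (gbest, grid[order[0]])
    return best[1], best[0], converged


def optimal_reaiming_point(
    ll_fits: list[LogLinearFit],
    units: list[UnitTuning],
    spec: DecoderSpec,
    target_dir: np.ndarray,
    n_dims: int = 2,
    zero_z: bool = True,
) -> np.ndarray:
    """Aim point on the unit sphere minimizing the one-step miss distance.

    The candidate point d* drives predicted rates through the log-linear
    tuning models; the decoder parameters (the units' b0, m, p) convert them
    to a one-step population-vector displacement.  By default the
    z-component of the displacement is zeroed for the 2D context, where the
    cursor cannot move in depth; ``zero_z=False`` keeps the literal
    unconstrained displacement.  Solved by refining the best cells of a
    5-degree grid scan with >= 8 local optimizations.
    """
    B0 = np.array([f.bll0 for f in ll_fits])
    M = np.array([f.mll for f in ll_fits])
    PL = np.array([f.pll for f in ll_fits])

    def rate_fn(grid):
        return np.exp(B0 + (grid @ PL.T) * M)

    J = _one_step_objective(rate_fn, units, spec, target_dir, n_dims, zero_z)
    d_star, _, _ = _optimize_on_sphere(J, np.asarray(target_dir, float))
    return d_star


def default_aim_table(
    units: list[UnitTuning],
    spec: DecoderSpec,
    n_dims: int = 2,
    zero_z: bool = True,
) -> dict[str, np.ndarray]:
    """Self-consistent aim table for the re-aiming generator: the optimal
    aim point per common planar target under the units' true linear tuning."""
    b0 = np.array([u.b0 for u in units])
    m = np.array([u.m for u in units])
    P = np.array([u.p for u in units])

    def rate_fn(grid):
        return b0 + (grid @ P.T) * m

    t3 = canonical_targets(3)
    ids3, _ = _common_ids()
    table = {}
    for tid in ids3:
        d = t3.direction_of(tid)
        J = _one_step_objective(rate_fn, units, spec, d, n_dims, zero_z)
        d_star, _, _ = _optimize_on_sphere(J, d)
        table[tid] = d_star
    return table


def _common_ids() -> tuple[list[str], list[str]]:
    t3, t2 = canonical_targets(3), canonical_targets(2)
    pairs = t2.common_with(t3)
    return [b for _, b in pairs], [a for a, _ in pairs]


def _fit_3d_loglinear(session: SessionData) -> dict[str, LogLinearFit]:
    """Per-unit Poisson log-link fits on all successful 3D-context trials."""
    t3 = canonical_targets(3)
    fits = {}
    obs_by_unit: dict[str, list] = {uid: [] for uid in session.unit_ids}
    for t in session.trials_in_context(3):
        if not t.success or t.target_id not in t3.ids:
            continue
        d = t3.direction_of(t.target_id)
        for uid, r in t.rates.items():
            obs_by_unit[uid].append((d, r * t.duration_s, t.duration_s))
    for uid, obs in obs_by_unit.items():
        if len(obs) >= 4:
            fits[uid] = fit_loglinear(obs)
    return fits


def reaiming_prediction(
    session: SessionData,
    zero_z: bool = True,
    table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Predicted vs observed sign of planar range change under re-aiming.

    Fits the log-linear model on the 3D block, derives the optimal aim point
    for each of the 8 common targets, and compares each unit's predicted
    re-aiming range (over the aim points) with its model planar range (over
    the common targets).  Returns the per-unit table and a 2x2 contingency
    summary of predicted vs observed increase/decrease.
    """
    fits = _fit_3d_loglinear(session)
    if set(fits) != set(session.unit_ids):
        missing = sorted(set(session.unit_ids) - set(fits))
        raise ValueError(f"could not fit 3D tuning for units {missing}")
    if table is None:
        table = tuning_ranges(session)

    t3 = canonical_targets(3)
    ids3, _ = _common_ids()
    unit_order = [uid for uid in session.unit_ids if uid in table.index]
    ll_fits = [fits[uid] for uid in unit_order]
    units = [session.unit(uid) for uid in unit_order]
    spec = session.decoder

    aim_points = {}
    for tid in ids3:
        aim_points[tid] = optimal_reaiming_point(
            ll_fits, units, spec, t3.direction_of(tid), n_dims=2, zero_z=zero_z
        )
    D = np.array([aim_points[tid] for tid in ids3])
    C = np.array([t3.direction_of(tid) for tid in ids3])

    rows = []
    for uid, f in zip(unit_order, ll_fits):
        r_reaim = np.exp(f.bll0 + f.mll * (D @ f.pll))
        r_ll = np.exp(f.bll0 + f.mll * (C @ f.pll))
        rho_reaim = float(r_reaim.max() - r_reaim.min())
        rho_ll = float(r_ll.max() - r_ll.min())
        observed = float(table.loc[uid, "diff_planar"])
        rows.append(
            {
                "unit_id": uid,
                "rho_reaim": rho_reaim,
                "rho_ll": rho_ll,
                "predicted_diff": rho_reaim - rho_ll,
                "predicted_sign": int(np.sign(rho_reaim - rho_ll)),
                "observed_sign": int(np.sign(observed)),
            }
        )
    out = pd.DataFrame(rows).set_index("unit_id")
    contingency = {
        "pred_inc_obs_inc": int(((out.predicted_sign > 0) & (out.observed_sign > 0)).sum()),
        "pred_inc_obs_dec": int(((out.predicted_sign > 0) & (out.observed_sign < 0)).sum()),
        "pred_dec_obs_inc": int(((out.predicted_sign < 0) & (out.observed_sign > 0)).sum()),
        "pred_dec_obs_dec": int(((out.predicted_sign < 0) & (out.observed_sign < 0)).sum()),
        "aim_points": {tid: aim_points[tid].tolist() for tid in ids3},
    }
    return out, contingency


# ---------------------------------------------------------------------------
# Mirrored pairs
# ---------------------------------------------------------------------------

def _circ_diff_deg(a: float, b: float) -> float:
    return (a - b + 180.0) % 360.0 - 180.0


def mirrored_pair_analysis(
    session: SessionData,
    azimuth_tol_deg: float = 15.0,
    min_elevation_deg: float = 10.0,
    table: pd.DataFrame | None = None,
) -> list[dict]:
    """Rate comparisons for PD pairs mirrored across the xy-plane.

    For each qualifying pair and the common planar target nearest their
    shared azimuth, collects per-trial rates for that 3D target, the 3D
    targets immediately above and below it, and the matching 2D target, and
    runs Mann-Whitney tests of (a) above-vs-below 3D rates and (b) 2D-vs-3D
    planar rates per unit.  Returns an empty list (with no error) when no
    pair qualifies.
    """
    if table is None:
        table = tuning_ranges(session)
    t3, t2 = canonical_targets(3), canonical_targets(2)
    ids3, ids2 = _common_ids()

    cands = [
        (uid, table.loc[uid, "azimuth_deg"], table.loc[uid, "elevation_deg"])
        for uid in table.index
        if abs(table.loc[uid, "elevation_deg"]) >= min_elevation_deg
    ]
    pairs = []
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            (ua, aza, ela), (ub, azb, elb) = cands[i], cands[j]
            if ela * elb < 0 and abs(_circ_diff_deg(aza, azb)) <= azimuth_tol_deg:
                pairs.append((ua, ub))

    def planar_trial_rates(ctx: int, tid: str, uid: str) -> list[float]:
        return [
            t.rates[uid]
            for t in session.trials_in_context(ctx)
            if t.success and t.target_id == tid and uid in t.rates
        ]

    results = []
    for ua, ub in pairs:
        mean_az = table.loc[ua, "azimuth_deg"] + _circ_diff_deg(
            table.loc[ub, "azimuth_deg"], table.loc[ua, "azimuth_deg"]
        ) / 2.0
        # nearest common planar target by azimuth
        az3 = {
            tid: math.degrees(math.atan2(*t3.direction_of(tid)[[1, 0]]))
            for tid in ids3
        }
        tid3 = min(az3, key=lambda t: abs(_circ_diff_deg(az3[t], mean_az)))
        tid2 = ids2[ids3.index(tid3)]
        # 3D targets sharing the azimuth, immediately above/below the plane
        above = below = None
        for tid in t3.ids:
            d = t3.direction_of(tid)
            az = math.degrees(math.atan2(d[1], d[0]))
            el = math.degrees(math.asin(np.clip(d[2], -1, 1)))
            if abs(_circ_diff_deg(az, az3[tid3])) < 1e-6 and el != 0.0:
                if el > 0 and (above is None or el < above[1]):
                    above = (tid, el)
                if el < 0 and (below is None or el > below[1]):
                    below = (tid, el)
        entry: dict[str, object] = {
            "units": (ua, ub),
            "planar_target_3d": tid3,
            "planar_target_2d": tid2,
            "above_target": above[0] if above else None,
            "below_target": below[0] if below else None,
            "per_unit": {},
        }
        for uid in (ua, ub):
            planar3 = planar_trial_rates(3, tid3, uid)
            planar2 = planar_trial_rates(2, tid2, uid)
            rates_above = planar_trial_rates(3, above[0], uid) if above else []
            rates_below = planar_trial_rates(3, below[0], uid) if below else []
            tests = {}
            if rates_above and rates_below:
                tests["above_vs_below"] = mann_whitney_u(rates_above, rates_below)
            if planar2 and planar3:
                tests["planar_2d_vs_3d"] = mann_whitney_u(planar2, planar3)
            entry["per_unit"][uid] = {
                "mean_3d_planar": float(np.mean(planar3)) if planar3 else np.nan,
                "mean_2d_planar": float(np.mean(planar2)) if planar2 else np.nan,
                "mean_above": float(np.mean(rates_above)) if rates_above else np.nan,
                "mean_below": float(np.mean(rates_below)) if rates_below else np.nan,
                "tests": tests,
            }
        results.append(entry)
    return results


# ---------------------------------------------------------------------------
# Mechanism classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MechanismCall:
    label: str
    features: dict


def elevation_sign_contrast(
    session: SessionData,
    table: pd.DataFrame,
    min_elevation_deg: float = 10.0,
) -> dict:
    """Contrast of preferred-target rate changes between up- and down-PD units.

    For each unit, the common planar target nearest its preferred azimuth is
    selected and the depth-normalized change in its trial-averaged rate from
    the 3D to the 2D context is computed.  Units are split by the sign of
    their PD elevation (|elevation| above ``min_elevation_deg``); the groups
    are compared with Welch's t-test.  Re-aiming above or below the plane is
    the only candidate mechanism that moves the two groups in opposite
    directions (the mirrored-pair signature); adaptation, speed gain and no
    adaptation all predict changes that depend on |elevation| only.
    """
    from .range_analysis import _context_target_means

    f3, _ = _context_target_means(session, 3)
    f2, _ = _context_target_means(session, 2)
    ids3, ids2 = _common_ids()
    t3 = canonical_targets(3)
    az_of = {
        tid: math.degrees(math.atan2(t3.direction_of(tid)[1], t3.direction_of(tid)[0]))
        for tid in ids3
    }
    x_up, x_down = [], []
    for uid in table.index:
        el = table.loc[uid, "elevation_deg"]
        if abs(el) <= min_elevation_deg or uid not in f3.columns or uid not in f2.columns:
            continue
        az = table.loc[uid, "azimuth_deg"]
        tid3 = min(ids3, key=lambda t: abs(_circ_diff_deg(az_of[t], az)))
        tid2 = ids2[ids3.index(tid3)]
        if tid3 not in f3.index or tid2 not in f2.index:
            continue
        mhat = max(table.loc[uid, "rho_3d_full"] / 2.0, 1e-9)
        dx = (float(f2.loc[tid2, uid]) - float(f3.loc[tid3, uid])) / mhat
        (x_up if el > 0 else x_down).append(dx)
    out = {
        "n_up": len(x_up),
        "n_down": len(x_down),
        "mean_up": float(np.mean(x_up)) if x_up else np.nan,
        "mean_down": float(np.mean(x_down)) if x_down else np.nan,
        "p": 1.0,
    }
    if len(x_up) >= 2 and len(x_down) >= 2:
        from scipy.stats import ttest_ind

        out["p"] = float(ttest_ind(x_up, x_down, equal_var=False).pvalue)
    return out


def classify_mechanism(
    session: SessionData,
    contrast_p: float = 0.005,
    slope_threshold: float = 0.25,
    slope_p: float = 0.01,
    ratio_threshold: float = 0.89,
) -> MechanismCall:
    """Label a session's mechanism from three separating statistics.

    Decision order: (1) re-aiming if the up-PD and down-PD groups change
    their preferred-target rates in opposite directions and the contrast is
    significant (:func:`elevation_sign_contrast`); (2) dynamic range
    adaptation if the cosine-transform dose-response slope is positive and
    significant; (3) speed gain if the weighted mean range ratio is well
    below 1; otherwise no adaptation.  Only re-aiming predicts coordinated
    opposite changes across the plane, only adaptation predicts
    elevation-magnitude-dependent changes, and only a speed gain predicts a
    uniform ratio shift, so the three signatures are mutually exclusive up
    to noise.
    """
    table = tuning_ranges(session)
    weights = dose_response_weights(session, table)
    fit, points = dose_response(table, transform="cos", weights=weights)
    mean_ratio = float(
        np.average(points["ratio"], weights=np.maximum(points["weight"], 1e-12))
    )
    contrast = elevation_sign_contrast(session, table)
    features = {
        "slope_cos": fit.statistic,
        "slope_p": fit.p,
        "intercept_cos": fit.extra["intercept"],
        "mean_ratio": mean_ratio,
        "contrast_p": contrast["p"],
        "contrast_mean_up": contrast["mean_up"],
        "contrast_mean_down": contrast["mean_down"],
        "n_units": int(len(table)),
    }
    opposite = (
        np.isfinite(contrast["mean_up"])
        and np.isfinite(contrast["mean_down"])
        and contrast["mean_up"] * contrast["mean_down"] < 0
    )
    if contrast["p"] < contrast_p and opposite:
        label = "reaiming"
    elif fit.statistic > slope_threshold and fit.p < slope_p:
        label = "dra"
    elif mean_ratio < ratio_threshold:
        label = "speed_gain"
    else:
        label = "null"
    return MechanismCall(label=label, features=features)
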