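"""Trial-by-trial adaptation timecourse around the 3D-to-2D context switch.

Cross-validated tuning models are fit separately for even- and odd-numbered
common-target trials of each context (planar log-linear fits: the common
targets all lie in the xy-plane).  For every aligned trial the per-unit
error |observed rate - model prediction| is standardized by the geometric
mean of the unit's two context dispersions, the prediction always coming
from the opposite-parity model, and averaged over units.  The resulting
curve spans the last 60 planar-target 3D trials (offsets -60..-1) and the
first 120 2D trials (offsets 1..120); offset 0 is the context switch.  The
drop in the 2D-model error after the switch is summarized by a nonlinear
least-squares fit of y = a + b exp(c x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_io import SessionData, canonical_targets
from .range_analysis import _common_target_ids, CoverageError
from .tuning import LinearFit, LogLinearFit, fit_linear, fit_loglinear

__all__ = [
    "ContextModels",
    "ExpFit",
    "crossval_context_models",
    "trial_error_curve",
    "average_curves",
    "fit_exponential",
]


@dataclass
class ContextModels:
    """Per-context, per-parity planar tuning fits and pooled dispersions."""

    fits: dict[tuple[int, str], dict[str, LogLinearFit]]  # (context, parity) -> unit fits
    dispersion: dict[tuple[int, str], float]  # (context, unit_id) -> pooled dispersion
    unit_ids: list[str]
    parity: dict[tuple[int, int], str] = None  # (context, trial_index) -> parity


@dataclass(frozen=True)
class ExpFit:
    a: float
    b: float
    c: float
    r2: float
    ci: dict  # parameter -> (lo, hi), 95%
    degenerate_c: bool = False


def _planar_direction(target_id: str, context_dim: int) -> np.ndarray:
    ts = canonical_targets(context_dim)
    return ts.direction_of(target_id)


def _dispersion_of(fit: LinearFit | LogLinearFit) -> float:
    if isinstance(fit, LogLinearFit):
        return fit.dispersion
    return max(fit.residual_variance, 1e-12)


def crossval_context_models(
    session: SessionData, min_trials: int = 2, model: str = "loglinear"
) -> ContextModels:
    """Fit even/odd planar tuning models per context on common targets.

    Trials are numbered per target within their context block (so each
    target's trials alternate parities and the split is balanced); parity is
    taken on that number.  Requires at least ``min_trials`` trials per parity
    per common target per context.  Dispersions are pooled (averaged) across
    parities.

    ``model`` selects the tuning family: ``"loglinear"`` fits the Poisson
    log-link model (dispersion = Pearson chi-square / dof, count scale);
    ``"linear"`` fits the cosine model by least squares (dispersion =
    residual variance, Hz^2).  The normalized error metric is invariant to
    the dispersion scale, so the two families differ only through model fit.
    """
    if model not in ("loglinear", "linear"):
        raise ValueError("model must be 'loglinear' or 'linear'")
    ids3, ids2 = _common_target_ids(session)
    fits: dict[tuple[int, str], dict[str, LogLinearFit]] = {}
    dispersion: dict[tuple[int, str], float] = {}
    parity_map: dict[tuple[int, int], str] = {}
    for ctx in (2, 3):
        counters: dict[str, int] = {}
        for t in sorted(session.trials_in_context(ctx), key=lambda t: t.trial_index):
            if not t.success:
                continue  # failed trials carry no usable rates
            k = counters.get(t.target_id, 0)
            parity_map[(ctx, t.trial_index)] = "even" if k % 2 == 0 else "odd"
            counters[t.target_id] = k + 1
    for ctx, ids in ((3, ids3), (2, ids2)):
        ts = canonical_targets(ctx)
        trials = [
            t
            for t in session.trials_in_context(ctx)
            if t.success and t.target_id in ids
        ]
        for parity in ("even", "odd"):
            keep = [t for t in trials if parity_map[(ctx, t.trial_index)] == parity]
            per_target = {tid: sum(1 for t in keep if t.target_id == tid) for tid in ids}
            short = [tid for tid, c in per_target.items() if c < min_trials]
            if short:
                raise CoverageError(
                    f"{ctx}D {parity}: fewer than {min_trials} trials for targets {short}"
                )
            obs_by_unit: dict[str, list] = {uid: [] for uid in session.unit_ids}
            for t in keep:
                d = ts.direction_of(t.target_id)
                for uid, r in t.rates.items():
                    obs_by_unit[uid].append((d, r, t.duration_s))
            if model == "loglinear":
                fits[(ctx, parity)] = {
                    uid: fit_loglinear([(d, r * e, e) for d, r, e in obs], planar=True)
                    for uid, obs in obs_by_unit.items()
                }
            else:
                fits[(ctx, parity)] = {
                    uid: fit_linear([(d, r) for d, r, _ in obs], planar=True)
                    for uid, obs in obs_by_unit.items()
                }
        for uid in session.unit_ids:
            dispersion[(ctx, uid)] = 0.5 * (
                _dispersion_of(fits[(ctx, "even")][uid])
                + _dispersion_of(fits[(ctx, "odd")][uid])
            )
    return ContextModels(
        fits=fits,
        dispersion=dispersion,
        unit_ids=list(session.unit_ids),
        parity=parity_map,
    )


def _trial_error(
    trial, models: ContextModels, model_ctx: int, norm: dict[str, float]
) -> float:
    own = models.parity.get((trial.context_dim, trial.trial_index), "even")
    parity = "odd" if own == "even" else "even"  # opposite-parity prediction
    fits = models.fits[(model_ctx, parity)]
    d = _planar_direction(trial.target_id, trial.context_dim)
    errs = []
    for uid in models.unit_ids:
        if uid not in trial.rates:
            continue
        pred = fits[uid].predict(d[:2])
        errs.append(abs(trial.rates[uid] - pred) / norm[uid])
    return float(np.mean(errs))


def trial_error_curve(
    session: SessionData,
    models: ContextModels,
    n_pre: int = 60,
    n_post: int = 120,
) -> pd.DataFrame:
    """Standardized population error per aligned trial around the switch.

    Returns a DataFrame indexed by trial_offset (-n_pre..-1, 1..n_post) with
    columns err_2d_model, err_3d_model and n_sessions_averaged (=1).  The 3D
    side keeps only common (planar) target trials, counted backward from the
    switch; 2D trials with non-common targets are left as NaN rows.
    """
    ids3, ids2 = _common_target_ids(session)
    norm = {
        uid: math.sqrt(
            models.dispersion[(2, uid)] * models.dispersion[(3, uid)]
        )
        for uid in models.unit_ids
    }
    trials3 = sorted(session.trials_in_context(3), key=lambda t: t.trial_index)
    planar3 = [t for t in trials3 if t.target_id in ids3 and t.success]
    trials2 = sorted(session.trials_in_context(2), key=lambda t: t.trial_index)

    offsets = list(range(-n_pre, 0)) + list(range(1, n_post + 1))
    rows = {o: (np.nan, np.nan) for o in offsets}
    for k, t in enumerate(reversed(planar3[-n_pre:])):
        o = -(k + 1)
        rows[o] = (
            _trial_error(t, models, 2, norm),
            _trial_error(t, models, 3, norm),
        )
    for k, t in enumerate(trials2[:n_post]):
        o = k + 1
        if t.target_id not in ids2 or not t.success:
            continue  # excluded: target outside the common set (or failed)
        rows[o] = (
            _trial_error(t, models, 2, norm),
            _trial_error(t, models, 3, norm),
        )
    df = pd.DataFrame(
        {
            "err_2d_model": [rows[o][0] for o in offsets],
            "err_3d_model": [rows[o][1] for o in offsets],
            "n_sessions_averaged": 1,
        },
        index=pd.Index(offsets, name="trial_offset"),
    )
    return df


def average_curves(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Offset-wise mean over sessions; offsets missing in some sessions are
    averaged over the sessions that have them."""
    if not curves:
        raise ValueError("no curves to average")
    cat = pd.concat(curves)
    grouped = cat.groupby(level=0)
    out = grouped[["err_2d_model", "err_3d_model"]].mean()
    out["n_sessions_averaged"] = grouped["err_2d_model"].count()
    return out


def fit_exponential(curve: pd.DataFrame, side: str = "2d_model") -> ExpFit:
    """Fit y = a + b exp(c x) to the post-switch error curve.

    Uses offsets 1..120 of ``err_2d_model`` (or ``err_3d_model``).
    Initialization: a = mean of the last 20 available points, b = y(1) - a,
    c = -0.2, with c bounded below -1e-4 (a decay).  95% confidence bounds
    come from the asymptotic covariance.
    """
    col = f"err_{side}"
    post = curve.loc[curve.index > 0, col].dropna()
    if len(post) < 10:
        raise ValueError("need at least 10 post-switch points")
    x = post.index.to_numpy(dtype=float)
    y = post.to_numpy(dtype=float)
    a0 = float(np.mean(y[-20:]))
    b0 = float(y[0] - a0)
    degenerate = abs(b0) < 1e-8 or np.allclose(y, y[0])

    def f(x, a, b, c):
        return a + b * np.exp(c * x)

    try:
        popt, pcov = curve_fit(
            f,
            x,
            y,
            p0=[a0, b0 if b0 != 0 else 1e-6, -0.2],
            bounds=([-np.inf, -np.inf, -np.inf], [np.inf, np.inf, -1e-4]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    resid = y - f(x, *popt)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    ci = {
        name: (float(p - 1.96 * s), float(p + 1.96 * s))
        for name, p, s in zip(("a", "b", "c"), popt, se)
    }
    if abs(popt[1]) < 1e-6:
        degenerate = True
    return ExpFit(
        a=float(popt[0]),
        b=float(popt[1]),
        c=float(popt[2]),
        r2=r2,
        ci=ci,
        degenerate_c=degenerate,
    )
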