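"""Directional tuning models.

Two tuning models are used throughout: a linear cosine model,

    r(d) = b0 + m * (d . p),

fit by ordinary least squares on trial-mean rates, and a log-linear model,

    r(d) = exp(bll0 + mll * (d . pll)),

fit as a Poisson GLM with log link on spike counts (with the trial duration
as exposure).  Both report the preferred direction p as a unit vector with a
non-negative depth; the sign is absorbed into p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .core_io import azimuth_elevation

__all__ = [
    "LinearFit",
    "LogLinearFit",
    "PDAngles",
    "fit_linear",
    "fit_loglinear",
    "pd_angles",
    "predict_rate",
    "SingularDesignError",
    "ConvergenceError",
]


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """GLM fitting failed to converge; carries the last iterate."""

    def __init__(self, msg: str, last_fit: "LogLinearFit | None" = None):
        super().__init__(msg)
        self.last_fit = last_fit


@dataclass(frozen=True)
class PDAngles:
    azimuth_deg: float
    elevation_deg: float


@dataclass(frozen=True)
class LinearFit:
    b0: float
    m: float
    p: np.ndarray
    residual_variance: float
    n_obs: int
    planar: bool = False  # True if fit on 2-component planar directions

    def predict(self, d: np.ndarray) -> float:
        d = np.asarray(d, dtype=float)
        k = min(len(d), len(self.p))
        return float(self.b0 + self.m * np.dot(d[:k], self.p[:k]))


@dataclass(frozen=True)
class LogLinearFit:
    bll0: float
    mll: float
    pll: np.ndarray
    dispersion: float
    n_obs: int
    planar: bool = False

    def predict(self, d: np.ndarray) -> float:
        d = np.asarray(d, dtype=float)
        k = min(len(d), len(self.pll))
        return float(np.exp(self.bll0 + self.mll * np.dot(d[:k], self.pll[:k])))


def _normalize_coef(coef: np.ndarray) -> tuple[float, np.ndarray]:
    """Depth = |coef|, direction = coef/|coef|; zero coef maps to +x."""
    m = float(np.linalg.norm(coef))
    if m == 0.0:
        p = np.zeros_like(coef, dtype=float)
        p[0] = 1.0
        return 0.0, p
    return m, coef / m


def _embed(p: np.ndarray) -> np.ndarray:
    """Embed a planar direction with z=0 for angle comparisons."""
    if len(p) == 3:
        return p
    return np.array([p[0], p[1], 0.0])


def fit_linear(observations: list[tuple[np.ndarray, float]], planar: bool = False) -> LinearFit:
    """OLS fit of rate = b0 + m (d . p) from (direction, mean rate) pairs.

    For a planar fit the regression runs on the 2-component planar direction
    and the returned p is embedded with z = 0.
    """
    if not observations:
        raise ValueError("no observations")
    dirs = np.array([np.asarray(d, float) for d, _ in observations])
    rates = np.array([r for _, r in observations], dtype=float)
    k = 2 if planar else 3
    D = dirs[:, :k]
    X = np.column_stack([np.ones(len(D)), D])
    if np.linalg.matrix_rank(X) < k + 1:
        raise SingularDesignError(
            f"need >= {k + 1} directions in general position, design rank "
            f"{np.linalg.matrix_rank(X)} < {k + 1}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, rates, rcond=None)
    resid = rates - X @ beta
    dof = max(len(rates) - (k + 1), 1)
    m, p = _normalize_coef(beta[1:])
    return LinearFit(
        b0=float(beta[0]),
        m=m,
        p=_embed(p),
        residual_variance=float(resid @ resid / dof),
        n_obs=len(rates),
        planar=planar,
    )


def fit_loglinear(
    observations: list[tuple[np.ndarray, float, float]],
    planar: bool = False,
    maxiter: int = 200,
) -> LogLinearFit:
    """Poisson log-link GLM fit from (direction, spike count, exposure_s).

    The exposure enters as an offset log(exposure), so the linear predictor
    models the rate in Hz.  The dispersion is the Pearson chi-square divided
    by the residual degrees of freedom.
    """
    if not observations:
        raise ValueError("no observations")
    dirs = np.array([np.asarray(d, float) for d, _, _ in observations])
    counts = np.array([c for _, c, _ in observations], dtype=float)
    expos = np.array([e for _, _, e in observations], dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative spike counts")
    if np.any(expos <= 0):
        raise ValueError("non-positive exposures")
    k = 2 if planar else 3
    X = np.column_stack([np.ones(len(dirs)), dirs[:, :k]])
    if np.linalg.matrix_rank(X) < k + 1:
        raise SingularDesignError("rank-deficient direction design")
    model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=np.log(expos))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter)
    mu = np.asarray(res.mu)
    dof = max(len(counts) - (k + 1), 1)
    pearson = float(np.sum((counts - mu) ** 2 / np.maximum(mu, 1e-12)))
    m, p = _normalize_coef(np.asarray(res.params)[1:])
    fit = LogLinearFit(
        bll0=float(res.params[0]),
        mll=m,
        pll=_embed(p),
        dispersion=max(pearson / dof, 1e-12),
        n_obs=len(counts),
        planar=planar,
    )
    if not res.converged:
        raise ConvergenceError(f"Poisson GLM did not converge in {maxiter} iterations", fit)
    return fit


def pd_angles(p: np.ndarray) -> PDAngles:
    """Azimuth/elevation of a preferred-direction unit vector, degrees."""
    az, el = azimuth_elevation(p)
    return PDAngles(azimuth_deg=az, elevation_deg=el)


def predict_rate(fit: LinearFit | LogLinearFit, d: np.ndarray) -> float:
    """Model-predicted mean rate (Hz) at direction d."""
    return fit.predict(np.asarray(d, dtype=float))
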