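"""Velocity decoders and cursor dynamics.

Rates are first normalized per unit (baseline subtracted, divided by the
modulation depth).  Two linear decoders map population activity to cursor
velocity:

* PVA (population vector algorithm):  v = ks * (nD/N) * sum_i u_i p_i
* OLE (optimal linear estimator):     v = ks * pinv(B) (r - b0), the
  least-squares solution with B the N x 3 matrix with rows m_i p_i^T.

Cursor position integrates velocity at the sampling interval; in the 2D
context the z-component of the decoded velocity is zeroed before
integration so movement stays in the xy-plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DecoderSpec, UnitTuning
from .tuning import SingularDesignError

__all__ = [
    "CursorState",
    "normalize_rates",
    "decode_pva",
    "decode_ole",
    "decode",
    "step_cursor",
]


@dataclass(frozen=True)
class CursorState:
    c: np.ndarray  # position, mm
    v: np.ndarray  # velocity, mm/s
    t: float       # time, s

    @staticmethod
    def initial() -> "CursorState":
        return CursorState(c=np.zeros(3), v=np.zeros(3), t=0.0)


def _pd_matrix(units: list[UnitTuning]) -> np.ndarray:
    return np.array([u.p for u in units])


def normalize_rates(r: np.ndarray, units: list[UnitTuning]) -> np.ndarray:
    """u_i = (r_i - b0_i) / m_i.  Requires every depth m_i > 0."""
    b0 = np.array([u.b0 for u in units])
    m = np.array([u.m for u in units])
    if np.any(m <= 0):
        bad = [units[i].unit_id for i in np.flatnonzero(m <= 0)]
        raise ValueError(f"non-positive modulation depth for units {bad}")
    return (np.asarray(r, dtype=float) - b0) / m


def decode_pva(u: np.ndarray, units: list[UnitTuning], spec: DecoderSpec) -> np.ndarray:
    """Population-vector decode of normalized rates to velocity (mm/s)."""
    P = _pd_matrix(units)
    v = spec.ks * (spec.n_dims / len(units)) * (P.T @ np.asarray(u, dtype=float))
    if spec.n_dims == 2:
        v = v.copy()
        v[2] = 0.0
    return v


def decode_ole(r: np.ndarray, units: list[UnitTuning], spec: DecoderSpec) -> np.ndarray:
    """Least-squares decode of raw rates to velocity (mm/s).

    Solves r - b0 = B v_norm for the normalized velocity and scales by ks.
    The full 3-column system is solved even for a planar decode; the
    z-component is zeroed afterward (matching the online implementation).
    """
    b0 = np.array([u.b0 for u in units])
    m = np.array([u.m for u in units])
    B = m[:, None] * _pd_matrix(units)
    if np.linalg.matrix_rank(B) < 3:
        raise SingularDesignError("OLE requires an N x 3 tuning matrix of rank 3")
    v_norm, _, _, _ = np.linalg.lstsq(B, np.asarray(r, dtype=float) - b0, rcond=None)
    v = spec.ks * v_norm
    if spec.n_dims == 2:
        v[2] = 0.0
    return v


def decode(r: np.ndarray, units: list[UnitTuning], spec: DecoderSpec) -> np.ndarray:
    """Dispatch on the decoder family; takes raw (smoothed) rates in Hz."""
    if spec.family == "pva":
        return decode_pva(normalize_rates(r, units), units, spec)
    return decode_ole(r, units, spec)


def step_cursor(state: CursorState, v: np.ndarray, spec: DecoderSpec) -> CursorState:
    """Integrate one sampling interval: c <- c + dt v, t <- t + dt."""
    v = np.asarray(v, dtype=float).copy()
    if spec.n_dims == 2:
        v[2] = 0.0
    return CursorState(c=state.c + spec.dt_s * v, v=v, t=state.t + spec.dt_s)
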