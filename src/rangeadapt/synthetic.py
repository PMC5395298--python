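"""Closed-loop center-out session simulator under competing mechanisms.

A population of cosine-tuned units drives a velocity decoder through blocks
of 3D (26-target) and 2D (16-target) center-out trials.  Firing rates are
generated from the speed-augmented tuning model

    r_i = b0_i + ||v|| bs_i + m_i (v . p_i)

evaluated at the subject's *intended* (normalized) velocity, with three
context-switch mechanisms layered on top:

* ``speed_gain``: the intended speed in the 2D context is multiplied by g,
  scaling every unit's planar tuning range by exactly g.
* ``reaiming``: in the 2D context the subject aims at a virtual point from a
  per-target aim table instead of the displayed target.
* ``dra`` (dynamic range adaptation): in the 2D context each unit's planar
  directional term m (d_xy . p_xy) is interpolated, with completeness
  weight alpha, toward the rescaled term m (d_xy . p_xy)/||p_xy||, so that
  at alpha = 1 the planar tuning range equals the unit's full range 2m.
  An optional exponential onset (time constant tau, in trials) ramps alpha
  over the first trials of the 2D block.

With ``noise="poisson"`` spike counts are drawn per 33 ms bin, smoothed
over the last five bins, and decoded online; trials fail at the 2 s reach
cap.  The ``loop="open"`` fast path draws whole-trial counts at the
intended-direction rate instead of running the cursor loop; it is
distribution-identical for trial-mean-rate analyses under the constant
straight-line intent assumed here, and is used for large Monte-Carlo
batteries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import decoder as dec
from .core_io import (
    TARGET_DISTANCE_MM,
    TARGET_RADIUS_MM,
    DecoderSpec,
    SessionData,
    TargetSet,
    TrialRecord,
    UnitTuning,
    canonical_targets,
)

__all__ = [
    "MechanismSpec",
    "SimConfig",
    "make_population",
    "intended_velocity",
    "unit_rate",
    "population_rates",
    "simulate_session",
    "elevated_aim_table",
    "push_aim_table",
]

#: Cursor-center to target-center acquisition distance, mm (sum of radii).
ACQUIRE_MM = 2.0 * TARGET_RADIUS_MM
#: Reach time limit, s.
REACH_CAP_S = 2.0


@dataclass(frozen=True)
class MechanismSpec:
    """Which context-switch mechanism generates the 2D-block rates."""

    kind: str = "null"  # "null" | "dra" | "speed_gain" | "reaiming"
    completeness: float = 1.0          # alpha, dra only
    gain: float = 1.2                  # g, speed_gain only
    aim_table: dict | None = None      # target_id -> unit 3-vector, reaiming only
    adaptation_tau: float | None = None  # trials; None = instantaneous (dra)
    bs: float = 0.0                    # additive speed term of the tuning model, Hz per unit speed

    def __post_init__(self) -> None:
        if self.kind not in ("null", "dra", "speed_gain", "reaiming"):
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        if self.kind == "dra" and not (0.0 <= self.completeness <= 1.0):
            raise ValueError("completeness must lie in [0, 1]")
        if self.kind == "speed_gain" and self.gain <= 0:
            raise ValueError("speed gain must be positive")
        if self.kind == "reaiming" and self.aim_table is None:
            raise ValueError("reaiming requires an aim_table")


@dataclass(frozen=True)
class SimConfig:
    n_units: int = 26
    pd_distribution: str = "uniform"  # "uniform" | "elevation_biased"
    pd_bias_deg: float = 30.0
    pd_concentration: float = 10.0    # 1/variance of elevation spread, rad^-2
    b0_range: tuple[float, float] = (8.0, 25.0)
    m_range: tuple[float, float] = (3.0, 12.0)
    noise: str = "poisson"            # "poisson" | "none"
    trials_per_target_3d: tuple[int, int] = (9, 13)
    trials_per_target_2d: tuple[int, int] = (15, 27)
    seed: int = 0
    decoder: DecoderSpec = field(default_factory=DecoderSpec)
    mechanism: MechanismSpec = field(default_factory=MechanismSpec)
    loop: str = "closed"              # "closed" | "open"
    block_order: tuple[int, ...] = (3, 2)
    session_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for lo, hi in (self.b0_range, self.m_range):
            if hi < lo or lo < 0:
                raise ValueError("empty or negative parameter range")
        if self.m_range[0] <= 0:
            raise ValueError("modulation depths must be positive for decoding")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        if self.loop not in ("closed", "open"):
            raise ValueError("loop must be 'closed' or 'open'")


def make_population(config: SimConfig, rng: np.random.Generator | None = None) -> list[UnitTuning]:
    """Draw a unit population; deterministic given the config seed.

    Preferred directions are uniform on the sphere or biased in elevation
    (azimuth uniform, elevation normal around the bias angle with standard
    deviation 1/sqrt(concentration) radians, clipped to +/-89 degrees).
    Baselines and depths are uniform in their ranges.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_units
    if config.pd_distribution == "uniform":
        v = rng.standard_normal((n, 3))
        P = v / np.linalg.norm(v, axis=1, keepdims=True)
    elif config.pd_distribution == "elevation_biased":
        az = rng.uniform(-180.0, 180.0, size=n)
        spread = math.degrees(1.0 / math.sqrt(config.pd_concentration))
        el = np.clip(rng.normal(config.pd_bias_deg, spread, size=n), -89.0, 89.0)
        azr, elr = np.radians(az), np.radians(el)
        P = np.column_stack(
            [np.cos(elr) * np.cos(azr), np.cos(elr) * np.sin(azr), np.sin(elr)]
        )
    else:
        raise ValueError(f"unknown pd_distribution {config.pd_distribution!r}")
    b0 = rng.uniform(*config.b0_range, size=n)
    m = rng.uniform(*config.m_range, size=n)
    return [
        UnitTuning(f"u{i:03d}", float(b0[i]), float(m[i]), P[i]) for i in range(n)
    ]


def elevated_aim_table(elevation_deg: float = 30.0) -> dict[str, np.ndarray]:
    """Aim table raising every common planar target by a fixed elevation.

    Models a subject who 'pushes' the cursor above (or, negative elevation,
    below) the plane in the 2D context: each of the 8 common targets maps to
    the unit vector at the same azimuth, tilted by ``elevation_deg``.  This
    is the canonical re-aiming scenario for a population whose preferred
    directions are biased toward that side of the plane.
    """
    t3, t2 = canonical_targets(3), canonical_targets(2)
    common = dict(t2.common_with(t3))
    el = math.radians(elevation_deg)
    table = {}
    for tid2 in t2.ids:
        d = t2.direction_of(tid2)
        azr = math.atan2(d[1], d[0])
        aim = np.array(
            [math.cos(el) * math.cos(azr), math.cos(el) * math.sin(azr), math.sin(el)]
        )
        table[tid2] = aim
        if tid2 in common:
            table[common[tid2]] = aim
    return table


def push_aim_table(
    elevation_deg: float = 30.0, bias_azimuth_deg: float = 0.0
) -> dict[str, np.ndarray]:
    """Aim table whose elevation varies with target azimuth.

    The aim for a target at azimuth a is tilted by elevation_deg *
    cos(a - bias_azimuth_deg): above the plane for targets on the population's
    preferred side and below the plane for the opposite targets.  This is the
    re-aiming geometry that produces mirrored tuning-range changes — units
    with preferred directions above the plane (near the bias azimuth)
    increase their planar range while their mirror images decrease it.
    """
    t3, t2 = canonical_targets(3), canonical_targets(2)
    common = dict(t2.common_with(t3))
    table = {}
    for tid2 in t2.ids:
        d = t2.direction_of(tid2)
        azr = math.atan2(d[1], d[0])
        el = math.radians(elevation_deg) * math.cos(azr - math.radians(bias_azimuth_deg))
        aim = np.array(
            [math.cos(el) * math.cos(azr), math.cos(el) * math.sin(azr), math.sin(el)]
        )
        table[tid2] = aim
        if tid2 in common:
            table[common[tid2]] = aim
    return table


def intended_velocity(
    mechanism: MechanismSpec,
    target_dir: np.ndarray,
    cursor_pos: np.ndarray,
    context_dim: int,
    base_speed: float,
    target_id: str | None = None,
    radius_mm: float = TARGET_DISTANCE_MM,
) -> np.ndarray:
    """Intended cursor velocity (mm/s): toward the (re-)aim point at base
    speed, times the gain g in the 2D context under ``speed_gain``."""
    goal_dir = np.asarray(target_dir, dtype=float)
    if mechanism.kind == "reaiming" and context_dim == 2 and target_id is not None:
        aim = mechanism.aim_table.get(target_id)
        if aim is not None:
            goal_dir = np.asarray(aim, dtype=float)
    goal = radius_mm * goal_dir
    delta = goal - np.asarray(cursor_pos, dtype=float)
    norm = np.linalg.norm(delta)
    if norm == 0.0:
        return np.zeros(3)
    speed = base_speed
    if mechanism.kind == "speed_gain" and context_dim == 2:
        speed *= mechanism.gain
    return speed * delta / norm


_warned_vertical = False


def population_rates(
    mechanism: MechanismSpec,
    b0: np.ndarray,
    m: np.ndarray,
    P: np.ndarray,
    v_norm: np.ndarray,
    context_dim: int,
    alpha_scale: float = 1.0,
) -> np.ndarray:
    """Vectorized mechanism-dependent rates (Hz) at a normalized intended
    velocity (unit magnitude at base speed).  Rates are floored at 0."""
    global _warned_vertical
    v_norm = np.asarray(v_norm, dtype=float)
    speed = np.linalg.norm(v_norm)
    if mechanism.kind == "dra" and context_dim == 2:
        alpha = mechanism.completeness * alpha_scale
        d_xy = v_norm[:2] / speed if speed > 0 else np.zeros(2)
        proj = P[:, :2] @ d_xy            # d_xy . p_xy
        pxy = np.linalg.norm(P[:, :2], axis=1)
        vertical = pxy == 0.0
        if np.any(vertical) and not _warned_vertical:
            warnings.warn(
                "unit(s) with exactly vertical preferred direction emit baseline "
                "rate under dynamic range adaptation",
                stacklevel=2,
            )
            _warned_vertical = True
        rescaled = np.divide(proj, pxy, out=np.zeros_like(proj), where=~vertical)
        mod = m * ((1.0 - alpha) * proj + alpha * rescaled)
        r = b0 + mod
    else:
        r = b0 + speed * mechanism.bs + m * (P @ v_norm)
    return np.maximum(r, 0.0)


def unit_rate(
    mechanism: MechanismSpec,
    unit: UnitTuning,
    v_intended: np.ndarray,
    context_dim: int,
    alpha_scale: float = 1.0,
) -> float:
    """Scalar convenience wrapper around :func:`population_rates`."""
    r = population_rates(
        mechanism,
        np.array([unit.b0]),
        np.array([unit.m]),
        unit.p[None, :],
        v_intended,
        context_dim,
        alpha_scale,
    )
    return float(r[0])


def _alpha_scale(mechanism: MechanismSpec, trial_in_block: int, context_dim: int) -> float:
    """Exponential adaptation onset: 1 - exp(-j/tau) over 2D-block trials."""
    if mechanism.kind != "dra" or mechanism.adaptation_tau is None or context_dim != 2:
        return 1.0
    return 1.0 - math.exp(-trial_in_block / mechanism.adaptation_tau)


def _trial_plan(
    targets: TargetSet, count_range: tuple[int, int], rng: np.random.Generator
) -> list[str]:
    counts = rng.integers(count_range[0], count_range[1] + 1, size=len(targets))
    plan = [tid for tid, c in zip(targets.ids, counts) for _ in range(c)]
    rng.shuffle(plan)
    return plan


def _simulate_trial_closed(
    config: SimConfig,
    spec: DecoderSpec,
    decode_mat: np.ndarray,
    b0: np.ndarray,
    m: np.ndarray,
    P: np.ndarray,
    target_id: str,
    target_dir: np.ndarray,
    context_dim: int,
    alpha_scale: float,
    rng: np.random.Generator,
) -> tuple[bool, float, np.ndarray]:
    """One closed-loop reach; returns (success, duration_s, mean rates).

    ``decode_mat`` maps baseline-subtracted (smoothed) rates to normalized
    velocity: pinv(B) for OLE, (nD/N) diag(1/m) P for PVA, precomputed once
    per context.  Semantics match :func:`population_rates` and the public
    decode operations exactly; this is the same loop with the per-bin
    linear algebra hoisted.
    """
    mech = config.mechanism
    goal = TARGET_DISTANCE_MM * target_dir
    aim_goal = goal
    if mech.kind == "reaiming" and context_dim == 2 and mech.aim_table is not None:
        aim = mech.aim_table.get(target_id)
        if aim is not None:
            aim_goal = TARGET_DISTANCE_MM * np.asarray(aim, dtype=float)
    dt = spec.dt_s
    max_bins = int(round(REACH_CAP_S / dt))
    poisson = config.noise == "poisson"
    gain = mech.gain if (mech.kind == "speed_gain" and context_dim == 2) else 1.0
    dra = mech.kind == "dra" and context_dim == 2
    if dra:
        alpha = mech.completeness * alpha_scale
        pxy = np.linalg.norm(P[:, :2], axis=1)
        vertical = pxy == 0.0
        mix = m * ((1.0 - alpha) + alpha * np.divide(
            1.0, pxy, out=np.zeros_like(pxy), where=~vertical))
        # mix * (d_xy . p_xy) reproduces population_rates' dra modulation
    n_smooth = spec.smoothing_bins
    recent: list[np.ndarray] = []
    smooth_sum = np.zeros(len(b0))
    sum_rates = np.zeros(len(b0))
    c = np.zeros(3)
    n_bins = 0
    success = False
    for _ in range(max_bins):
        delta = aim_goal - c
        norm = float(np.linalg.norm(delta))
        if norm == 0.0:
            v_norm = np.zeros(3)
        else:
            v_norm = (gain / norm) * delta
        if dra:
            sp = float(np.hypot(v_norm[0], v_norm[1]))
            if sp > 0:
                proj = (P[:, 0] * v_norm[0] + P[:, 1] * v_norm[1]) / sp
            else:
                proj = np.zeros(len(b0))
            rates = b0 + mix * proj
        else:
            speed = float(np.linalg.norm(v_norm))
            rates = b0 + speed * mech.bs + m * (P @ v_norm)
        np.maximum(rates, 0.0, out=rates)
        obs = rng.poisson(rates * dt) / dt if poisson else rates
        sum_rates += obs
        n_bins += 1
        recent.append(obs)
        smooth_sum += obs
        if len(recent) > n_smooth:
            smooth_sum -= recent.pop(0)
        smoothed = smooth_sum / len(recent)
        v = spec.ks * (decode_mat @ (smoothed - b0))
        if context_dim == 2:
            v[2] = 0.0
        c = c + dt * v
        if float(np.linalg.norm(c - goal)) <= ACQUIRE_MM:
            success = True
            break
    return success, n_bins * dt, sum_rates / n_bins


def _simulate_trial_open(
    config: SimConfig,
    units: list[UnitTuning],
    b0: np.ndarray,
    m: np.ndarray,
    P: np.ndarray,
    target_id: str,
    target_dir: np.ndarray,
    context_dim: int,
    alpha_scale: float,
    rng: np.random.Generator,
) -> tuple[bool, float, np.ndarray]:
    """Open-loop fast path: whole-trial counts at the intended-direction rate.

    The trial duration matches the noiseless closed-loop reach time (the
    number of 33 ms bins needed to cover 85 - 16 mm at speed ks).
    """
    mech = config.mechanism
    spec = config.decoder
    v_int = intended_velocity(
        mech, target_dir, np.zeros(3), context_dim, spec.ks, target_id
    )
    rates = population_rates(mech, b0, m, P, v_int / spec.ks, context_dim, alpha_scale)
    n_bins = int(math.ceil((TARGET_DISTANCE_MM - ACQUIRE_MM) / (spec.ks * spec.dt_s)))
    duration = n_bins * spec.dt_s
    if config.noise == "poisson":
        obs = rng.poisson(rates * duration) / duration
    else:
        obs = rates
    return True, duration, obs


def simulate_session(config: SimConfig, units: list[UnitTuning] | None = None) -> SessionData:
    """Simulate a full session of context blocks; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    if units is None:
        units = make_population(config, rng)
    b0 = np.array([u.b0 for u in units])
    m = np.array([u.m for u in units])
    P = np.array([u.p for u in units])
    unit_ids = [u.unit_id for u in units]

    trials: list[TrialRecord] = []
    block_order: list[tuple[int, int]] = []
    for block_index, context_dim in enumerate(config.block_order):
        block_order.append((block_index, context_dim))
        targets = canonical_targets(context_dim)
        count_range = (
            config.trials_per_target_3d if context_dim == 3 else config.trials_per_target_2d
        )
        plan = _trial_plan(targets, count_range, rng)
        spec = replace(config.decoder, n_dims=context_dim)
        if spec.family == "pva":
            decode_mat = (spec.n_dims / len(units)) * (P.T / m)
        else:
            decode_mat = np.linalg.pinv(m[:, None] * P)
        for j, target_id in enumerate(plan, start=1):
            target_dir = targets.direction_of(target_id)
            a = _alpha_scale(config.mechanism, j, context_dim)
            if config.loop == "closed":
                success, duration, mean_rates = _simulate_trial_closed(
                    config, spec, decode_mat, b0, m, P, target_id, target_dir,
                    context_dim, a, rng,
                )
            else:
                success, duration, mean_rates = _simulate_trial_open(
                    config, units, b0, m, P, target_id, target_dir,
                    context_dim, a, rng,
                )
            trials.append(
                TrialRecord(
                    session_id=config.session_id,
                    block_index=block_index,
                    context_dim=context_dim,
                    trial_index=j - 1,
                    target_id=target_id,
                    success=success,
                    duration_s=duration,
                    rates=dict(zip(unit_ids, mean_rates.tolist())),
                )
            )
    return SessionData(
        session_id=config.session_id,
        units=list(units),
        trials=trials,
        block_order=block_order,
        decoder=config.decoder,
    )
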