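"""Data model, canonical task geometry, and session file I/O.

The experiment is a center-out cursor task performed in two contexts: a 3D
context with 26 radial targets and a 2D context with 16 targets confined to
the horizontal (xy) plane.  Eight directions are shared between the contexts
and anchor every cross-context comparison.  Sessions are stored as plain
CSV/YAML files: a trial table (one row per trial, one rate column per unit),
a unit table (tuning parameters used by the decoder), and a small decoder
YAML.

Coordinate conventions: right-handed axes with x rightward, y forward and z
upward; azimuth is measured counter-clockwise from +x within the xy-plane and
elevation is positive above the plane.  Angles are stored in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TargetSet",
    "UnitTuning",
    "TrialRecord",
    "DecoderSpec",
    "SessionData",
    "canonical_targets",
    "load_session",
    "write_session",
    "ValidationError",
]

#: Target distance from the workspace origin, mm.
TARGET_DISTANCE_MM = 85.0
#: Radius of each spherical target, mm (the cursor has the same radius).
TARGET_RADIUS_MM = 8.0


class ValidationError(ValueError):
    """A session file or in-memory record violates the data-model contract."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero vector has no direction")
    return np.asarray(v, dtype=float) / n


def azimuth_elevation(p: Sequence[float]) -> tuple[float, float]:
    """Spherical decomposition of a direction vector, in degrees.

    Returns (azimuth in [-180, 180), elevation in [-90, 90]).  The vector
    need not be normalized; the zero vector raises ``ValueError``.
    """
    p = np.asarray(p, dtype=float)
    if np.linalg.norm(p) == 0.0:
        raise ValueError("zero vector has no angles")
    az = math.degrees(math.atan2(p[1], p[0]))
    if az >= 180.0:
        az -= 360.0
    el = math.degrees(math.atan2(p[2], math.hypot(p[0], p[1])))
    return az, el


def direction_from_angles(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Inverse of :func:`azimuth_elevation`; returns a unit 3-vector."""
    az = math.radians(azimuth_deg)
    el = math.radians(elevation_deg)
    return np.array(
        [math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)]
    )


@dataclass(frozen=True)
class TargetSet:
    """A set of radial target directions for one task context."""

    context_dim: int
    directions: np.ndarray  # (n, 3) unit rows
    ids: tuple[str, ...]
    radius_mm: float = TARGET_DISTANCE_MM
    target_radius_mm: float = TARGET_RADIUS_MM

    def __post_init__(self) -> None:
        if self.context_dim not in (2, 3):
            raise ValueError(f"context_dim must be 2 or 3, got {self.context_dim}")
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("target directions must be unit vectors")
        object.__setattr__(self, "directions", d)
        if len(self.ids) != len(d):
            raise ValueError("ids and directions length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def direction_of(self, target_id: str) -> np.ndarray:
        return self.directions[self.ids.index(target_id)]

    def common_with(self, other: "TargetSet", tol_rad: float = 1e-6) -> list[tuple[str, str]]:
        """Pairs of ids whose directions agree within an angular tolerance."""
        pairs = []
        for i, di in enumerate(self.directions):
            dots = np.clip(other.directions @ di, -1.0, 1.0)
            j = int(np.argmax(dots))
            if math.acos(dots[j]) <= tol_rad:
                pairs.append((self.ids[i], other.ids[j]))
        return pairs


@dataclass(frozen=True)
class UnitTuning:
    """Cosine-tuning parameters of one unit: rate = b0 + m * (d . p)."""

    unit_id: str
    b0: float  # baseline rate, Hz
    m: float   # modulation depth, Hz per unit normalized velocity
    p: np.ndarray  # preferred direction, unit 3-vector

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if abs(np.linalg.norm(p) - 1.0) > 1e-9:
            raise ValueError(f"unit {self.unit_id}: preferred direction not unit length")
        object.__setattr__(self, "p", p)

    @property
    def azimuth_deg(self) -> float:
        return azimuth_elevation(self.p)[0]

    @property
    def elevation_deg(self) -> float:
        return azimuth_elevation(self.p)[1]


@dataclass
class TrialRecord:
    session_id: str
    block_index: int
    context_dim: int
    trial_index: int
    target_id: str
    success: bool
    duration_s: float
    rates: dict[str, float]  # unit_id -> mean rate (Hz) presentation->acquisition
    counts: dict[str, np.ndarray] | None = None  # optional binned spike counts

    def __post_init__(self) -> None:
        if self.context_dim not in (2, 3):
            raise ValidationError("context_dim must be 2 or 3")
        if not (0.0 < self.duration_s <= 2.2):
            raise ValidationError(
                f"trial {self.trial_index}: duration {self.duration_s} outside (0, 2.2] s"
            )
        for uid, r in self.rates.items():
            if r < 0:
                raise ValidationError(f"trial {self.trial_index}: negative rate for {uid}")


@dataclass(frozen=True)
class DecoderSpec:
    """Decoder family and parameters; shared by the simulator and analyses."""

    family: str = "ole"          # "pva" or "ole"
    ks: float = 90.0             # speed factor, mm/s per unit normalized speed
    dt_s: float = 1.0 / 30.0     # sampling interval
    n_dims: int = 3
    smoothing_bins: int = 5

    def __post_init__(self) -> None:
        if self.family not in ("pva", "ole"):
            raise ValueError(f"unknown decoder family {self.family!r}")
        if self.ks <= 0 or self.dt_s <= 0:
            raise ValueError("ks and dt_s must be positive")
        if self.n_dims not in (2, 3):
            raise ValueError("n_dims must be 2 or 3")


@dataclass
class SessionData:
    session_id: str
    units: list[UnitTuning]
    trials: list[TrialRecord]
    block_order: list[tuple[int, int]]  # (block_index, context_dim)
    decoder: DecoderSpec

    def __post_init__(self) -> None:
        ids = {u.unit_id for u in self.units}
        ctx = dict(self.block_order)
        for t in self.trials:
            missing = set(t.rates) - ids
            if missing:
                raise ValidationError(
                    f"trial {t.trial_index} references unknown units {sorted(missing)}"
                )
            if t.block_index not in ctx:
                raise ValidationError(f"trial {t.trial_index}: block {t.block_index} not in block_order")
            if ctx[t.block_index] != t.context_dim:
                raise ValidationError(
                    f"trial {t.trial_index}: context {t.context_dim} conflicts with block_order"
                )

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit(self, unit_id: str) -> UnitTuning:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def trials_in_context(self, context_dim: int) -> list[TrialRecord]:
        return [t for t in self.trials if t.context_dim == context_dim]


def _grid_directions_3d() -> np.ndarray:
    """The 26 normalized nonzero vectors with components in {-1, 0, 1}.

    These cover cube corners (8), edge midpoints (12), and face centers (6),
    and contain the 8 planar directions at multiples of 45 degrees azimuth.
    """
    dirs = []
    for x in (-1, 0, 1):
        for y in (-1, 0, 1):
            for z in (-1, 0, 1):
                if (x, y, z) == (0, 0, 0):
                    continue
                dirs.append(_unit(np.array([x, y, z], dtype=float)))
    return np.array(dirs)


def canonical_targets(context_dim: int) -> TargetSet:
    """The canonical target geometry for a context.

    3D: the 26 directions of the 3x3x3 grid around the origin, normalized.
    2D: 16 equally spaced azimuths in the xy-plane (every 22.5 degrees,
    exact zero z-component).  Their intersection is the 8 planar directions
    at multiples of 45 degrees.  Deterministic and order-stable.
    """
    if context_dim == 3:
        dirs = _grid_directions_3d()
        ids = []
        for d in dirs:
            az, el = azimuth_elevation(d)
            ids.append(f"T3_{az:+08.2f}_{el:+07.2f}")
        return TargetSet(3, dirs, tuple(ids))
    if context_dim == 2:
        az = np.arange(16) * 22.5
        dirs = np.column_stack([np.cos(np.radians(az)), np.sin(np.radians(az)), np.zeros(16)])
        # exact zeros and exact unit norms for the cardinal directions
        dirs[np.abs(dirs) < 1e-15] = 0.0
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        # the 8 directions shared with the 3D context are bit-identical to
        # the corresponding grid directions (the targets are the same points)
        grid = _grid_directions_3d()
        for i in range(0, 16, 2):
            dots = grid @ dirs[i]
            dirs[i] = grid[int(np.argmax(dots))]
        ids = tuple(f"T2_{a:+08.2f}" for a in ((az + 180.0) % 360.0 - 180.0))
        return TargetSet(2, dirs, ids)
    raise ValueError(f"context_dim must be 2 or 3, got {context_dim}")


# ---------------------------------------------------------------------------
# CSV/YAML session round-trip
# ---------------------------------------------------------------------------

_TRIAL_COLS = [
    "session_id",
    "block_index",
    "context_dim",
    "trial_index",
    "target_id",
    "success",
    "duration_s",
]


def write_session(session: SessionData, out_dir: str | Path) -> dict[str, Path]:
    """Write trials.csv, units.csv and decoder.yaml under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unit_ids = session.unit_ids

    rows = []
    for t in session.trials:
        row: dict[str, object] = {
            "session_id": t.session_id,
            "block_index": t.block_index,
            "context_dim": t.context_dim,
            "trial_index": t.trial_index,
            "target_id": t.target_id,
            "success": t.success,
            "duration_s": t.duration_s,
        }
        for uid in unit_ids:
            row[f"rate_{uid}"] = t.rates.get(uid, np.nan)
        rows.append(row)
    cols = _TRIAL_COLS + [f"rate_{uid}" for uid in unit_ids]
    trials_df = pd.DataFrame(rows, columns=cols)
    trials_path = out / "trials.csv"
    trials_df.to_csv(trials_path, index=False, float_format="%.12g")

    units_df = pd.DataFrame(
        {
            "session_id": session.session_id,
            "unit_id": [u.unit_id for u in session.units],
            "b0_hz": [u.b0 for u in session.units],
            "m_hz": [u.m for u in session.units],
            "px": [u.p[0] for u in session.units],
            "py": [u.p[1] for u in session.units],
            "pz": [u.p[2] for u in session.units],
        }
    )
    units_path = out / "units.csv"
    units_df.to_csv(units_path, index=False, float_format="%.17g")

    dec = session.decoder
    decoder_path = out / "decoder.yaml"
    with open(decoder_path, "w") as fh:
        yaml.safe_dump(
            {
                "family": dec.family,
                "ks": dec.ks,
                "dt_s": dec.dt_s,
                "n_dims": dec.n_dims,
                "smoothing_bins": dec.smoothing_bins,
            },
            fh,
            sort_keys=False,
        )
    return {"trials": trials_path, "units": units_path, "decoder": decoder_path}


def _parse_error(path: Path, row: int | None, col: str, msg: str) -> ValidationError:
    where = f"{path.name}" + (f" row {row}" if row is not None else "") + f" column {col!r}"
    return ValidationError(f"{where}: {msg}")


def load_session(
    trials_path: str | Path,
    units_path: str | Path,
    decoder_path: str | Path,
) -> SessionData:
    """Load and validate a session from its three files."""
    trials_path, units_path, decoder_path = map(Path, (trials_path, units_path, decoder_path))
    units_df = pd.read_csv(units_path)
    for col in ("session_id", "unit_id", "b0_hz", "m_hz", "px", "py", "pz"):
        if col not in units_df.columns:
            raise _parse_error(units_path, None, col, "missing column")
    units = []
    for i, row in units_df.iterrows():
        p = np.array([row.px, row.py, row.pz], dtype=float)
        n = np.linalg.norm(p)
        if n == 0:
            raise _parse_error(units_path, int(i), "px", "zero preferred direction")
        units.append(UnitTuning(str(row.unit_id), float(row.b0_hz), float(row.m_hz), p / n))
    session_id = str(units_df["session_id"].iloc[0]) if len(units_df) else "session"

    with open(decoder_path) as fh:
        dec_raw = yaml.safe_load(fh)
    decoder = DecoderSpec(
        family=str(dec_raw["family"]),
        ks=float(dec_raw["ks"]),
        dt_s=float(dec_raw["dt_s"]),
        n_dims=int(dec_raw["n_dims"]),
        smoothing_bins=int(dec_raw.get("smoothing_bins", 5)),
    )

    trials_df = pd.read_csv(trials_path)
    for col in _TRIAL_COLS:
        if col not in trials_df.columns:
            raise _parse_error(trials_path, None, col, "missing column")
    rate_cols = [c for c in trials_df.columns if c.startswith("rate_")]
    known = {u.unit_id for u in units}
    for c in rate_cols:
        uid = c[len("rate_"):]
        if uid not in known:
            raise _parse_error(trials_path, None, c, f"unknown unit_id {uid!r}")

    trials = []
    block_order: dict[int, int] = {}
    for i, row in trials_df.iterrows():
        rates = {}
        for c in rate_cols:
            v = row[c]
            if pd.notna(v):
                if v < 0:
                    raise _parse_error(trials_path, int(i), c, f"negative rate {v}")
                rates[c[len("rate_"):]] = float(v)
        try:
            rec = TrialRecord(
                session_id=str(row.session_id),
                block_index=int(row.block_index),
                context_dim=int(row.context_dim),
                trial_index=int(row.trial_index),
                target_id=str(row.target_id),
                success=bool(row.success),
                duration_s=float(row.duration_s),
                rates=rates,
            )
        except (ValidationError, ValueError) as exc:
            raise _parse_error(trials_path, int(i), "trial", str(exc)) from exc
        block_order.setdefault(rec.block_index, rec.context_dim)
        trials.append(rec)

    return SessionData(
        session_id=session_id,
        units=units,
        trials=trials,
        block_order=sorted(block_order.items()),
        decoder=decoder,
    )


def load_targets_csv(path: str | Path, context_dim: int) -> TargetSet:
    """Optional override of the canonical geometry from a targets.csv table."""
    df = pd.read_csv(path)
    df = df[df["context_dim"] == context_dim]
    if df.empty:
        raise ValidationError(f"no targets with context_dim={context_dim} in {path}")
    dirs = df[["dx", "dy", "dz"]].to_numpy(dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return TargetSet(context_dim, dirs, tuple(str(t) for t in df["target_id"]))
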