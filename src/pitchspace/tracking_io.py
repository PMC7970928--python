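"""Tracking and pass-event I/O.

Defines the in-memory containers (player states, frame snapshots, pass events)
and their CSV schemas, plus finite-difference velocity estimation for tracking
feeds that provide positions only.

Tracking CSV columns: ``frame, time_s, team, player_id, x_m, y_m, is_gk``
with optional ``vx_mps, vy_mps``; one row per player per frame, 22 players per
frame. Pass CSV columns: ``t_o_s, x_o_m, y_o_m, t_e_s, x_e_m, y_e_m, q,
pre_shot, possession`` (``pre_shot`` optional, default 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_DT, MAX_SPEED, POSITION_PAD, Pitch
from .errors import SchemaError, ValidationError

SIDES = ("home", "away")

_TRACKING_COLS = ["frame", "time_s", "team", "player_id", "x_m", "y_m", "is_gk"]
_PASS_COLS = ["t_o_s", "x_o_m", "y_o_m", "t_e_s", "x_e_m", "y_e_m", "q", "possession"]


def other_side(side: str) -> str:
    if side not in SIDES:
        raise ValidationError(f"unknown side {side!r}; expected one of {SIDES}")
    return "away" if side == "home" else "home"


@dataclass
class PlayerState:
    """One player's kinematic state at a frame."""

    player_id: str
    team: str
    position: np.ndarray  # (2,) m, pitch-centred
    velocity: np.ndarray  # (2,) m/s
    is_goalkeeper: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)
        self.velocity = np.asarray(self.velocity, dtype=float).reshape(2)
        if self.team not in SIDES:
            raise ValidationError(
                f"player {self.player_id}: team must be one of {SIDES}, got {self.team!r}"
            )

    def validate(self, pitch: Pitch | None = None) -> None:
        pitch = pitch or Pitch()
        if not pitch.contains(self.position, pad=POSITION_PAD):
            raise ValidationError(
                f"player {self.player_id}: position {self.position} outside "
                f"pitch bounds (+{POSITION_PAD} m pad)"
            )
        speed = float(np.linalg.norm(self.velocity))
        if speed >= MAX_SPEED:
            raise ValidationError(
                f"player {self.player_id}: speed {speed:.1f} m/s >= {MAX_SPEED} m/s"
            )


@dataclass
class Snapshot:
    """All 22 player states at one instant, plus which side has the ball.

    ``possession`` may be None for tracking feeds without ball data; analyses
    that need an offense side will then require it explicitly.
    """

    time: float
    players: list[PlayerState] = field(default_factory=list)
    possession: str | None = None
    frame: int | None = None

    def side(self, team: str) -> list[PlayerState]:
        if team not in SIDES:
            raise ValidationError(f"unknown side {team!r}")
        return [p for p in self.players if p.team == team]

    def field_players(self) -> list[PlayerState]:
        return [p for p in self.players if not p.is_goalkeeper]

    def validate(self, pitch: Pitch | None = None) -> None:
        tag = f"frame {self.frame}" if self.frame is not None else f"t={self.time}"
        if self.time < 0:
            raise ValidationError(f"{tag}: time must be >= 0")
        if len(self.players) != 22:
            raise ValidationError(f"{tag}: expected 22 players, found {len(self.players)}")
        for team in SIDES:
            members = self.side(team)
            if len(members) != 11:
                raise ValidationError(
                    f"{tag}: expected 11 {team} players, found {len(members)}"
                )
            n_gk = sum(p.is_goalkeeper for p in members)
            if n_gk != 1:
                raise ValidationError(f"{tag}: expected 1 {team} goalkeeper, found {n_gk}")
        for p in self.players:
            p.validate(pitch)


@dataclass
class PassEvent:
    """One pass record: origin/end times and coordinates, outcome, flags."""

    t_o: float
    x_o: np.ndarray  # (2,) m
    t_e: float
    x_e: np.ndarray  # (2,) m
    q: int  # 1 success, 0 failure
    pre_shot: bool = False
    possession: str | None = None

    def __post_init__(self) -> None:
        self.x_o = np.asarray(self.x_o, dtype=float).reshape(2)
        self.x_e = np.asarray(self.x_e, dtype=float).reshape(2)
        if self.q not in (0, 1):
            raise ValidationError(f"pass outcome q must be 0 or 1, got {self.q!r}")
        self.q = int(self.q)
        if self.t_e < self.t_o:
            raise ValidationError(f"pass ends before it starts: t_o={self.t_o}, t_e={self.t_e}")
        if self.possession is not None and self.possession not in SIDES:
            raise ValidationError(f"possession must be one of {SIDES}, got {self.possession!r}")


def estimate_velocities(positions, dt: float, window: int = 5) -> np.ndarray:
    """Finite-difference velocities from a fixed-rate position series.

    Interior frames use a central difference across the window (exact for
    affine motion, O(dt^2) error otherwise); the first and last half-window
    frames fall back to one-sided differences over the same span.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:
        positions = positions[:, None]
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    if window < 3 or window % 2 == 0:
        raise ValidationError(f"window must be an odd count >= 3, got {window}")
    n = len(positions)
    if n < window:
        raise ValidationError(
            f"series of length {n} is shorter than window {window}; "
            f"need at least {window} frames"
        )
    h = (window - 1) // 2
    vel = np.empty_like(positions)
    vel[h : n - h] = (positions[2 * h :] - positions[: n - 2 * h]) / (2 * h * dt)
    vel[:h] = (positions[h : 2 * h] - positions[:h]) / (h * dt)
    vel[n - h :] = (positions[n - h :] - positions[n - 2 * h : n - h]) / (h * dt)
    return vel


def _estimate_track_velocities(positions: np.ndarray, dt: float, window: int) -> np.ndarray:
    """Velocity estimation with graceful degradation for short tracks."""
    n = len(positions)
    if n == 1:
        warnings.warn("isolated single-frame track: assigning zero velocity", stacklevel=2)
        return np.zeros_like(positions)
    if n < window:
        window = n if n % 2 == 1 else n - 1
        if window < 3:  # exactly two frames: forward/backward difference
            v = (positions[1] - positions[0]) / dt
            return np.broadcast_to(v, positions.shape).copy()
    return estimate_velocities(positions, dt, window)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} file is missing required column '{col}'")


def read_tracking(
    path: str | Path,
    *,
    pitch: Pitch | None = None,
    window: int = 5,
    validate: bool = True,
) -> list[Snapshot]:
    """Read a tracking CSV into time-ordered snapshots.

    Velocities are taken from ``vx_mps``/``vy_mps`` when present, otherwise
    estimated per player by central differences at the file's sampling rate.
    """
    df = pd.read_csv(path)
    _require_columns(df, _TRACKING_COLS, "tracking")
    bad_team = set(df["team"].unique()) - set(SIDES)
    if bad_team:
        raise ValidationError(f"unknown team labels {sorted(bad_team)}; expected {SIDES}")
    df = df.sort_values(["time_s", "frame"], kind="stable")

    has_vel = "vx_mps" in df.columns and "vy_mps" in df.columns
    if not has_vel:
        times = np.sort(df["time_s"].unique())
        dt = float(np.median(np.diff(times))) if len(times) > 1 else DEFAULT_DT
        df = df.copy()
        df["vx_mps"] = 0.0
        df["vy_mps"] = 0.0
        for _, track in df.groupby(["team", "player_id"], sort=False):
            pos = track[["x_m", "y_m"]].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vel = _estimate_track_velocities(pos, dt, window)
            df.loc[track.index, ["vx_mps", "vy_mps"]] = vel

    has_possession = "possession" in df.columns
    snapshots: list[Snapshot] = []
    for frame_id, rows in df.groupby("frame", sort=False):
        players = [
            PlayerState(
                player_id=str(r.player_id),
                team=str(r.team),
                position=(r.x_m, r.y_m),
                velocity=(r.vx_mps, r.vy_mps),
                is_goalkeeper=bool(int(r.is_gk)),
            )
            for r in rows.itertuples()
        ]
        possession = None
        if has_possession:
            possession = str(rows["possession"].iloc[0])
        snap = Snapshot(
            time=float(rows["time_s"].iloc[0]),
            players=players,
            possession=possession,
            frame=int(frame_id),
        )
        if validate:
            snap.validate(pitch)
        snapshots.append(snap)
    snapshots.sort(key=lambda s: s.time)
    return snapshots


def write_tracking(path: str | Path, snapshots: Iterable[Snapshot]) -> None:
    """Write snapshots back to the tracking CSV schema (velocities included)."""
    rows = []
    for i, snap in enumerate(snapshots):
        frame = snap.frame if snap.frame is not None else i
        for p in snap.players:
            row = {
                "frame": frame,
                "time_s": snap.time,
                "team": p.team,
                "player_id": p.player_id,
                "x_m": p.position[0],
                "y_m": p.position[1],
                "is_gk": int(p.is_goalkeeper),
                "vx_mps": p.velocity[0],
                "vy_mps": p.velocity[1],
            }
            if snap.possession is not None:
                row["possession"] = snap.possession
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def nearest_snapshot(snapshots: Sequence[Snapshot], t: float, tol: float = DEFAULT_DT) -> Snapshot:
    """Snapshot whose timestamp is nearest to ``t`` (must be within ``tol``)."""
    if not snapshots:
        raise ValidationError("no snapshots available")
    times = np.array([s.time for s in snapshots])
    i = int(np.argmin(np.abs(times - t)))
    if abs(times[i] - t) > tol + 1e-9:
        raise ValidationError(
            f"no snapshot within {tol} s of t={t} (nearest is {times[i]})"
        )
    return snapshots[i]


def read_passes(path: str | Path) -> list[PassEvent]:
    """Read a pass-event CSV; the outcome column ``q`` is parsed strictly as 0/1."""
    df = pd.read_csv(path)
    _require_columns(df, _PASS_COLS, "passes")
    if "pre_shot" not in df.columns:
        df = df.assign(pre_shot=0)
    q = df["q"].to_numpy()
    if not np.isin(q, (0, 1)).all():
        bad = sorted(set(q) - {0, 1})
        raise ValidationError(f"pass outcome q must be 0 or 1; found {bad}")
    return [
        PassEvent(
            t_o=float(r.t_o_s),
            x_o=(r.x_o_m, r.y_o_m),
            t_e=float(r.t_e_s),
            x_e=(r.x_e_m, r.y_e_m),
            q=int(r.q),
            pre_shot=bool(int(r.pre_shot)),
            possession=str(r.possession),
        )
        for r in df.itertuples()
    ]


def passes_frame(passes: Iterable[PassEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_o_s": p.t_o,
            "x_o_m": p.x_o[0],
            "y_o_m": p.x_o[1],
            "t_e_s": p.t_e,
            "x_e_m": p.x_e[0],
            "y_e_m": p.x_e[1],
            "q": p.q,
            "pre_shot": int(p.pre_shot),
            "possession": p.possession,
        }
        for p in passes
    )


def write_passes(path: str | Path, passes: Iterable[PassEvent]) -> None:
    passes_frame(passes).to_csv(path, index=False)


def write_features(path: str | Path, passes: Sequence[PassEvent], features) -> None:
    """Write the per-pass feature table: all pass columns plus z1, z2, r_tilde."""
    if len(passes) != len(features):
        raise ValidationError(
            f"got {len(passes)} passes but {len(features)} feature rows"
        )
    df = passes_frame(passes)
    df["z1"] = [f.z1 for f in features]
    df["z2"] = [f.z2 for f in features]
    df["r_tilde"] = [f.r_tilde for f in features]
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV (needs at least z1 and q; z2/r_tilde/pre_shot optional)."""
    df = pd.read_csv(path)
    _require_columns(df, ["z1", "q"], "features")
    q = df["q"].to_numpy()
    if not np.isin(q, (0, 1)).all():
        raise ValidationError("feature outcome q must be 0 or 1")
    return df
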