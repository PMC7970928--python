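"""Team arrival-time fields, the z1/z2 transform and the four-way division.

Every pitch location x at time t carries two arrival times: tau_of, the
minimum over the ball-possessing (offense) team of each player's minimum
arrival time, and tau_df, the same for the defending team. Rotating the
(tau_of, tau_df) plane by 45 degrees gives two orthogonal, interpretable
coordinates:

    z1 = (tau_df - tau_of) / sqrt(2)   degree of safety (offense first => z1 > 0)
    z2 = (tau_df + tau_of) / sqrt(2)   degree of sparsity (everyone far => large)

The rotation preserves the Euclidean norm, so z1^2 + z2^2 = tau_of^2 + tau_df^2
cell by cell. The pitch is divided into four spaces by the axes z1 = 0 and
z2 = 2: (A) safe dense, (B) safe sparse, (C) risky sparse, (D) risky dense.
On the boundaries we label z1 = 0 as risky and z2 = 2 as dense.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import Pitch
from .errors import NumericalError, ValidationError
from .motion_model import MotionParams, arrival_time_field, min_arrival_time
from .tracking_io import Snapshot, other_side

SQRT2 = np.sqrt(2.0)

#: default cell spacing (m) of the evaluation grid
DEFAULT_RESOLUTION = 0.5
#: default thresholds of the four-way division
Z1_THRESHOLD = 0.0
Z2_THRESHOLD = 2.0


@dataclass(frozen=True)
class Grid:
    """Uniform grid of cell centres covering the pitch, boundary included."""

    x: np.ndarray  # (nx,) m
    y: np.ndarray  # (ny,) m
    resolution: float

    @classmethod
    def from_pitch(cls, pitch: Pitch | None = None, resolution: float = DEFAULT_RESOLUTION) -> "Grid":
        pitch = pitch or Pitch()
        if resolution <= 0:
            raise ValidationError(f"grid resolution must be positive, got {resolution}")
        nx = round(pitch.length / resolution)
        ny = round(pitch.width / resolution)
        if abs(nx * resolution - pitch.length) > 1e-9 or abs(ny * resolution - pitch.width) > 1e-9:
            raise ValidationError(
                f"resolution {resolution} m does not divide the "
                f"{pitch.length} x {pitch.width} m pitch evenly"
            )
        x = pitch.x_min + resolution * np.arange(nx + 1)
        y = pitch.y_min + resolution * np.arange(ny + 1)
        return cls(x=x, y=y, resolution=resolution)

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx): field arrays are indexed [iy, ix]."""
        return (len(self.y), len(self.x))

    @property
    def n_cells(self) -> int:
        return len(self.x) * len(self.y)

    def points(self) -> np.ndarray:
        """All cell centres as an (n_cells, 2) array, row-major in (iy, ix)."""
        xx, yy = np.meshgrid(self.x, self.y)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class SpaceField:
    """Per-cell evaluation of one snapshot; arrays are shaped ``grid.shape``."""

    grid: Grid
    tau_of: np.ndarray  # s
    tau_df: np.ndarray  # s
    z1: np.ndarray
    z2: np.ndarray
    region: np.ndarray  # labels 'A'..'D'
    time: float
    possession: str


def team_min_arrival(
    snapshot: Snapshot,
    side: str,
    target,
    params: MotionParams | None = None,
    *,
    include_goalkeepers: bool = True,
) -> float:
    """Minimum over a side's players of the per-player minimum arrival time."""
    params = params or MotionParams()
    players = snapshot.side(side)
    if not include_goalkeepers:
        players = [p for p in players if not p.is_goalkeeper]
    if not players:
        raise ValidationError(f"side {side!r} has no players to evaluate")
    return min(min_arrival_time(p, params, target) for p in players)


def z_transform(tau_of, tau_df):
    """Rotate arrival times into (z1, z2); both inputs must be non-negative."""
    tau_of = np.asarray(tau_of, dtype=float)
    tau_df = np.asarray(tau_df, dtype=float)
    if np.any(tau_of < 0) or np.any(tau_df < 0):
        raise ValidationError("arrival times must be non-negative")
    z1 = (tau_df - tau_of) / SQRT2
    z2 = (tau_df + tau_of) / SQRT2
    if z1.ndim == 0:
        return float(z1), float(z2)
    return z1, z2


def classify_region(z1, z2, z1_threshold: float = Z1_THRESHOLD, z2_threshold: float = Z2_THRESHOLD):
    """Label locations A/B/C/D from the signs of z1 and z2 - threshold.

    Boundary convention: z1 on the threshold counts as risky, z2 on the
    threshold counts as dense, so (0, 2) -> 'D'.
    """
    z1 = np.asarray(z1)
    z2 = np.asarray(z2)
    safe = z1 > z1_threshold
    sparse = z2 > z2_threshold
    region = np.where(
        safe,
        np.where(sparse, "B", "A"),
        np.where(sparse, "C", "D"),
    )
    if region.ndim == 0:
        return str(region)
    return region


def _team_tau_field(
    snapshot: Snapshot,
    side: str,
    points: np.ndarray,
    params: MotionParams,
    include_goalkeepers: bool,
) -> np.ndarray:
    players = snapshot.side(side)
    if not include_goalkeepers:
        players = [p for p in players if not p.is_goalkeeper]
    if not players:
        raise ValidationError(f"side {side!r} has no players to evaluate")
    tau = np.full(len(points), np.inf)
    for p in players:
        tau = np.minimum(tau, arrival_time_field(p.position, p.velocity, params, points))
    return tau


def compute_space_field(
    snapshot: Snapshot,
    grid: Grid | None = None,
    params: MotionParams | None = None,
    *,
    possession: str | None = None,
    include_goalkeepers: bool = True,
    z1_threshold: float = Z1_THRESHOLD,
    z2_threshold: float = Z2_THRESHOLD,
) -> SpaceField:
    """Evaluate tau_of/tau_df, z1/z2 and the region label on every grid cell.

    The offense side is the snapshot's possession label unless overridden.
    Deterministic: identical snapshot, grid and parameters give an identical
    field.
    """
    grid = grid or Grid.from_pitch()
    params = params or MotionParams()
    offense = possession or snapshot.possession
    if offense is None:
        raise ValidationError(
            "snapshot has no possession label; pass possession='home'|'away'"
        )
    defense = other_side(offense)
    pts = grid.points()
    try:
        tau_of = _team_tau_field(snapshot, offense, pts, params, include_goalkeepers)
        tau_df = _team_tau_field(snapshot, defense, pts, params, include_goalkeepers)
    except NumericalError as err:  # attach grid context
        raise NumericalError(f"space-field evaluation failed on the grid: {err}") from err
    z1, z2 = z_transform(tau_of, tau_df)
    region = classify_region(z1, z2, z1_threshold, z2_threshold)
    shape = grid.shape
    return SpaceField(
        grid=grid,
        tau_of=tau_of.reshape(shape),
        tau_df=tau_df.reshape(shape),
        z1=z1.reshape(shape),
        z2=z2.reshape(shape),
        region=region.reshape(shape),
        time=snapshot.time,
        possession=offense,
    )


def field_frame(field: SpaceField) -> pd.DataFrame:
    """Long-format table: one row per cell with coordinates, taus, z's, region."""
    pts = field.grid.points()
    return pd.DataFrame(
        {
            "x_m": pts[:, 0],
            "y_m": pts[:, 1],
            "tau_of_s": field.tau_of.ravel(),
            "tau_df_s": field.tau_df.ravel(),
            "z1": field.z1.ravel(),
            "z2": field.z2.ravel(),
            "region": field.region.ravel(),
        }
    )


def write_field(path: str | Path, field: SpaceField) -> None:
    field_frame(field).to_csv(path, index=False)


def plot_field(
    field: SpaceField,
    path: str | Path,
    *,
    quantity: str = "tau_df",
    cap: float | None = 2.0,
) -> None:
    """Contour plot of one field quantity, optionally capped (seconds) for display."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = getattr(field, quantity)
    if cap is not None:
        values = np.minimum(values, cap)
    fig, ax = plt.subplots(figsize=(9, 6))
    cs = ax.contourf(field.grid.x, field.grid.y, values, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=ax, label=quantity)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120)
    plt.close(fig)
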