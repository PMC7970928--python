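"""Formation geometry: centroid, spread, and the formation-relative pass distance.

The formation is summarised by the centroid of the 20 outfield players (both
teams, goalkeepers excluded) and its spread, the root-mean-square distance of
those players from the centroid. A pass ending at x_e is placed relative to
the formation through

    R~ = || x_e - x_c(t_o) || / sigma(t_o),

the end-point distance from the centroid in units of the spread; R~ < 1 means
the pass ends roughly inside the formation. Plotting the mean R~ against the
sparsity coordinate z2 of the end point locates the sparsity value at which
passes leave the formation (empirically near z2 = 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tracking_io import PassEvent, Snapshot

#: default z2 bin width for the mean-R~ curve
DEFAULT_Z2_BIN = 0.25
#: a pass snapshot must sit within one 25 Hz frame of the pass origin time
FRAME_TOL = 0.04

N_FIELD_PLAYERS = 20


@dataclass(frozen=True)
class FormationSummary:
    """Centroid (m) and RMS spread (m) of the 20 outfield players at one time."""

    centroid: np.ndarray
    spread: float
    time: float


def formation_summary(snapshot: Snapshot) -> FormationSummary:
    """Centroid and spread of the outfield players of both teams."""
    players = snapshot.field_players()
    if len(players) != N_FIELD_PLAYERS:
        raise ValidationError(
            f"formation summary needs exactly {N_FIELD_PLAYERS} outfield players, "
            f"found {len(players)}"
        )
    pos = np.array([p.position for p in players])
    centroid = pos.mean(axis=0)
    spread = float(np.sqrt(np.mean(np.sum((pos - centroid) ** 2, axis=1))))
    return FormationSummary(centroid=centroid, spread=spread, time=snapshot.time)


def r_tilde(pass_event: PassEvent, snapshot: Snapshot) -> float:
    """Formation-relative distance of the pass end point at the origin time."""
    if abs(snapshot.time - pass_event.t_o) > FRAME_TOL + 1e-9:
        raise ValidationError(
            f"snapshot at t={snapshot.time} is not within {FRAME_TOL} s of "
            f"pass origin t_o={pass_event.t_o}"
        )
    summary = formation_summary(snapshot)
    if summary.spread <= 0:
        raise ValidationError("degenerate formation: spread is zero")
    return float(np.linalg.norm(pass_event.x_e - summary.centroid) / summary.spread)


def r_tilde_vs_z2_curve(features: Sequence | pd.DataFrame, bin_width: float = DEFAULT_Z2_BIN) -> pd.DataFrame:
    """Mean R~ in bins of z2; empty bins are omitted.

    Accepts a feature DataFrame (columns z2, r_tilde) or a sequence of
    objects with ``z2`` and ``r_tilde`` attributes. Returns columns
    ``z2_bin_center, mean_r_tilde, n``.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin width must be positive, got {bin_width}")
    if isinstance(features, pd.DataFrame):
        z2 = features["z2"].to_numpy(dtype=float)
        rt = features["r_tilde"].to_numpy(dtype=float)
    else:
        z2 = np.array([f.z2 for f in features], dtype=float)
        rt = np.array([f.r_tilde for f in features], dtype=float)
    if len(z2) == 0:
        raise ValidationError("no features to bin")
    idx = np.floor(z2 / bin_width).astype(int)
    out = (
        pd.DataFrame({"idx": idx, "r_tilde": rt})
        .groupby("idx")["r_tilde"]
        .agg(["mean", "size"])
        .reset_index()
    )
    return pd.DataFrame(
        {
            "z2_bin_center": (out["idx"] + 0.5) * bin_width,
            "mean_r_tilde": out["mean"],
            "n": out["size"].astype(int),
        }
    )
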