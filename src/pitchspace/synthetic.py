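"""Seeded synthetic tracking and pass-data generators.

Real professional tracking feeds are proprietary, so every stage of the
pipeline is exercised on generated data that carries the statistical
structure the analysis assumes:

* 22-player snapshots: a 4-4-2 template per side with Gaussian positional
  jitter (sd 3 m), one goalkeeper per side near each goal line, and random
  velocities with speeds uniform on (0, 8) m/s;
* labelled safety values: z1 | q drawn from class-conditional normals with
  a Bernoulli success prior — the structure behind the class-normal fits;
* outcome passes: z1 uniform on (-2, 3) with q ~ Bernoulli(expit(a z1 + b))
  — the structure behind the logistic fit;
* full (snapshot, pass) pairs whose ground-truth z1/z2 are recomputable from
  the emitted snapshot — the end-to-end fixture.

Default model parameters are the published fits on professional match data:
class normals (mu1, sigma1) = (0.69, 0.54) and (mu0, sigma0) = (-0.25, 0.38),
logistic coefficients (a, b) = (4.68, 0.48). All randomness flows from one
seed through ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .config import Pitch
from .errors import ValidationError
from .motion_model import MotionParams
from .pass_stats import PassFeature
from .space_field import team_min_arrival, z_transform
from .tracking_io import PassEvent, PlayerState, Snapshot, other_side

MODES = ("class_normals", "sigmoid_outcomes", "full_snapshots")


@dataclass
class SimConfig:
    """Generator settings; defaults state the emulated world once."""

    seed: int = 0
    n_passes: int = 1000
    pitch: Pitch = field(default_factory=Pitch)
    mode: str = "sigmoid_outcomes"
    # class-conditional normal structure of z1
    mu1: float = 0.69
    sigma1: float = 0.54
    mu0: float = -0.25
    sigma0: float = 0.38
    #: prior success probability; professional pass completion runs near 0.78
    prior1: float = 0.78
    # logistic success model
    a: float = 4.68
    b: float = 0.48
    #: design range of z1 for outcome generation
    z1_low: float = -2.0
    z1_high: float = 3.0
    #: player speed cap (m/s) and positional jitter sd (m) for snapshots
    speed_max: float = 8.0
    jitter_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (0.0 <= self.prior1 <= 1.0):
            raise ValidationError(f"prior1 must be in [0, 1], got {self.prior1}")
        if self.sigma1 < 0 or self.sigma0 < 0:
            raise ValidationError("class sigmas must be non-negative")
        if self.n_passes < 0:
            raise ValidationError("n_passes must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# 4-4-2 template for the side defending the left goal, attacking rightwards;
# mirrored in x for the other side.
_TEMPLATE_442 = np.array(
    [
        (-50.0, 0.0),  # goalkeeper (first row)
        (-35.0, -22.5), (-35.0, -7.5), (-35.0, 7.5), (-35.0, 22.5),
        (-15.0, -22.5), (-15.0, -7.5), (-15.0, 7.5), (-15.0, 22.5),
        (-2.0, -9.0), (-2.0, 9.0),
    ]
)


def gen_snapshot(config: SimConfig, rng: np.random.Generator, *, time: float = 0.0) -> Snapshot:
    """One random 22-player snapshot around mirrored 4-4-2 templates."""
    players: list[PlayerState] = []
    scale = np.array([config.pitch.length / 105.0, config.pitch.width / 68.0])
    for side, sign in (("home", 1.0), ("away", -1.0)):
        base = _TEMPLATE_442 * scale * np.array([sign, 1.0])
        jitter = rng.normal(0.0, config.jitter_sd, size=base.shape)
        jitter[0] *= 0.3  # keep the goalkeeper near the goal line
        pos = base + jitter
        pos[:, 0] = np.clip(pos[:, 0], config.pitch.x_min + 0.2, config.pitch.x_max - 0.2)
        pos[:, 1] = np.clip(pos[:, 1], config.pitch.y_min + 0.2, config.pitch.y_max - 0.2)
        speeds = rng.uniform(0.0, config.speed_max, size=len(base))
        angles = rng.uniform(0.0, 2.0 * np.pi, size=len(base))
        vel = speeds[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
        for i in range(len(base)):
            players.append(
                PlayerState(
                    player_id=f"{side}_{i:02d}",
                    team=side,
                    position=pos[i],
                    velocity=vel[i],
                    is_goalkeeper=(i == 0),
                )
            )
    possession = "home" if rng.random() < 0.5 else "away"
    return Snapshot(time=time, players=players, possession=possession)


def gen_labeled_z1(
    config: SimConfig, rng: np.random.Generator, n: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(z1, q) pairs: q ~ Bernoulli(prior1), z1 | q ~ Normal(mu_q, sigma_q)."""
    n = config.n_passes if n is None else n
    q = (rng.random(n) < config.prior1).astype(int)
    mu = np.where(q == 1, config.mu1, config.mu0)
    sigma = np.where(q == 1, config.sigma1, config.sigma0)
    z1 = rng.normal(mu, sigma)
    return z1, q


def gen_outcome_passes(
    config: SimConfig, rng: np.random.Generator, n: int | None = None
) -> list[PassFeature]:
    """Pass features whose outcomes follow the logistic success model.

    z1 is uniform on the design range, q ~ Bernoulli(expit(a z1 + b)); z2 is
    drawn uniformly above |z1| (arrival times force z2 >= |z1|), and R~ rises
    with z2 so that the mean-R~ curve crosses 1 near z2 = 2.
    """
    n = config.n_passes if n is None else n
    z1 = rng.uniform(config.z1_low, config.z1_high, size=n)
    q = (rng.random(n) < expit(config.a * z1 + config.b)).astype(int)
    z2 = np.abs(z1) + rng.uniform(0.0, 4.0, size=n)
    rt = np.clip(z2 / 2.0 + rng.normal(0.0, 0.15, size=n), 0.0, None)
    pre = rng.random(n) < 0.1
    return [
        PassFeature(z1=float(z1[i]), z2=float(z2[i]), r_tilde=float(rt[i]),
                    q=int(q[i]), pre_shot=bool(pre[i]))
        for i in range(n)
    ]


def gen_pass_with_tracking(
    config: SimConfig,
    rng: np.random.Generator,
    params: MotionParams | None = None,
    *,
    time: float = 0.0,
) -> tuple[Snapshot, PassEvent]:
    """A snapshot and a pass whose ground truth is recomputable from it.

    The pass originates at a random outfield player of the possessing side;
    the end point is uniform on the pitch and the outcome is drawn from the
    logistic model evaluated at the true z1 of the end point.
    """
    params = params or MotionParams()
    snap = gen_snapshot(config, rng, time=time)
    offense = snap.possession
    passers = [p for p in snap.side(offense) if not p.is_goalkeeper]
    origin = passers[rng.integers(len(passers))]
    x_e = np.array(
        [
            rng.uniform(config.pitch.x_min + 1.0, config.pitch.x_max - 1.0),
            rng.uniform(config.pitch.y_min + 1.0, config.pitch.y_max - 1.0),
        ]
    )
    tau_of = team_min_arrival(snap, offense, x_e, params)
    tau_df = team_min_arrival(snap, other_side(offense), x_e, params)
    z1, _ = z_transform(tau_of, tau_df)
    q = int(rng.random() < expit(config.a * z1 + config.b))
    event = PassEvent(
        t_o=snap.time,
        x_o=origin.position.copy(),
        t_e=snap.time + float(rng.uniform(0.5, 2.0)),
        x_e=x_e,
        q=q,
        pre_shot=bool(rng.random() < 0.1),
        possession=offense,
    )
    return snap, event


def gen_match_data(
    config: SimConfig,
    rng: np.random.Generator,
    n_passes: int | None = None,
    params: MotionParams | None = None,
    *,
    frame_interval: float = 1.0,
) -> tuple[list[Snapshot], list[PassEvent]]:
    """A tracking sequence and pass list: one snapshot per pass, spaced in time."""
    n = config.n_passes if n_passes is None else n_passes
    snapshots: list[Snapshot] = []
    passes: list[PassEvent] = []
    for k in range(n):
        snap, event = gen_pass_with_tracking(config, rng, params, time=k * frame_interval)
        snap.frame = k
        snapshots.append(snap)
        passes.append(event)
    return snapshots, passes
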