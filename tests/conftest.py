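"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pitchspace import MotionParams, Pitch, PlayerState, SimConfig, Snapshot, gen_snapshot


@pytest.fixture
def params() -> MotionParams:
    return MotionParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def snapshot(rng) -> Snapshot:
    """A full, valid 22-player snapshot."""
    return gen_snapshot(SimConfig(seed=7), np.random.default_rng(7))


def player(x, y, vx=0.0, vy=0.0, team="home", pid="p", gk=False) -> PlayerState:
    return PlayerState(player_id=pid, team=team, position=(x, y), velocity=(vx, vy),
                       is_goalkeeper=gk)


def two_team_snapshot(home_xy, away_xy, time=0.0, possession="home") -> Snapshot:
    """Ad-hoc snapshot from raw position lists (no 22-player requirement)."""
    players = [player(x, y, team="home", pid=f"h{i}") for i, (x, y) in enumerate(home_xy)]
    players += [player(x, y, team="away", pid=f"a{i}") for i, (x, y) in enumerate(away_xy)]
    return Snapshot(time=time, players=players, possession=possession)


def dense_scan_arrival(x0, v0, params: MotionParams, target, dt=1e-4) -> float:
    """Brute-force first-crossing oracle: scan g(t) on a dense time grid.

    Independent of the package's solver: evaluates the drift-plus-radius
    geometry directly at every grid time and returns the first non-positive g.
    """
    x0 = np.asarray(x0, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    target = np.asarray(target, dtype=float)
    d0 = float(np.linalg.norm(target - x0))
    if d0 < 1e-6:
        return 0.0
    a, vm = params.alpha, params.v_max
    t_hi = (d0 + np.linalg.norm(v0) / a) / vm + 1.0 / a + 0.5
    t = np.arange(0.0, t_hi, dt)
    drift = (1.0 - np.exp(-a * t)) / a
    centers = x0 + drift[:, None] * v0
    g = np.linalg.norm(target - centers, axis=1) - vm * (t - drift)
    idx = int(np.argmax(g <= 0.0))
    assert g[idx] <= 0.0, "oracle scan found no crossing"
    return float(t[idx])
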