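"""Pitch geometry and run configuration.

Coordinates are pitch-centred: x along the long axis, y along the short axis,
both in metres. The default pitch is 105 x 68 m, so x in [-52.5, 52.5] and
y in [-34, 34].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ValidationError

#: padding (m) allowed beyond the touchlines for recorded positions
POSITION_PAD = 5.0
#: sanity bound on recorded player speed (m/s)
MAX_SPEED = 15.0
#: default tracking sample interval (s), 25 Hz
DEFAULT_DT = 0.04


@dataclass(frozen=True)
class Pitch:
    """Pitch dimensions in metres, origin at the centre spot."""

    length: float = 105.0
    width: float = 68.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValidationError("pitch dimensions must be positive")

    @property
    def x_min(self) -> float:
        return -self.length / 2.0

    @property
    def x_max(self) -> float:
        return self.length / 2.0

    @property
    def y_min(self) -> float:
        return -self.width / 2.0

    @property
    def y_max(self) -> float:
        return self.width / 2.0

    def contains(self, xy, pad: float = 0.0) -> bool:
        x, y = float(xy[0]), float(xy[1])
        return (
            self.x_min - pad <= x <= self.x_max + pad
            and self.y_min - pad <= y <= self.y_max + pad
        )


@dataclass
class RunConfig:
    """Resolved configuration for a CLI run.

    Defaults reproduce the framework's stated constants: terminal sprint
    speed 7.8 m/s, relaxation rate 1.3 1/s, safety threshold z1 = 0 and
    sparsity threshold z2 = 2.
    """

    v_max: float = 7.8
    alpha: float = 1.3
    pitch_length: float = 105.0
    pitch_width: float = 68.0
    grid_resolution: float = 0.5
    z1_threshold: float = 0.0
    z2_threshold: float = 2.0
    z1_bin_width: float = 0.1
    z2_bin_width: float = 0.25
    min_bin_count: int = 30
    seed: int = 0
    include_goalkeepers_in_tau: bool = True
    dt: float = DEFAULT_DT
    velocity_window: int = 5

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.alpha <= 0:
            raise ValidationError("v_max and alpha must be positive")
        if self.grid_resolution <= 0:
            raise ValidationError("grid_resolution must be positive")
        if self.z1_bin_width <= 0 or self.z2_bin_width <= 0:
            raise ValidationError("bin widths must be positive")

    @property
    def pitch(self) -> Pitch:
        return Pitch(self.pitch_length, self.pitch_width)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config file; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
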