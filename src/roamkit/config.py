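"""Run configuration shared by every pipeline stage.

All distances are metres in a single projected CRS; all speeds are metres per
minute; clock times are the owner's local clock (no UTC conversion, since the
day/night split is defined on household schedules).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


@dataclass(frozen=True)
class BlockZone:
    """Circular exclusion zone: fixes inside are dropped before any other filter.

    Replaces ad hoc manual removal of known-bad locations (e.g. a
    researcher's house) with a reproducible coordinate blocklist.
    """

    x: float
    y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"blocklist radius must be > 0, got {self.radius}")

    def contains(self, x: float, y: float) -> bool:
        return (x - self.x) ** 2 + (y - self.y) ** 2 <= self.radius**2


@dataclass(frozen=True)
class RunConfig:
    """All tunable constants of the analysis pipeline.

    Defaults are the study conditions: a 100 m/min speed ceiling (faster than
    a sustained trot for a cat), the 15 m/min + 165–180° spike rule, 95/50 %
    kernel isopleths, a 66 m road-sampling radius, a 300 m owner buffer,
    10:1 available:used RSF sampling, 85 % CIs for AICc-based retention and a
    20 % safety margin on the management buffer.
    """

    crs_epsg: int = 32617  # UTM zone 17N / WGS84
    speed_threshold: float = 100.0  # m/min, strict >
    spike_speed: float = 15.0  # m/min, inclusive >=
    spike_angle_range: tuple[float, float] = (165.0, 180.0)  # degrees
    stationary_tol: float = 1e-9  # metres; "within 0 m" after float parsing
    day_window: tuple[str, str] = ("06:00", "17:59")  # local clock, inclusive
    kde_isopleths: tuple[float, ...] = (95.0, 50.0)  # percent
    kde_grid: int = 200  # cells per axis
    road_radius: float = 66.0  # metres
    owner_buffer_radius: float = 300.0  # metres
    avail_ratio: int = 10  # available points per used point
    ci_level_glm: float = 0.85
    ci_level_rsf: float = 0.95
    delta_aicc_cut: float = 2.0
    buffer_margin: float = 0.20
    rng_seed: int = 0
    blocklist: tuple[BlockZone, ...] = ()

    def __post_init__(self) -> None:
        for name in ("speed_threshold", "spike_speed", "road_radius",
                     "owner_buffer_radius", "stationary_tol"):
            v = getattr(self, name)
            if name != "stationary_tol" and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.stationary_tol < 0:
            raise ValueError("stationary_tol must be >= 0")
        for name in ("ci_level_glm", "ci_level_rsf"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.avail_ratio < 1:
            raise ValueError(f"avail_ratio must be >= 1, got {self.avail_ratio}")
        lo, hi = self.spike_angle_range
        if not (0 <= lo <= hi <= 180):
            raise ValueError(
                f"spike_angle_range must be ordered within [0, 180], got {lo, hi}"
            )
        if self.buffer_margin < 0:
            raise ValueError("buffer_margin must be >= 0")
        if self.delta_aicc_cut <= 0:
            raise ValueError("delta_aicc_cut must be > 0")
        if self.kde_grid < 10:
            raise ValueError("kde_grid must be >= 10")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocklist"] = [asdict(z) for z in self.blocklist]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "blocklist" in d:
            d["blocklist"] = tuple(BlockZone(**z) for z in d["blocklist"])
        for key in ("spike_angle_range", "day_window", "kde_isopleths"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Stable short hash recorded in every output sidecar."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


#: Canonical six-way land-cover scheme.
CATEGORIES: tuple[str, ...] = (
    "impervious",
    "road",
    "greenspace",
    "agriculture",
    "undifferentiated",
    "water",
)

#: Categories excluded from habitat-selection designs (points dropped).
EXCLUDED_CATEGORIES: frozenset[str] = frozenset({"undifferentiated", "water"})
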