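"""Four-pass GPS trajectory cleaning.

Raw collar fixes contain satellite-interference artifacts: isolated points
implying impossible speeds, "spike" locations (an implausibly fast out-and-
back excursion, i.e. high speed on both legs with a near-180° turn), points
stranded between removed neighbours, and long stationary runs logged while
the animal was indoors. The pipeline removes them in a fixed order:

    blocklist → speed → spike → between-removed → stationary collapse

Speeds are metres per minute and are assigned to the *later* fix of each
consecutive pair ("arriving" speed). The speed ceiling is strict
(> threshold removes) while the spike speed is inclusive (>= threshold),
mirroring the wording of the thresholds they implement. The speed pass
removes the provably smallest set of fixes whose absence leaves every
bridged speed at or below the ceiling; the spike pass is a left-to-right
scan that recomputes metrics after each removal.

Coordinates are never altered, only removed; survivor order is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig

logger = logging.getLogger(__name__)

PASS_NAMES = ("blocklist", "speed", "spike", "between", "stationary")


# ---------------------------------------------------------------------------
# Step metrics
# ---------------------------------------------------------------------------

@dataclass
class StepMetrics:
    """Per-step distances/speeds and per-interior-fix turning angles.

    ``distance[i]``, ``dt[i]`` and ``speed[i]`` describe the step from fix
    ``i`` to fix ``i+1`` (the speed "arrives" at fix ``i+1``).
    ``turn_angle[i]`` is the angle in degrees between the incoming and
    outgoing displacement vectors at interior fix ``i+1``: 0° means straight
    ahead, 180° a full reversal.
    """

    distance: np.ndarray
    dt: np.ndarray
    speed: np.ndarray
    turn_angle: np.ndarray


def _t_minutes(t: pd.Series | np.ndarray) -> np.ndarray:
    t = pd.to_datetime(pd.Series(t))
    return (t - t.iloc[0]).dt.total_seconds().to_numpy() / 60.0


def compute_step_metrics(traj: pd.DataFrame) -> StepMetrics:
    """Euclidean step metrics for a single-animal trajectory (sorted by t)."""
    if len(traj) < 2:
        raise ValueError("need at least 2 fixes to compute step metrics")
    x = traj["x"].to_numpy(float)
    y = traj["y"].to_numpy(float)
    tm = _t_minutes(traj["t"])
    return _step_metrics_arrays(x, y, tm)


def _step_metrics_arrays(x: np.ndarray, y: np.ndarray,
                         tm: np.ndarray) -> StepMetrics:
    dx, dy = np.diff(x), np.diff(y)
    dist = np.hypot(dx, dy)
    dt = np.diff(tm)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ValueError(
            f"non-increasing timestamps between fixes {i} and {i + 1}"
        )
    speed = dist / dt
    # angle between consecutive displacement vectors
    if len(dx) >= 2:
        v1x, v1y = dx[:-1], dy[:-1]
        v2x, v2y = dx[1:], dy[1:]
        dot = v1x * v2x + v1y * v2y
        n1 = np.hypot(v1x, v1y)
        n2 = np.hypot(v2x, v2y)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.clip(dot / (n1 * n2), -1.0, 1.0)
        turn = np.degrees(np.arccos(cosang))
        turn[(n1 == 0) | (n2 == 0)] = np.nan  # undefined for zero-length legs
    else:
        turn = np.empty(0)
    return StepMetrics(dist, dt, speed, turn)


# ---------------------------------------------------------------------------
# Individual passes (operate on position arrays, return kept positions)
# ---------------------------------------------------------------------------

def _speed_pass(x: np.ndarray, y: np.ndarray, tm: np.ndarray,
                threshold: float) -> np.ndarray:
    """Exact minimal-removal speed filter; boolean keep-mask over positions.

    Keeps the largest subsequence of fixes whose every consecutive speed,
    recomputed across removal gaps, is at or below the threshold (the
    boundary value is retained; only speeds strictly over are impossible).
    Solved as a longest-valid-subsequence dynamic program, so the survivor
    set provably minimises the number of removals; among equally small
    removal sets the lexicographically earliest survivor sequence is chosen
    (which keeps the earliest fixes and removes the fastest-arriving one in
    the simple single-outlier case). A greedy remove-the-fastest loop is
    *not* equivalent: when two consecutive fixes are displaced together it
    blames and removes the following clean fix as well.
    """
    n = len(x)
    if n < 2:
        return np.ones(n, dtype=bool)
    # R[i]: length of the longest valid subsequence starting at i;
    # a step i -> j is valid when dist <= threshold * dt (arriving speed)
    r = np.ones(n, dtype=np.int64)
    for i in range(n - 2, -1, -1):
        dist = np.hypot(x[i + 1:] - x[i], y[i + 1:] - y[i])
        ok = dist <= threshold * (tm[i + 1:] - tm[i])
        if ok.any():
            r[i] = 1 + r[i + 1:][ok].max()
    k = int(r.max())
    # lexicographically earliest reconstruction of a maximal chain
    keep = []
    i = int(np.argmax(r == k))  # first index achieving the maximum
    keep.append(i)
    remaining = k - 1
    while remaining > 0:
        js = np.arange(i + 1, n)
        dist = np.hypot(x[js] - x[i], y[js] - y[i])
        ok = (dist <= threshold * (tm[js] - tm[i])) & (r[js] == remaining)
        i = int(js[np.argmax(ok)])
        keep.append(i)
        remaining -= 1
    mask = np.zeros(n, dtype=bool)
    mask[keep] = True
    return mask


def _is_spike(x, y, tm, a: int, b: int, c: int, spike_speed: float,
              lo: float, hi: float) -> bool:
    d1 = float(np.hypot(x[b] - x[a], y[b] - y[a]))
    d2 = float(np.hypot(x[c] - x[b], y[c] - y[b]))
    dt1, dt2 = tm[b] - tm[a], tm[c] - tm[b]
    if d1 == 0 or d2 == 0:
        return False
    s1, s2 = d1 / dt1, d2 / dt2
    if s1 < spike_speed or s2 < spike_speed:
        return False
    dot = (x[b] - x[a]) * (x[c] - x[b]) + (y[b] - y[a]) * (y[c] - y[b])
    ang = float(np.degrees(np.arccos(np.clip(dot / (d1 * d2), -1.0, 1.0))))
    return lo <= ang <= hi


def _spike_pass(x, y, tm, spike_speed: float,
                angle_range: tuple[float, float]) -> np.ndarray:
    """Left-to-right spike removal with metric recomputation.

    An interior fix is a spike when both its legs are at or above the spike
    speed and the turn angle falls in the configured near-reversal band; the
    apex fix alone is removed. After a removal the scan steps back one fix,
    because the predecessor's outgoing leg has changed.
    """
    lo, hi = angle_range
    keep = list(range(len(x)))
    i = 1
    while i < len(keep) - 1:
        if _is_spike(x, y, tm, keep[i - 1], keep[i], keep[i + 1],
                     spike_speed, lo, hi):
            del keep[i]
            i = max(1, i - 1)
        else:
            i += 1
    mask = np.zeros(len(x), dtype=bool)
    mask[keep] = True
    return mask


def _between_pass(removed_so_far: np.ndarray) -> np.ndarray:
    """Remove survivors whose original-sequence neighbours were both removed.

    ``removed_so_far`` is a boolean mask over the *original* fix positions;
    returns a mask of additional removals.
    """
    n = len(removed_so_far)
    extra = np.zeros(n, dtype=bool)
    if n < 3:
        return extra
    interior = ~removed_so_far[1:-1] & removed_so_far[:-2] & removed_so_far[2:]
    extra[1:-1] = interior
    return extra


def _stationary_pass(x, y, tol: float) -> np.ndarray:
    """Collapse runs of successively coincident fixes to their first member."""
    n = len(x)
    mask = np.ones(n, dtype=bool)
    if n < 2:
        return mask
    dist = np.hypot(np.diff(x), np.diff(y))
    mask[1:] = dist > tol
    return mask


# ---------------------------------------------------------------------------
# Public single-pass wrappers (single-animal trajectory frames)
# ---------------------------------------------------------------------------

def _split(traj: pd.DataFrame, mask: np.ndarray):
    return (traj.iloc[mask].reset_index(drop=True),
            traj.iloc[~mask].reset_index(drop=True))


def filter_speed(traj: pd.DataFrame, threshold: float):
    """Remove fixes whose arriving speed is strictly over ``threshold`` m/min."""
    if len(traj) < 2:
        return traj.reset_index(drop=True), traj.iloc[0:0]
    mask = _speed_pass(traj["x"].to_numpy(float), traj["y"].to_numpy(float),
                       _t_minutes(traj["t"]), threshold)
    return _split(traj, mask)


def filter_spikes(traj: pd.DataFrame, spike_speed: float,
                  angle_range: tuple[float, float]):
    """Remove single out-and-back spike fixes (fast legs, near-180° turn)."""
    if len(traj) < 3:
        return traj.reset_index(drop=True), traj.iloc[0:0]
    mask = _spike_pass(traj["x"].to_numpy(float), traj["y"].to_numpy(float),
                       _t_minutes(traj["t"]), spike_speed, angle_range)
    return _split(traj, mask)


def filter_between_removed(traj_all: pd.DataFrame, removed_mask: np.ndarray):
    """Remove survivors sandwiched between two already-removed originals.

    ``traj_all`` is the original (pre-filtering) single-animal frame and
    ``removed_mask`` flags which of its rows earlier passes removed.
    """
    extra = _between_pass(np.asarray(removed_mask, dtype=bool))
    keep = ~np.asarray(removed_mask, dtype=bool) & ~extra
    return (traj_all.iloc[keep].reset_index(drop=True),
            traj_all.iloc[extra].reset_index(drop=True))


def collapse_stationary(traj: pd.DataFrame, tol: float = 1e-9):
    """Keep only the first fix of each stationary run (successive moves <= tol)."""
    if len(traj) < 2:
        return traj.reset_index(drop=True), traj.iloc[0:0]
    mask = _stationary_pass(traj["x"].to_numpy(float),
                            traj["y"].to_numpy(float), tol)
    return _split(traj, mask)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Bookkeeping for one animal's pass through the cleaning pipeline."""

    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)
    labels: np.ndarray | None = None  # reason per original fix, "" = kept
    usable: bool = True

    def __post_init__(self) -> None:
        if self.n_input - self.n_retained != sum(self.removed.values()):
            raise ValueError("filter report counts are inconsistent")


def run_filter_pipeline(traj: pd.DataFrame, config: RunConfig
                        ) -> tuple[pd.DataFrame, FilterReport]:
    """Clean one animal's sorted fixes; returns survivors and a report.

    Pass order: blocklist, speed (> speed_threshold), spike
    (>= spike_speed within spike_angle_range), between-removed, stationary
    collapse. Fewer than 2 surviving fixes flags the animal unusable.
    """
    n = len(traj)
    x = traj["x"].to_numpy(float)
    y = traj["y"].to_numpy(float)
    tm = _t_minutes(traj["t"]) if n >= 2 else np.zeros(n)
    labels = np.full(n, "", dtype=object)

    # pass 1: blocklist
    for zone in config.blocklist:
        inside = (x - zone.x) ** 2 + (y - zone.y) ** 2 <= zone.radius**2
        labels[inside & (labels == "")] = "blocklist"

    def alive() -> np.ndarray:
        return np.flatnonzero(labels == "")

    # pass 2: speed
    idx = alive()
    if len(idx) >= 2:
        keep = _speed_pass(x[idx], y[idx], tm[idx], config.speed_threshold)
        labels[idx[~keep]] = "speed"

    # pass 3: spikes
    idx = alive()
    if len(idx) >= 3:
        keep = _spike_pass(x[idx], y[idx], tm[idx], config.spike_speed,
                           config.spike_angle_range)
        labels[idx[~keep]] = "spike"

    # pass 4: in-between removed (original-sequence neighbours)
    extra = _between_pass(labels != "")
    labels[extra] = "between"

    # pass 5: stationary collapse
    idx = alive()
    if len(idx) >= 2:
        keep = _stationary_pass(x[idx], y[idx], config.stationary_tol)
        labels[idx[~keep]] = "stationary"

    kept_mask = labels == ""
    removed = {name: int(np.sum(labels == name)) for name in PASS_NAMES}
    report = FilterReport(
        n_input=n,
        n_retained=int(kept_mask.sum()),
        removed=removed,
        labels=labels,
        usable=int(kept_mask.sum()) >= 2,
    )
    if not report.usable:
        animal = traj["animal_id"].iloc[0] if n else "?"
        logger.warning("animal %s: fewer than 2 fixes survive filtering",
                       animal)
    return traj.iloc[kept_mask].reset_index(drop=True), report


def filter_all(fixes: pd.DataFrame, config: RunConfig
               ) -> tuple[pd.DataFrame, dict[str, FilterReport]]:
    """Run the cleaning pipeline per animal over a multi-animal fix table."""
    cleaned, reports = [], {}
    for animal, traj in fixes.groupby("animal_id", sort=True):
        out, rep = run_filter_pipeline(traj.reset_index(drop=True), config)
        cleaned.append(out)
        reports[animal] = rep
    if not cleaned:
        return fixes.iloc[0:0], reports
    return pd.concat(cleaned, ignore_index=True), reports
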