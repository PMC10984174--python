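"""Synthetic landscapes, road networks and owned-cat trajectories.

Every downstream stage is exercised against data with known ground truth:

* a clustered categorical landscape grown from random seeds to exact
  per-category cell quotas (urban land cover is patchy, not i.i.d. noise);
* a home-tethered, habitat-biased random walk: at each fix time the walker
  proposes K candidate displacements (turning-angle-correlated headings,
  exponential step lengths, a deterministic pull toward the owner's home)
  and picks among them with probability proportional to the selection
  weight of the land cover at each candidate — a step-selection kernel, the
  simplest generative model under which a point-level logistic resource
  selection function is well specified;
* a degradation stage adding isotropic Gaussian GPS error and injecting
  labelled artifacts of the three classes the cleaning pipeline targets
  (implausible-speed outliers, out-and-back spikes, stationary runs).

Default selection weights mirror the qualitative pattern observed in urban
pet cats — strong preference for impervious residential cover, avoidance
of roads, greenspace and agriculture. True inter-fix speeds never exceed
the 100 m/min cleaning ceiling by construction, so any fix the speed
filter removes from synthetic data is a known artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .config import CATEGORIES
from .io import Landscape, RoadNetwork
from . import filtering

DEFAULT_PROPORTIONS: dict[str, float] = {
    "impervious": 0.66,
    "road": 0.26,
    "greenspace": 0.06,
    "agriculture": 0.02,
}

#: Step-selection weights; ratios chosen to mirror observed urban-cat
#: selection strength (strong for impervious, weakest for agriculture).
DEFAULT_WEIGHTS: dict[str, float] = {
    "impervious": 1.45,
    "road": 0.80,
    "greenspace": 0.60,
    "agriculture": 0.25,
}


@dataclass
class SimScenario:
    """Study conditions for one simulated tracking campaign."""

    n_animals: int = 6
    extent: float = 2000.0  # square landscape side, metres
    cell: float = 10.0  # raster cell, metres
    landscape_spec: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    selection_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))
    tether_strength: float = 0.15  # per-step pull toward home, (0, 1]
    step_scale: float = 25.0  # mean exponential step length, metres
    turn_kappa: float = 1.0  # von Mises heading concentration
    n_candidates: int = 20  # K proposals per step
    fix_interval_range: tuple[float, float] = (2.0, 60.0)  # minutes
    gps_sigma: float = 4.8  # metres (open-sky collar accuracy)
    outlier_rate: float = 0.02
    spike_rate: float = 0.02
    stationary_run_rate: float = 0.02
    duration_days: float = 20.0
    night_step_multiplier: float = 1.0  # optional nocturnal activity change
    rng_seed: int = 0
    speed_cap: float = 100.0  # m/min; true speeds stay strictly below

    def __post_init__(self) -> None:
        total = sum(self.landscape_spec.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"landscape proportions must sum to 1, got {total}")
        if any(w < 0 for w in self.selection_weights.values()):
            raise ValueError("selection weights must be >= 0")
        if not 0 < self.tether_strength <= 1:
            raise ValueError("tether_strength must be in (0, 1]")
        for name in ("outlier_rate", "spike_rate", "stationary_run_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        lo, hi = self.fix_interval_range
        if not 0 < lo <= hi:
            raise ValueError("fix_interval_range must be ordered positive")


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

def generate_landscape(spec: dict[str, float], extent: float, cell: float,
                       seed: int, n_seeds: int | None = None,
                       x0: float = 0.0, y0: float = 0.0) -> Landscape:
    """Clustered categorical raster grown to exact per-category quotas.

    Random seed cells (count per category proportional to its target share)
    grow breadth-first with randomised frontiers until each category has
    claimed its quota of cells, yielding contiguous patches whose realised
    proportions match the spec to within rounding. By default one seed is
    planted per ~500 cells, so the mean patch is ~5 ha at a 10 m cell —
    the scale of an urban block — independent of the overall extent.
    """
    total = sum(spec.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"landscape proportions must sum to 1, got {total}")
    n = int(round(extent / cell))
    if n < 50:
        raise ValueError("extent/cell must yield at least 50x50 cells")
    if n_seeds is None:
        n_seeds = max(10, (n * n) // 500)
    rng = np.random.default_rng(seed)
    cats = [c for c in spec if spec[c] > 0]
    cat_idx = {c: CATEGORIES.index(c) for c in cats}

    ncells = n * n
    quotas = {c: int(round(spec[c] * ncells)) for c in cats}
    # fix rounding drift on the largest category
    drift = ncells - sum(quotas.values())
    quotas[max(cats, key=lambda c: spec[c])] += drift

    grid = np.full((n, n), -1, dtype=np.int32)
    remaining = dict(quotas)
    frontiers: dict[str, list[tuple[int, int]]] = {c: [] for c in cats}

    # seed cells
    for c in cats:
        k = max(1, int(round(n_seeds * spec[c])))
        for _ in range(min(k, remaining[c])):
            frontiers[c].append((int(rng.integers(n)), int(rng.integers(n))))

    unassigned = ncells
    active = [c for c in cats if remaining[c] > 0]
    while unassigned > 0:
        weights = np.array([remaining[c] for c in active], dtype=float)
        c = active[int(rng.choice(len(active), p=weights / weights.sum()))]
        cell_rc = None
        front = frontiers[c]
        while front:
            j = int(rng.integers(len(front)))
            front[j], front[-1] = front[-1], front[j]
            r, q = front.pop()
            if grid[r, q] == -1:
                cell_rc = (r, q)
                break
        if cell_rc is None:  # re-seed on any free cell
            free = np.flatnonzero(grid.ravel() == -1)
            pick = int(free[rng.integers(len(free))])
            cell_rc = (pick // n, pick % n)
        r, q = cell_rc
        grid[r, q] = cat_idx[c]
        remaining[c] -= 1
        unassigned -= 1
        if remaining[c] == 0:
            active.remove(c)
            if not active:
                break
        for rr, qq in ((r - 1, q), (r + 1, q), (r, q - 1), (r, q + 1)):
            if 0 <= rr < n and 0 <= qq < n and grid[rr, qq] == -1:
                frontiers[c].append((rr, qq))

    assert (grid >= 0).all()
    return Landscape(grid, x0, y0, cell)


def generate_roads(extent: float, seed: int, spacing: float = 200.0,
                   major_every: int = 5, x0: float = 0.0,
                   y0: float = 0.0) -> RoadNetwork:
    """Rectilinear street grid with jittered spacing; every ``major_every``-th
    street is a major road."""
    rng = np.random.default_rng(seed)
    geoms, classes = [], []
    count = 0
    for axis in ("v", "h"):
        pos = x0 if axis == "v" else y0
        while True:
            pos += spacing * float(rng.uniform(0.7, 1.3))
            if pos >= (x0 if axis == "v" else y0) + extent:
                break
            if axis == "v":
                geoms.append(LineString([(pos, y0), (pos, y0 + extent)]))
            else:
                geoms.append(LineString([(x0, pos), (x0 + extent, pos)]))
            count += 1
            classes.append("major" if count % major_every == 0 else "minor")
    return RoadNetwork(geoms, classes)


# ---------------------------------------------------------------------------
# Movement simulation
# ---------------------------------------------------------------------------

def simulate_trajectory(scenario: SimScenario, landscape: Landscape,
                        home_xy: tuple[float, float], animal_id: str,
                        rng: np.random.Generator,
                        t0: pd.Timestamp | None = None) -> pd.DataFrame:
    """True (error-free) fix sequence for one animal.

    Discrete-time step-selection walk at irregular fix times; candidate
    displacements are chosen with probability proportional to the selection
    weight of the land cover they land in. Walks exiting the landscape are
    reflected at the boundary. True inter-fix speed stays strictly below
    ``scenario.speed_cap`` by construction.
    """
    xmin, ymin, xmax, ymax = landscape.extent
    hx, hy = home_xy
    if not (xmin <= hx < xmax and ymin <= hy < ymax):
        raise ValueError("home must lie inside the landscape extent")
    if t0 is None:
        t0 = pd.Timestamp("2021-06-01 00:00:00")

    weights = np.array([scenario.selection_weights.get(c, 1.0)
                        for c in landscape.categories])
    lo, hi = scenario.fix_interval_range
    total_min = scenario.duration_days * 24 * 60.0
    k = scenario.n_candidates

    times = []
    tcur = 0.0
    while True:
        tcur += float(rng.uniform(lo, hi))
        if tcur > total_min:
            break
        times.append(tcur)
    if not times:
        raise ValueError("duration too short for a single fix interval")

    xs, ys = [hx], [hy]
    heading = float(rng.uniform(0, 2 * math.pi))
    px, py = hx, hy
    prev_t = 0.0
    for tm in times:
        dt = tm - prev_t
        clock_h = ((t0 + pd.Timedelta(minutes=tm)).hour)
        scale = scenario.step_scale
        if not (6 <= clock_h < 18):
            scale *= scenario.night_step_multiplier
        max_disp = 0.95 * scenario.speed_cap * dt

        ang = heading + rng.vonmises(0.0, scenario.turn_kappa, size=k)
        length = rng.exponential(scale, size=k)
        dx = length * np.cos(ang) + scenario.tether_strength * (hx - px)
        dy = length * np.sin(ang) + scenario.tether_strength * (hy - py)
        norm = np.hypot(dx, dy)
        over = norm > max_disp
        if over.any():
            shrink = max_disp / norm[over]
            dx[over] *= shrink
            dy[over] *= shrink
        cx = px + dx
        cy = py + dy
        # reflect at the boundary
        cx = np.where(cx < xmin, 2 * xmin - cx, cx)
        cx = np.where(cx >= xmax, 2 * xmax - cx - 1e-9, cx)
        cy = np.where(cy < ymin, 2 * ymin - cy, cy)
        cy = np.where(cy >= ymax, 2 * ymax - cy - 1e-9, cy)
        cx = np.clip(cx, xmin, np.nextafter(xmax, -np.inf))
        cy = np.clip(cy, ymin, np.nextafter(ymax, -np.inf))

        w = weights[landscape.category_index_at(cx, cy)]
        if w.sum() <= 0:
            nx, ny = px, py  # nowhere acceptable: stay put
        else:
            j = int(rng.choice(k, p=w / w.sum()))
            nx, ny = float(cx[j]), float(cy[j])
        if (nx, ny) != (px, py):
            heading = math.atan2(ny - py, nx - px)
        px, py = nx, ny
        xs.append(px)
        ys.append(py)
        prev_t = tm

    t_index = [t0] + [t0 + pd.Timedelta(seconds=round(m * 60)) for m in times]
    return pd.DataFrame({
        "animal_id": animal_id,
        "t": pd.to_datetime(t_index),
        "x": xs,
        "y": ys,
    })


# ---------------------------------------------------------------------------
# Observation degradation
# ---------------------------------------------------------------------------

def degrade(true_fixes: pd.DataFrame, scenario: SimScenario,
            rng: np.random.Generator) -> pd.DataFrame:
    """GPS error plus labelled artifacts.

    Adds isotropic Gaussian positional error (sd ``gps_sigma``), then
    injects, at the configured per-fix rates:

    * ``outlier`` — a fix displaced far enough that its arriving speed
      exceeds the 100 m/min cleaning ceiling;
    * ``spike`` — an extra fix inserted between two neighbours, placed so
      both legs are at or above the 15 m/min spike speed with a turn angle
      in the near-reversal band (verified against the cleaning pipeline's
      own spike predicate);
    * ``stationary`` — runs of >= 2 consecutive fixes pinned to an
      identical coordinate (only the duplicates are labelled).

    Returns the observed frame with an ``artifact`` column ("" = clean).
    """
    df = true_fixes.reset_index(drop=True).copy()
    n = len(df)
    x = df["x"].to_numpy(float).copy()
    y = df["y"].to_numpy(float).copy()
    tm = filtering._t_minutes(df["t"])
    if scenario.gps_sigma > 0:
        x += rng.normal(0, scenario.gps_sigma, n)
        y += rng.normal(0, scenario.gps_sigma, n)
    label = np.full(n, "", dtype=object)

    # stationary runs first (coordinates copied after noise)
    i = 1
    while i < n - 1:
        if label[i] == "" and rng.random() < scenario.stationary_run_rate:
            run = int(rng.integers(2, 5))
            j_end = min(n, i + run)
            for j in range(i + 1, j_end):
                x[j], y[j] = x[i], y[i]
                label[j] = "stationary"
            i = j_end
        i += 1

    # speed outliers
    for i in range(1, n):
        if label[i] != "" or label[i - 1] != "":
            continue
        if rng.random() < scenario.outlier_rate:
            dt_in = tm[i] - tm[i - 1]
            dt_out = tm[i + 1] - tm[i] if i + 1 < n else dt_in
            mag = 2.0 * scenario.speed_cap * max(dt_in, dt_out) \
                + float(np.hypot(x[i] - x[i - 1], y[i] - y[i - 1]))
            theta = rng.uniform(0, 2 * math.pi)
            x[i] += mag * math.cos(theta)
            y[i] += mag * math.sin(theta)
            label[i] = "outlier"

    rows = []
    lo_ang, hi_ang = 165.0, 180.0
    for i in range(n):
        rows.append((df["t"].iloc[i], x[i], y[i], label[i]))
        if i + 1 < n and label[i] == "" and label[i + 1] == "":
            if rng.random() < scenario.spike_rate:
                spike = _make_spike(x[i], y[i], tm[i], x[i + 1], y[i + 1],
                                    tm[i + 1], rng, lo_ang, hi_ang)
                if spike is not None:
                    sx, sy, s_tm = spike
                    t_spike = df["t"].iloc[0] + pd.Timedelta(
                        seconds=round(s_tm * 60))
                    rows.append((t_spike, sx, sy, "spike"))

    out = pd.DataFrame(rows, columns=["t", "x", "y", "artifact"])
    out.insert(0, "animal_id", df["animal_id"].iloc[0])
    return out


def _make_spike(ax, ay, at, cx, cy, ct, rng, lo_ang, hi_ang,
                spike_speed: float = 15.0, speed_cap: float = 100.0):
    """Place a spike apex between fixes A and C: both legs at or above the
    spike speed but below the cleaning ceiling, turn angle within
    [lo_ang, hi_ang]. The apex sits perpendicular to the A–C chord, where a
    large offset drives the turn angle toward 180°. Infeasible gaps (A and
    C too far apart for a slow near-reversal) are skipped; the result is
    verified with the cleaning pipeline's own spike predicate."""
    s_tm = 0.5 * (at + ct)
    half = s_tm - at  # equal half-intervals by construction
    if half <= 0:
        return None
    chord = math.hypot(cx - ax, cy - ay)
    # offset bounds: angle >= lo_ang needs b >= chord / (2 tan((180-lo)/2));
    # leg speed in [spike_speed, 0.95*cap) bounds the leg length.
    half_gap = math.radians(180.0 - lo_ang) / 2.0
    b_min_angle = chord / (2.0 * math.tan(half_gap)) if half_gap > 0 else 0.0
    leg_min = spike_speed * half
    leg_max = 0.95 * speed_cap * half
    b_min = max(b_min_angle,
                math.sqrt(max(leg_min**2 - (chord / 2.0) ** 2, 0.0)))
    if (chord / 2.0) ** 2 + b_min**2 >= leg_max**2:
        return None  # infeasible gap
    b_max = math.sqrt(leg_max**2 - (chord / 2.0) ** 2)
    b = float(rng.uniform(b_min, min(b_max, 2.0 * b_min + 100.0)))

    mx, my = 0.5 * (ax + cx), 0.5 * (ay + cy)
    if chord > 1e-9:
        ux, uy = -(cy - ay) / chord, (cx - ax) / chord
    else:
        theta = rng.uniform(0, 2 * math.pi)
        ux, uy = math.cos(theta), math.sin(theta)
    if rng.random() < 0.5:
        ux, uy = -ux, -uy
    sx, sy = mx + b * ux, my + b * uy
    xs = np.array([ax, sx, cx])
    ys = np.array([ay, sy, cy])
    tms = np.array([at, s_tm, ct])
    if filtering._is_spike(xs, ys, tms, 0, 1, 2, spike_speed, lo_ang, hi_ang):
        return sx, sy, s_tm
    return None


# ---------------------------------------------------------------------------
# Scenario driver
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    landscape: Landscape
    roads: RoadNetwork
    homes: dict[str, tuple[float, float]]
    true_fixes: pd.DataFrame
    observed: pd.DataFrame  # includes the artifact label column


def run_scenario(scenario: SimScenario,
                 landscape: Landscape | None = None) -> SimResult:
    """Generate a full synthetic campaign: landscape, roads, trajectories
    and degraded observations, all driven by ``scenario.rng_seed``."""
    rng = np.random.default_rng(scenario.rng_seed)
    if landscape is None:
        landscape = generate_landscape(scenario.landscape_spec,
                                       scenario.extent, scenario.cell,
                                       seed=int(rng.integers(2**31)))
    roads = generate_roads(scenario.extent, seed=int(rng.integers(2**31)))
    xmin, ymin, xmax, ymax = landscape.extent
    pad = 0.2 * (xmax - xmin)

    homes, true_list, obs_list = {}, [], []
    for a in range(scenario.n_animals):
        animal = f"cat_{a:02d}"
        home = (float(rng.uniform(xmin + pad, xmax - pad)),
                float(rng.uniform(ymin + pad, ymax - pad)))
        homes[animal] = home
        true = simulate_trajectory(scenario, landscape, home, animal, rng)
        obs = degrade(true, scenario, rng)
        true_list.append(true)
        obs_list.append(obs)
    return SimResult(landscape, roads, homes,
                     pd.concat(true_list, ignore_index=True),
                     pd.concat(obs_list, ignore_index=True))
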