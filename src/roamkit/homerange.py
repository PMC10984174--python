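"""Home-range estimation and the derived management-buffer geometry.

Two classic estimators: the 100 % minimum convex polygon (MCP; convex hull
of all retained fixes) and Gaussian-kernel utilisation-distribution
isopleths (95 % "home range", 50 % "core"). Both report areas in hectares.
The kernel isopleth is computed by ranking grid cells by density and
accumulating mass — the standard volume-contour construction — with the
reference bandwidth href = σ̂·n^(−1/6), σ̂² the mean of the two coordinate
variances, unless a bandwidth is given explicitly.

Also here: the day/night clock split, the sample-size asymptote diagnostic
(has the MCP stopped growing as fixes accumulate?), the equivalent-circle
buffer-distance rule used to size cat-exclusion zones around conservation
areas, and the two small-sample tests used on per-animal areas (Wilcoxon
signed-rank, Brown–Forsythe).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "HomeRangeEstimate", "AsymptoteCurve", "mcp", "kde_isopleth",
    "href_bandwidth", "split_day_night", "asymptote_curve",
    "equivalent_circle_diameter", "buffer_distance",
    "paired_day_night_test", "variance_equality_test", "homerange_table",
]


@dataclass
class HomeRangeEstimate:
    animal_id: str
    method: str  # "MCP" | "KDE"
    level: float  # percent
    polygon: object  # shapely geometry (may be None for KDE)
    area_ha: float
    n_fixes: int
    bandwidth: float | None = None  # metres, KDE only
    period: str = "all"  # "all" | "day" | "night"


# ---------------------------------------------------------------------------
# Minimum convex polygon
# ---------------------------------------------------------------------------

def mcp(traj: pd.DataFrame, level: float = 100.0,
        period: str = "all") -> HomeRangeEstimate:
    """Minimum convex polygon home range.

    For ``level`` < 100 the fixes farthest from the centroid are dropped
    first (keeping the closest ``level`` % of points), then the hull of the
    remainder is taken.
    """
    pts = traj[["x", "y"]].to_numpy(float)
    if len(pts) < 3:
        raise ValueError("degenerate hull: need at least 3 fixes")
    if not 0 < level <= 100:
        raise ValueError(f"level must be in (0, 100], got {level}")
    if level < 100:
        centroid = pts.mean(axis=0)
        d = np.hypot(*(pts - centroid).T)
        n_keep = int(math.ceil(len(pts) * level / 100.0))
        pts = pts[np.argsort(d, kind="stable")[:n_keep]]
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("degenerate hull: fixes are collinear")
    animal = str(traj["animal_id"].iloc[0]) if "animal_id" in traj else ""
    return HomeRangeEstimate(animal, "MCP", level, hull, hull.area / 1e4,
                             len(pts), period=period)


# ---------------------------------------------------------------------------
# Kernel density isopleths
# ---------------------------------------------------------------------------

def href_bandwidth(pts: np.ndarray) -> float:
    """Reference bandwidth σ̂·n^(−1/6), σ̂² = (var(x)+var(y))/2."""
    n = len(pts)
    sigma = math.sqrt((pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1)) / 2.0)
    return sigma * n ** (-1.0 / 6.0)


def _kde_grid_density(pts: np.ndarray, h: float, n_grid: int):
    """Gaussian KDE evaluated on a regular grid padded by 3 bandwidths."""
    xmin, ymin = pts.min(axis=0) - 3 * h
    xmax, ymax = pts.max(axis=0) + 3 * h
    # square cells: expand the shorter axis
    side = max(xmax - xmin, ymax - ymin)
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    xmin, xmax = cx - side / 2, cx + side / 2
    ymin, ymax = cy - side / 2, cy + side / 2
    cell = side / n_grid
    gx = xmin + (np.arange(n_grid) + 0.5) * cell
    gy = ymin + (np.arange(n_grid) + 0.5) * cell

    dens = np.zeros((n_grid, n_grid))
    norm = 1.0 / (len(pts) * 2.0 * math.pi * h * h)
    # chunk over points to bound memory at n_grid² × chunk
    chunk = max(1, int(2e7 / (n_grid * n_grid)))
    for s in range(0, len(pts), chunk):
        px = pts[s:s + chunk, 0]
        py = pts[s:s + chunk, 1]
        ex = np.exp(-0.5 * ((gx[:, None] - px[None, :]) / h) ** 2)
        ey = np.exp(-0.5 * ((gy[:, None] - py[None, :]) / h) ** 2)
        dens += ey @ ex.T  # (ny, nx)
    dens *= norm
    return dens, gx, gy, cell


def kde_isopleth(traj: pd.DataFrame, level: float,
                 bandwidth: float | None = None, n_grid: int = 200,
                 period: str = "all") -> HomeRangeEstimate:
    """Utilisation-distribution isopleth: the smallest-area set of grid
    cells holding ``level`` % of the estimated density mass."""
    pts = traj[["x", "y"]].to_numpy(float)
    if len(pts) < 5:
        raise ValueError("need at least 5 fixes for a kernel home range")
    if not 0 < level < 100:
        raise ValueError(f"level must be in (0, 100), got {level}")
    h = href_bandwidth(pts) if bandwidth is None else float(bandwidth)
    if not h > 0:
        raise ValueError("zero variance in both axes: bandwidth is 0")

    dens, gx, gy, cell = _kde_grid_density(pts, h, n_grid)
    flat = np.sort(dens.ravel())[::-1]
    mass = flat / flat.sum()
    csum = np.cumsum(mass)
    k = int(np.searchsorted(csum, level / 100.0)) + 1
    k = min(k, len(flat))
    area_m2 = k * cell * cell
    thresh = flat[k - 1]

    polygon = _contour_polygon(dens, gx, gy, cell, thresh)
    animal = str(traj["animal_id"].iloc[0]) if "animal_id" in traj else ""
    return HomeRangeEstimate(animal, "KDE", level, polygon, area_m2 / 1e4,
                             len(pts), bandwidth=h, period=period)


def _contour_polygon(dens, gx, gy, cell, thresh):
    """Isopleth outline for mapping (area bookkeeping stays cell-based)."""
    try:
        from skimage import measure
    except ImportError:  # pragma: no cover
        return None
    polys = []
    for contour in measure.find_contours(dens, thresh):
        if len(contour) < 4:
            continue
        xs = gx[0] + contour[:, 1] * cell
        ys = gy[0] + contour[:, 0] * cell
        p = Polygon(np.column_stack([xs, ys]))
        if p.is_valid and p.area > 0:
            polys.append(p)
    if not polys:
        return None
    from shapely.ops import unary_union
    return unary_union(polys)


# ---------------------------------------------------------------------------
# Day / night split
# ---------------------------------------------------------------------------

def _clock_minutes(spec: str) -> int:
    h, m = spec.split(":")
    return int(h) * 60 + int(m)


def split_day_night(traj: pd.DataFrame,
                    day_window: tuple[str, str] = ("06:00", "17:59")
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition fixes by local clock time.

    The day window is inclusive of its boundary minutes: the default
    06:00–17:59 puts 17:59:59 in the day and 18:00:00 in the night.
    """
    start = _clock_minutes(day_window[0])
    end = _clock_minutes(day_window[1]) + 1  # end minute inclusive
    t = pd.to_datetime(traj["t"])
    minutes = t.dt.hour * 60 + t.dt.minute + t.dt.second / 60.0
    if start <= end:
        is_day = (minutes >= start) & (minutes < end)
    else:  # window wrapping midnight
        is_day = (minutes >= start) | (minutes < end)
    return (traj[is_day].reset_index(drop=True),
            traj[~is_day].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Sample-size asymptote diagnostic
# ---------------------------------------------------------------------------

@dataclass
class AsymptoteCurve:
    counts: np.ndarray  # cumulative fix counts
    areas_ha: np.ndarray  # MCP area at each count
    plateau: bool


def asymptote_curve(traj: pd.DataFrame, step: int = 1,
                    window_frac: float = 0.20,
                    growth_tol: float = 0.05) -> AsymptoteCurve:
    """MCP area versus number of fixes, accumulated chronologically.

    The plateau flag replaces visual asymptote inspection: it is set when
    the final ``window_frac`` of the curve grows the area by less than
    ``growth_tol`` (relative).
    """
    if len(traj) < 10:
        raise ValueError("need at least 10 fixes for the asymptote curve")
    pts = traj[["x", "y"]].to_numpy(float)
    counts, areas = [], []
    for m in range(3, len(pts) + 1, step):
        hull = MultiPoint(pts[:m]).convex_hull
        counts.append(m)
        areas.append(hull.area / 1e4)
    if counts[-1] != len(pts):
        counts.append(len(pts))
        areas.append(MultiPoint(pts).convex_hull.area / 1e4)
    counts = np.asarray(counts)
    areas = np.asarray(areas)

    i0 = int(math.floor(len(areas) * (1.0 - window_frac)))
    i0 = min(max(i0, 0), len(areas) - 1)
    base = areas[i0]
    plateau = bool(base > 0 and (areas[-1] - base) / base < growth_tol)
    return AsymptoteCurve(counts, areas, plateau)


# ---------------------------------------------------------------------------
# Buffer geometry
# ---------------------------------------------------------------------------

def equivalent_circle_diameter(area_ha: float) -> tuple[float, float]:
    """Diameter of the circle with the given area.

    Returns ``(raw_m, reported_m)``; the reported value is rounded to the
    nearest 10 m, the resolution at which buffer guidance is quoted.
    """
    if area_ha <= 0:
        raise ValueError(f"area must be > 0 ha, got {area_ha}")
    d = 2.0 * math.sqrt(area_ha * 1e4 / math.pi)
    return d, round(d / 10.0) * 10.0


def buffer_distance(area_ha: float, margin: float) -> tuple[float, float]:
    """Management-buffer distance: equivalent-circle diameter plus a safety
    margin (e.g. 0.20 for 20 %), reported to the nearest 10 m."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    d, _ = equivalent_circle_diameter(area_ha)
    b = d * (1.0 + margin)
    return b, round(b / 10.0) * 10.0


# ---------------------------------------------------------------------------
# Small-sample tests on per-animal areas
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float  # W = sum of positive-difference ranks
    p_value: float
    n_used: int  # pairs remaining after dropping zero differences
    exact: bool


def _signed_rank_w(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(diffs))  # average ranks on ties
    w = float(ranks[diffs > 0].sum())
    return w, ranks


def paired_day_night_test(a, b) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired per-animal areas.

    W is the sum of positive-difference ranks; zero differences are dropped
    and tied absolute differences get average ranks. The two-sided p-value
    is exact (full sign enumeration) for up to 12 non-zero pairs, and uses
    the continuity-corrected normal approximation (with tie correction)
    beyond that.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    m = len(d)
    if m == 0:
        import warnings
        warnings.warn("all paired differences are zero", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, True)
    w, ranks = _signed_rank_w(d)

    if m <= 12:
        # exact null: every sign assignment equally likely
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        p_ge = float(np.mean(sums >= w - 1e-12))
        p_le = float(np.mean(sums <= w + 1e-12))
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(w, p, m, True)

    mean = m * (m + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_corr
    if var <= 0:
        return WilcoxonResult(w, 1.0, m, False)
    z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w, p, m, False)


@dataclass
class VarianceTestResult:
    statistic: float  # one-way ANOVA F on |x - group median|
    p_value: float


def variance_equality_test(group_a, group_b) -> VarianceTestResult:
    """Brown–Forsythe test of equal spread: ANOVA on absolute deviations
    from each group's median (robust to non-normal areas)."""
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 observations")
    za = np.abs(group_a - np.median(group_a))
    zb = np.abs(group_b - np.median(group_b))
    f, p = stats.f_oneway(za, zb)
    if np.isnan(f):  # all deviations identical in both groups
        return VarianceTestResult(0.0, 1.0)
    return VarianceTestResult(float(f), float(p))


# ---------------------------------------------------------------------------
# Multi-animal driver
# ---------------------------------------------------------------------------

def homerange_table(fixes: pd.DataFrame, kde_levels=(95.0, 50.0),
                    periods=("all",), day_window=("06:00", "17:59"),
                    n_grid: int = 200, bandwidth: float | None = None
                    ) -> tuple[pd.DataFrame, list[HomeRangeEstimate]]:
    """Per-animal MCP and KDE areas, optionally split by day/night."""
    rows, estimates = [], []
    for animal, traj in fixes.groupby("animal_id", sort=True):
        traj = traj.reset_index(drop=True)
        subsets = {}
        if "all" in periods:
            subsets["all"] = traj
        if "day" in periods or "night" in periods:
            day, night = split_day_night(traj, day_window)
            if "day" in periods:
                subsets["day"] = day
            if "night" in periods:
                subsets["night"] = night
        for period, sub in subsets.items():
            ests = []
            if len(sub) >= 3:
                try:
                    ests.append(mcp(sub, 100.0, period=period))
                except ValueError:
                    pass
            if len(sub) >= 5:
                for level in kde_levels:
                    try:
                        ests.append(kde_isopleth(sub, level, bandwidth,
                                                 n_grid, period=period))
                    except ValueError:
                        pass
            for est in ests:
                estimates.append(est)
                rows.append({
                    "animal_id": animal, "method": est.method,
                    "level": est.level, "period": est.period,
                    "area_ha": est.area_ha, "n_fixes": est.n_fixes,
                })
    return pd.DataFrame(rows), estimates
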