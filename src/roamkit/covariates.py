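"""Per-animal predictor construction for the home-range models.

Extrinsic predictors: road density (metres of road inside a fixed-radius
disc centred on the animal's mean coordinates — the radius is derived from
the median core home-range area so availability is standardised across
animals), and a binary flag for a major road intersecting the 100 % MCP.
Intrinsic predictors: sex, age and a neuroticism score from an owner-rated
personality inventory (mean of the 13 neuroticism Likert items, reported
z-standardised across the study's animals).

Disc clipping is exact analytic line–circle intersection; the disc is
closed, so length lying on the boundary counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RoadNetwork

N_NEUROTICISM_ITEMS = 13


# ---------------------------------------------------------------------------
# Road covariates
# ---------------------------------------------------------------------------

def _clip_segment_length(p0, p1, cx, cy, r) -> float:
    """Length of segment p0–p1 inside the closed disc (analytic)."""
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    fx, fy = p0[0] - cx, p0[1] - cy
    a = dx * dx + dy * dy
    if a == 0:
        return 0.0
    b = 2.0 * (fx * dx + fy * dy)
    c = fx * fx + fy * fy - r * r
    disc = b * b - 4.0 * a * c
    if disc <= 0:
        return 0.0  # misses the circle (or tangent: zero length)
    sq = math.sqrt(disc)
    t1 = max((-b - sq) / (2.0 * a), 0.0)
    t2 = min((-b + sq) / (2.0 * a), 1.0)
    if t2 <= t1:
        return 0.0
    return (t2 - t1) * math.sqrt(a)


def road_length_in_circle(roads: RoadNetwork, center: tuple[float, float],
                          radius: float) -> float:
    """Total road length (m) within the closed disc around ``center``."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    cx, cy = center
    total = 0.0
    for geom in roads.geoms:
        coords = list(geom.coords)
        for p0, p1 in zip(coords[:-1], coords[1:]):
            total += _clip_segment_length(p0, p1, cx, cy, radius)
    return total


def radius_from_median_kde(areas_ha) -> float:
    """Disc radius (m, nearest metre) whose area equals the median
    kernel home-range area — the standardised road-sampling radius."""
    areas_ha = np.asarray(areas_ha, dtype=float)
    if areas_ha.size == 0:
        raise ValueError("need at least one area")
    med = float(np.median(areas_ha))
    if med <= 0:
        raise ValueError(f"median area must be > 0 ha, got {med}")
    return float(round(math.sqrt(med * 1e4 / math.pi)))


def major_road_flag(roads: RoadNetwork, mcp_polygon) -> int:
    """1 iff any major-class road intersects the home-range polygon
    (closed-set intersection: touching the boundary counts)."""
    for geom, cls in zip(roads.geoms, roads.classes):
        if cls == "major" and geom.intersects(mcp_polygon):
            return 1
    return 0


# ---------------------------------------------------------------------------
# Personality scoring
# ---------------------------------------------------------------------------

def neuroticism_score(survey: pd.DataFrame, item_map: dict[str, str],
                      standardize: bool = True) -> pd.Series:
    """Neuroticism score per animal from the Likert item table.

    ``survey`` is indexed by animal with one column per item (ratings 1–7);
    ``item_map`` maps item name → trait domain and must assign exactly 13
    items to ``"neuroticism"`` (the domain's item count in the inventory).
    The raw score is the mean of the 13 item ratings; by default the score
    is z-standardised across animals (raw scores are recoverable with
    ``standardize=False``).
    """
    items = [it for it, dom in item_map.items() if dom == "neuroticism"]
    if len(items) != N_NEUROTICISM_ITEMS:
        raise ValueError(
            f"item map must assign exactly {N_NEUROTICISM_ITEMS} items to "
            f"neuroticism, got {len(items)}"
        )
    missing = [it for it in items if it not in survey.columns]
    if missing:
        raise ValueError(f"survey is missing neuroticism item(s): {missing}")
    block = survey[items]
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise ValueError(f"incomplete ratings for item(s): {bad}")
    vals = block.to_numpy(float)
    if not np.isin(vals, np.arange(1, 8)).all():
        raise ValueError("Likert ratings must be integers in 1..7")
    raw = block.mean(axis=1)
    if not standardize:
        return raw
    sd = raw.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError(
            "zero variance in raw neuroticism scores: standardisation "
            "undefined"
        )
    return (raw - raw.mean()) / sd


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    ``item_matrix`` is (animals × items); alpha =
    (k/(k−1))·(1 − Σ item variances / variance of the total score),
    with sample (n−1) variances.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 animals and 2 items")
    k = m.shape[1]
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


# ---------------------------------------------------------------------------
# Covariate table assembly
# ---------------------------------------------------------------------------

@dataclass
class AnimalCovariates:
    animal_id: str
    sex: str  # "M" | "F" | "unknown"
    age: float  # years
    neuroticism: float  # standardised score
    road_density: float  # metres of road in the sampling disc
    major_road: int  # 0/1
    start_ordinal_date: int  # day of year of first fix, Jan 1 = 1
    mean_x: float
    mean_y: float


def build_covariate_table(fixes: pd.DataFrame, roads: RoadNetwork,
                          metadata: pd.DataFrame,
                          survey: pd.DataFrame | None,
                          item_map: dict[str, str] | None,
                          mcp_polygons: dict[str, object],
                          road_radius: float) -> pd.DataFrame:
    """Assemble the per-animal predictor table.

    ``metadata`` is indexed by animal with columns sex and age; animals
    missing from the survey get NaN neuroticism (model stages drop them
    with a logged count rather than failing).
    """
    neuro = None
    if survey is not None and item_map is not None:
        neuro = neuroticism_score(survey, item_map)
    rows = []
    for animal, traj in fixes.groupby("animal_id", sort=True):
        mx, my = float(traj["x"].mean()), float(traj["y"].mean())
        t0 = pd.to_datetime(traj["t"]).min()
        sex = "unknown"
        age = np.nan
        if metadata is not None and animal in metadata.index:
            sex = str(metadata.loc[animal].get("sex", "unknown"))
            age = float(metadata.loc[animal].get("age", np.nan))
        nz = float(neuro.loc[animal]) if neuro is not None \
            and animal in neuro.index else np.nan
        flag = major_road_flag(roads, mcp_polygons[animal]) \
            if animal in mcp_polygons else 0
        rows.append({
            "animal_id": animal,
            "sex": sex,
            "age": age,
            "neuroticism": nz,
            "road_density": road_length_in_circle(roads, (mx, my),
                                                  road_radius),
            "major_road": flag,
            "start_ordinal_date": int(t0.dayofyear),
            "mean_x": mx,
            "mean_y": my,
        })
    return pd.DataFrame(rows).set_index("animal_id")
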