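"""Readers, writers and in-memory spatial containers.

Trajectories are plain pandas DataFrames with columns
``(animal_id, t, x, y)`` — timestamps are naive local-clock datetimes and
coordinates are metres in the run's projected CRS. Land cover is a regular
categorical raster (ESRI ASCII grid on disk, plain text); roads and
home-range polygons travel as GeoJSON (RFC 7946) through shapely.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, mapping, shape

from .config import CATEGORIES, RunConfig
from .projection import lonlat_to_xy, xy_to_lonlat

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["animal_id", "t", "x", "y"]


# ---------------------------------------------------------------------------
# Land cover raster
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    """Categorical land-cover raster in projected metres.

    ``grid[row, col]`` holds an index into ``categories``; row 0 is the
    southern edge (y increasing with row index). A point belongs to the cell
    whose half-open square ``[x0+i*cell, x0+(i+1)*cell)`` contains it.
    """

    grid: np.ndarray  # (nrows, ncols) int
    x0: float  # west edge, metres
    y0: float  # south edge, metres
    cell: float  # cell size, metres
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int16)
        if self.grid.ndim != 2:
            raise ValueError("landscape grid must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")
        if self.grid.size and self.grid.max() >= len(self.categories):
            raise ValueError("grid contains codes outside the category list")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        nrows, ncols = self.grid.shape
        return (self.x0, self.y0, self.x0 + ncols * self.cell,
                self.y0 + nrows * self.cell)

    def category_index_at(self, x, y) -> np.ndarray:
        """Vectorised category-code lookup; raises outside the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        bad = (x < xmin) | (x >= xmax) | (y < ymin) | (y >= ymax)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"point ({np.atleast_1d(x).flat[i]:.1f}, "
                f"{np.atleast_1d(y).flat[i]:.1f}) lies outside the landscape "
                f"extent {self.extent}"
            )
        col = ((x - self.x0) // self.cell).astype(int)
        row = ((y - self.y0) // self.cell).astype(int)
        return self.grid[row, col]

    def category_at(self, x, y):
        idx = self.category_index_at(x, y)
        if np.ndim(idx) == 0:
            return self.categories[int(idx)]
        return np.asarray(self.categories, dtype=object)[idx]

    def proportions(self) -> dict[str, float]:
        counts = np.bincount(self.grid.ravel(), minlength=len(self.categories))
        total = counts.sum()
        return {c: counts[i] / total for i, c in enumerate(self.categories)}


# ---------------------------------------------------------------------------
# Road network
# ---------------------------------------------------------------------------

@dataclass
class RoadNetwork:
    """Road line features with a major/minor class attribute."""

    geoms: list  # shapely LineString, metres
    classes: list  # "major" | "minor" per feature

    def __post_init__(self) -> None:
        if len(self.geoms) != len(self.classes):
            raise ValueError("one class attribute per road feature required")
        for i, cls in enumerate(self.classes):
            if cls not in ("major", "minor"):
                raise ValueError(
                    f"road feature {i}: class must be 'major' or 'minor', "
                    f"got {cls!r}"
                )

    def __len__(self) -> int:
        return len(self.geoms)

    def subset(self, road_class: str) -> "RoadNetwork":
        keep = [i for i, c in enumerate(self.classes) if c == road_class]
        return RoadNetwork([self.geoms[i] for i in keep],
                           [self.classes[i] for i in keep])


# ---------------------------------------------------------------------------
# GPS fix ingestion
# ---------------------------------------------------------------------------

def _parse_gpx(path: Path) -> pd.DataFrame:
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    rows = []
    for trk in root.findall("gpx:trk", ns):
        name_el = trk.find("gpx:name", ns)
        animal = name_el.text if name_el is not None else "animal_0"
        for pt in trk.iter("{http://www.topografix.com/GPX/1/1}trkpt"):
            time_el = pt.find("gpx:time", ns)
            rows.append({
                "animal_id": animal,
                "timestamp": time_el.text if time_el is not None else None,
                "lat": float(pt.attrib["lat"]),
                "lon": float(pt.attrib["lon"]),
            })
    return pd.DataFrame(rows)


def read_fixes(path: str | Path, config: RunConfig) -> pd.DataFrame:
    """Load GPS fixes from CSV or GPX into the canonical trajectory frame.

    Geographic input (lon/lat columns) is projected into the configured UTM
    zone; projected input (x/y columns) is taken as-is. Exact duplicate
    records are dropped with a logged count; two different positions at the
    same (animal, time) are an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        raw = _parse_gpx(path)
    else:
        raw = pd.read_csv(path)

    if "animal_id" not in raw.columns or "timestamp" not in raw.columns:
        raise ValueError("fix table needs 'animal_id' and 'timestamp' columns")

    t = pd.to_datetime(raw["timestamp"], errors="coerce", format="mixed")
    if t.isna().any():
        bad_rows = list(raw.index[t.isna()][:10])
        raise ValueError(f"unparseable timestamp(s) at row(s) {bad_rows}")
    # local clock semantics: drop any timezone info after parsing
    try:
        t = t.dt.tz_localize(None)
    except TypeError:
        pass

    df = pd.DataFrame({"animal_id": raw["animal_id"].astype(str), "t": t})
    if {"x", "y"}.issubset(raw.columns):
        df["x"] = raw["x"].astype(float)
        df["y"] = raw["y"].astype(float)
        if {"lon", "lat"}.issubset(raw.columns):
            df["lon"] = raw["lon"].astype(float)
            df["lat"] = raw["lat"].astype(float)
    elif {"lon", "lat"}.issubset(raw.columns):
        x, y = lonlat_to_xy(raw["lon"].to_numpy(float),
                            raw["lat"].to_numpy(float), config.crs_epsg)
        df["x"], df["y"] = x, y
        df["lon"] = raw["lon"].astype(float)
        df["lat"] = raw["lat"].astype(float)
    else:
        raise ValueError("fix table needs either (x, y) or (lon, lat) columns")

    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in fix table")

    n0 = len(df)
    df = df.drop_duplicates(subset=["animal_id", "t", "x", "y"])
    n_dup = n0 - len(df)
    if n_dup:
        logger.info("%d duplicate fix(es) dropped", n_dup)

    conflict = df.duplicated(subset=["animal_id", "t"], keep=False)
    if conflict.any():
        row = df[conflict].iloc[0]
        raise ValueError(
            f"conflicting positions for animal {row.animal_id!r} at {row.t}"
        )

    df = df.sort_values(["animal_id", "t"], kind="mergesort").reset_index(drop=True)
    return df


def write_fixes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["timestamp"] = out.pop("t").dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid + category-mapping sidecar)
# ---------------------------------------------------------------------------

def read_landscape(path: str | Path, mapping_path: str | Path) -> Landscape:
    """Read an ESRI ASCII grid and normalise its codes to the 6-way scheme.

    ``mapping_path`` is a JSON object mapping raster codes (as strings) to
    category names; any code present in the grid but absent from the mapping
    is an error listing the offending codes.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    data = np.loadtxt(lines[n_header:], dtype=int)
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"grid body {data.shape} does not match header ({nrows}, {ncols})"
        )
    data = data[::-1]  # file rows run north→south; store south-up

    with open(mapping_path) as fh:
        code_map = {int(k): v for k, v in json.load(fh).items()}
    present = np.unique(data)
    missing = [int(c) for c in present if int(c) not in code_map]
    if missing:
        raise ValueError(f"unmapped land-cover code(s): {missing}")
    bad_names = sorted({v for v in code_map.values()} - set(CATEGORIES))
    if bad_names:
        raise ValueError(
            f"mapping targets outside the category scheme: {bad_names}"
        )

    lut = np.zeros(int(present.max()) + 1, dtype=np.int16)
    for code, name in code_map.items():
        if 0 <= code < len(lut):
            lut[code] = CATEGORIES.index(name)
    grid = lut[data]
    return Landscape(grid, header["xllcorner"], header["yllcorner"],
                     header["cellsize"])


def write_landscape(ls: Landscape, path: str | Path,
                    mapping_path: str | Path | None = None) -> None:
    """Write as ESRI ASCII grid; codes are indices into the canonical scheme."""
    nrows, ncols = ls.grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n" f"nrows {nrows}\n")
        fh.write(f"xllcorner {ls.x0}\n" f"yllcorner {ls.y0}\n")
        fh.write(f"cellsize {ls.cell}\n" "NODATA_value -1\n")
        np.savetxt(fh, ls.grid[::-1], fmt="%d")
    if mapping_path is not None:
        with open(mapping_path, "w") as fh:
            json.dump({str(i): c for i, c in enumerate(ls.categories)}, fh,
                      indent=1)


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

def read_roads(path: str | Path) -> RoadNetwork:
    with open(path) as fh:
        gj = json.load(fh)
    geoms, classes = [], []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if "road_class" not in props:
            raise ValueError(f"road feature {i} is missing 'road_class'")
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiLineString":
            for part in geom.geoms:
                geoms.append(part)
                classes.append(props["road_class"])
        else:
            geoms.append(geom)
            classes.append(props["road_class"])
    return RoadNetwork(geoms, classes)


def write_roads(roads: RoadNetwork, path: str | Path) -> None:
    feats = [
        {"type": "Feature", "properties": {"road_class": cls},
         "geometry": mapping(geom)}
        for geom, cls in zip(roads.geoms, roads.classes)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_polygons(records: list[dict], path: str | Path) -> None:
    """Write home-range polygons: each record has 'geometry' plus properties."""
    feats = []
    for rec in records:
        rec = dict(rec)
        geom = rec.pop("geometry")
        feats.append({"type": "Feature", "properties": rec,
                      "geometry": mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_polygons(path: str | Path) -> list[dict]:
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj["features"]:
        rec = dict(feat.get("properties") or {})
        rec["geometry"] = shape(feat["geometry"])
        out.append(rec)
    return out


def write_sidecar(path: str | Path, config: RunConfig,
                  extra: dict | None = None) -> None:
    """Metadata sidecar written next to every pipeline output."""
    meta = {"config_hash": config.config_hash(), "rng_seed": config.rng_seed}
    if extra:
        meta.update(extra)
    with open(Path(path).with_suffix(Path(path).suffix + ".meta.json"),
              "w") as fh:
        json.dump(meta, fh, indent=1)
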