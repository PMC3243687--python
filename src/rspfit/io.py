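"""Plain-text artifact I/O.

Rasters are written as ESRI ASCII grids (.asc), vector features as GeoJSON
FeatureCollections in the local projected frame (coordinates in meters),
points as CSV with ``x_m``/``y_m`` columns, and each run carries a JSON
manifest recording the seeds and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, mapping, shape

from .landscape import FeatureSet, HabitatGrid, LandscapeBundle
from .survey import SurveyDesign

__all__ = [
    "write_ascii_grid", "read_ascii_grid",
    "write_features_geojson", "read_features_geojson",
    "write_points_csv", "read_points_csv",
    "save_landscape", "load_landscape",
    "save_design", "load_design",
    "config_hash", "write_manifest",
]

NODATA = -9999


def write_ascii_grid(path, values: np.ndarray, origin: tuple[float, float],
                     cell_m: float, fmt: str = "%.6g") -> None:
    """ESRI ASCII grid; ``origin`` is the (x, ytop) of the top-left corner."""
    values = np.asarray(values)
    nrow, ncol = values.shape
    x0, ytop = origin
    header = (
        f"ncols {ncol}\nnrows {nrow}\n"
        f"xllcorner {x0:.6f}\nyllcorner {ytop - nrow * cell_m:.6f}\n"
        f"cellsize {cell_m:.6f}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Returns (values, (x0, ytop), cell_m)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    nrow = int(header["nrows"])
    ncol = int(header["ncols"])
    values = values.reshape(nrow, ncol)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrow * cell)
    return values, origin, cell


def write_features_geojson(path, features: FeatureSet) -> None:
    feats = []

    def add(geom, kind, **props):
        if geom is None or getattr(geom, "is_empty", False):
            return
        feats.append({"type": "Feature", "properties": {"kind": kind, **props},
                      "geometry": mapping(geom)})

    for i, r in enumerate(features.roads):
        add(r, "road", main=r in features.main_roads, index=i)
    for i, r in enumerate(features.rivers):
        add(r, "river", index=i)
    add(features.park, "park")
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_features_geojson(path, springs: np.ndarray, elevation: np.ndarray) -> FeatureSet:
    with open(path) as fh:
        gj = json.load(fh)
    roads, main_roads, rivers = [], [], []
    park = shapely.Polygon()
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        kind = feat["properties"].get("kind")
        if kind == "road":
            roads.append(geom)
            if feat["properties"].get("main"):
                main_roads.append(geom)
        elif kind == "river":
            rivers.append(geom)
        elif kind == "park":
            park = geom
    return FeatureSet(roads=roads, main_roads=main_roads, rivers=rivers,
                      springs=springs, park=park, elevation=elevation)


def write_points_csv(path, xy: np.ndarray, **attrs) -> None:
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    df = pd.DataFrame({"x_m": xy[:, 0], "y_m": xy[:, 1], **attrs})
    df.to_csv(path, index=False)


def read_points_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- landscape / design bundles ---------------------------------------------


def save_landscape(outdir, bundle: LandscapeBundle) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = bundle.habitat
    write_ascii_grid(outdir / "habitat.asc", grid.codes, grid.origin, grid.cell_m, fmt="%d")
    write_ascii_grid(outdir / "elevation.asc", bundle.elevation, grid.origin, grid.cell_m)
    write_features_geojson(outdir / "features.geojson", bundle.features)
    write_points_csv(outdir / "springs.csv", bundle.features.springs)


def load_landscape(outdir) -> LandscapeBundle:
    outdir = Path(outdir)
    codes, origin, cell = read_ascii_grid(outdir / "habitat.asc")
    elev, _, _ = read_ascii_grid(outdir / "elevation.asc")
    springs_df = read_points_csv(outdir / "springs.csv")
    springs = springs_df[["x_m", "y_m"]].to_numpy() if len(springs_df) else np.empty((0, 2))
    grid = HabitatGrid(codes.astype(np.int16), origin, cell)
    features = read_features_geojson(outdir / "features.geojson", springs, elev)
    return LandscapeBundle(habitat=grid, features=features)


def save_design(outdir, design: SurveyDesign) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t, wp in enumerate(design.transects):
        for k in range(len(wp)):
            rows.append((t, design.quadrat_of[t], k, wp[k, 0], wp[k, 1]))
    pd.DataFrame(rows, columns=["transect", "quadrat", "waypoint", "x_m", "y_m"]) \
        .to_csv(outdir / "waypoints.csv", index=False)
    pd.DataFrame(design.quadrats, columns=["x0", "y0", "x1", "y1"]) \
        .to_csv(outdir / "quadrats.csv", index=False)
    with open(outdir / "design.json", "w") as fh:
        json.dump({"extent": list(design.extent), "waypoint_m": design.waypoint_m,
                   "km_walked": design.km_walked}, fh, indent=2)


def load_design(outdir) -> SurveyDesign:
    outdir = Path(outdir)
    wp = pd.read_csv(outdir / "waypoints.csv")
    quads = pd.read_csv(outdir / "quadrats.csv")
    with open(outdir / "design.json") as fh:
        meta = json.load(fh)
    transects, quadrat_of = [], []
    for t, g in wp.groupby("transect", sort=True):
        g = g.sort_values("waypoint")
        transects.append(g[["x_m", "y_m"]].to_numpy())
        quadrat_of.append(int(g["quadrat"].iloc[0]))
    return SurveyDesign(
        quadrats=[tuple(r) for r in quads.to_numpy()],
        transects=transects, quadrat_of=quadrat_of,
        extent=tuple(meta["extent"]), waypoint_m=meta["waypoint_m"])


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, config: dict, seed: int, extra: dict | None = None) -> None:
    from importlib.metadata import version

    try:
        ver = version("rspfit")
    except Exception:
        ver = "unknown"
    manifest = {"seed": seed, "config_hash": config_hash(config),
                "package_version": ver, **(extra or {})}
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
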