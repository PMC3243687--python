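"""Synthetic Cerrado-like landscapes.

The study system is a mosaic of natural savanna vegetation (riparian forest,
woodland cerrado, open cerrado, grassland, seasonal marsh) interleaved with
cattle pasture and row-crop agriculture, around a large grassland-dominated
national park. No real classified raster is distributed with the package, so
this module synthesises landscapes with that structure: a categorical habitat
raster, an elevation surface, a park polygon, rivers buffered by riparian
forest, ordinary and main roads, and spring points — all co-registered on one
projected planar grid (meters, arbitrary local frame).

Habitat classes are drawn by rank-thresholding a Gaussian-smoothed random
field separately inside and outside the park, which produces spatially
clustered patches whose class proportions match the requested mix essentially
exactly; the park interior mix shifts the developed-class mass (pasture,
agriculture) onto natural classes, and the exterior mix compensates so the
landscape-wide proportions still match.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box

from ._streams import stream

__all__ = [
    "CLASS_NAMES",
    "CLASS_CODES",
    "NATURAL_CLASSES",
    "CLOSED_CLASSES",
    "OPEN_CLASSES",
    "LandscapeConfig",
    "HabitatGrid",
    "FeatureSet",
    "LandscapeBundle",
    "generate_landscape",
]

# Habitat classes (Cerrado vegetation / land-use mosaic) and integer codes.
CLASS_NAMES: tuple[str, ...] = (
    "forest",         # riparian, tall-canopy forest
    "cerrado",        # closed woodland, 50-90% crown cover
    "open cerrado",   # shrubby savanna, >30% crown cover
    "grassland",      # open dry grassland
    "marsh",          # seasonally waterlogged grassland
    "pasture",        # cattle ranchland
    "agriculture",    # row crops (soy, corn, cotton, ...)
    "unknown",        # unclassifiable (cloud cover etc.)
)
CLASS_CODES: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

NATURAL_CLASSES = ("forest", "cerrado", "open cerrado", "grassland", "marsh")
CLOSED_CLASSES = ("forest", "cerrado")
# open-canopy, non-crop: grassland, open cerrado and ranchland (pasture)
OPEN_CLASSES = ("grassland", "open cerrado", "pasture")

#: Landscape-wide class mix used by default: an agriculture-dominated matrix
#: with remnant natural vegetation, emulating the study region.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "forest": 0.06,
    "cerrado": 0.08,
    "open cerrado": 0.10,
    "grassland": 0.18,
    "marsh": 0.02,
    "pasture": 0.16,
    "agriculture": 0.37,
    "unknown": 0.03,
}


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration for :func:`generate_landscape`.

    Defaults describe the full study system: a ~4600 km^2 area at 30 m
    resolution, ~29% of it inside the park, surveyed with 65 quadrats of
    5x5 km.
    """

    extent_m: tuple[float, float] = (80_000.0, 57_600.0)  # (width, height)
    cell_m: float = 30.0
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    park_fraction: float = 0.28
    n_quadrats: int = 65
    quadrat_size_m: float = 5_000.0
    patch_m: float = 600.0          # habitat patch correlation length
    n_rivers: int = 3
    n_roads: int = 6
    n_main_roads: int = 2
    n_springs: int = 40
    river_buffer_m: float = 60.0    # riparian forest buffer along rivers
    seed: int = 0

    def validate(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ValueError("extent_m must be positive")
        for name, p in self.class_mix.items():
            if name not in CLASS_CODES:
                raise ValueError(f"unknown habitat class in class_mix: {name!r}")
            if p < 0:
                raise ValueError(f"class_mix[{name!r}] = {p} is negative; infeasible mix")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total!r})")
        for dim in (w, h):
            if abs(dim / self.cell_m - round(dim / self.cell_m)) > 1e-9:
                raise ValueError("extent must be divisible by the cell size")
        if not (0.0 <= self.park_fraction < 1.0):
            raise ValueError("park_fraction must be in [0, 1)")

    def replace(self, **kw) -> "LandscapeConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class HabitatGrid:
    """Categorical habitat raster on a projected planar grid.

    ``origin`` is the (x, y) of the top-left corner; rows increase downward
    (decreasing y), columns increase with x. A point maps to its containing
    cell with half-open intervals [x, x+cell) horizontally and (y-cell, y]
    vertically.
    """

    codes: np.ndarray            # (nrow, ncol) int array of class codes
    origin: tuple[float, float]  # (x0, ytop)
    cell_m: float

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or self.codes.size == 0:
            raise ValueError("habitat grid must be a non-empty 2-D array")
        valid = set(CLASS_CODES.values())
        if not set(np.unique(self.codes)).issubset(valid):
            raise ValueError("habitat grid contains invalid class codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        x0, ytop = self.origin
        nrow, ncol = self.codes.shape
        return (x0, ytop - nrow * self.cell_m, x0 + ncol * self.cell_m, ytop)

    def cell_index(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each point (no bounds check)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x0, ytop = self.origin
        col = np.floor((xy[:, 0] - x0) / self.cell_m).astype(int)
        row = np.floor((ytop - xy[:, 1]) / self.cell_m).astype(int)
        # points exactly on the top edge belong to row 0
        row = np.where(np.isclose(xy[:, 1], ytop), 0, row)
        col = np.where(np.isclose(xy[:, 0], x0 + self.codes.shape[1] * self.cell_m),
                       self.codes.shape[1] - 1, col)
        return row, col

    def contains(self, xy: np.ndarray) -> np.ndarray:
        row, col = self.cell_index(xy)
        nrow, ncol = self.codes.shape
        return (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)

    def class_at(self, xy: np.ndarray) -> np.ndarray:
        """Class code of the cell containing each point."""
        row, col = self.cell_index(xy)
        nrow, ncol = self.codes.shape
        bad = (row < 0) | (row >= nrow) | (col < 0) | (col >= ncol)
        if np.any(bad):
            ids = np.nonzero(bad)[0].tolist()
            raise ValueError(f"points outside grid extent at indices {ids}")
        return self.codes[row, col]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as 1-D arrays over columns / rows."""
        x0, ytop = self.origin
        nrow, ncol = self.codes.shape
        xs = x0 + (np.arange(ncol) + 0.5) * self.cell_m
        ys = ytop - (np.arange(nrow) + 0.5) * self.cell_m
        return xs, ys

    def proportions(self) -> dict[str, float]:
        counts = np.bincount(self.codes.ravel(), minlength=len(CLASS_NAMES))
        return {name: counts[code] / self.codes.size for name, code in CLASS_CODES.items()}


@dataclass
class FeatureSet:
    """Vector features and the elevation surface co-registered with the grid."""

    roads: list[LineString]
    main_roads: list[LineString]
    rivers: list[LineString]
    springs: np.ndarray          # (n, 2) point coordinates
    park: Polygon
    elevation: np.ndarray        # co-registered with the habitat grid

    def __post_init__(self) -> None:
        ids = {id(r) for r in self.roads}
        for m in self.main_roads:
            if id(m) not in ids and m not in self.roads:
                raise ValueError("main_roads must be a subset of roads")


@dataclass
class LandscapeBundle:
    """Everything downstream stages need, on one projected grid."""

    habitat: HabitatGrid
    features: FeatureSet
    config: LandscapeConfig | None = None

    @property
    def park(self) -> Polygon:
        return self.features.park

    @property
    def elevation(self) -> np.ndarray:
        return self.features.elevation


# ---------------------------------------------------------------------------
# generation internals


def _smooth_field(shape: tuple[int, int], sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    field = rng.standard_normal(shape)
    return ndimage.gaussian_filter(field, sigma=max(sigma_cells, 0.5), mode="reflect")


def _assign_by_rank(field: np.ndarray, mask: np.ndarray, mix: dict[str, float],
                    class_order: list[str], out: np.ndarray) -> None:
    """Fill ``out[mask]`` with class codes whose counts match ``mix`` exactly
    (up to integer rounding), clustering classes along the field's level sets."""
    vals = field[mask]
    n = vals.size
    if n == 0:
        return
    order = np.argsort(vals, kind="stable")
    codes = np.empty(n, dtype=out.dtype)
    start = 0
    remaining = n
    names = [c for c in class_order if mix.get(c, 0.0) > 0]
    weights = np.array([mix[c] for c in names], dtype=float)
    weights = weights / weights.sum()
    for i, name in enumerate(names):
        take = remaining if i == len(names) - 1 else int(round(weights[i] * n))
        take = min(take, remaining)
        codes[order[start:start + take]] = CLASS_CODES[name]
        start += take
        remaining -= take
    out[mask] = codes


def _park_polygon(cfg: LandscapeConfig, rng: np.random.Generator) -> Polygon:
    w, h = cfg.extent_m
    if cfg.park_fraction <= 0:
        return Polygon()  # empty: no park
    area = cfg.park_fraction * w * h
    aspect = w / h
    pw = min(np.sqrt(area * aspect), 0.9 * w)
    ph = area / pw
    if ph > 0.9 * h:
        ph = 0.9 * h
        pw = area / ph
    # random placement with a margin, snapped to the cell lattice
    x0 = rng.uniform(0.02 * w, w - pw - 0.02 * w) if w - pw > 0.04 * w else (w - pw) / 2
    y0 = rng.uniform(0.02 * h, h - ph - 0.02 * h) if h - ph > 0.04 * h else (h - ph) / 2
    c = cfg.cell_m
    x0, y0 = round(x0 / c) * c, round(y0 / c) * c
    return box(x0, y0, x0 + pw, y0 + ph)


def _meander(start: np.ndarray, heading: float, extent: tuple[float, float],
             rng: np.random.Generator, step: float = 200.0, wiggle: float = 0.18) -> LineString:
    """Random-walk polyline from an edge point until it leaves the extent."""
    w, h = extent
    pts = [start.copy()]
    pos = start.copy()
    for _ in range(int(4 * (w + h) / step)):
        heading += rng.normal(0.0, wiggle)
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        pts.append(pos.copy())
        if not (0 <= pos[0] <= w and 0 <= pos[1] <= h):
            break
    line = LineString(pts)
    clipped = line.intersection(box(0, 0, w, h))
    if clipped.is_empty or clipped.geom_type != "LineString" or len(clipped.coords) < 2:
        # fall back to the straight chord across the extent
        return LineString([(0, rng.uniform(0.2, 0.8) * h), (w, rng.uniform(0.2, 0.8) * h)])
    return clipped


def _rivers(cfg: LandscapeConfig, rng: np.random.Generator) -> list[LineString]:
    w, h = cfg.extent_m
    rivers = []
    for _ in range(cfg.n_rivers):
        if rng.uniform() < 0.5:
            start = np.array([0.0, rng.uniform(0.15, 0.85) * h])
            heading = rng.normal(0.0, 0.2)
        else:
            start = np.array([rng.uniform(0.15, 0.85) * w, h])
            heading = rng.normal(-np.pi / 2, 0.2)
        rivers.append(_meander(start, heading, (w, h), rng))
    return rivers


def _roads(cfg: LandscapeConfig, rng: np.random.Generator) -> list[LineString]:
    w, h = cfg.extent_m
    roads = []
    for _ in range(cfg.n_roads):
        if rng.uniform() < 0.5:  # roughly east-west
            y1, y2 = rng.uniform(0.05, 0.95, 2) * h
            roads.append(LineString([(0, y1), (w, y2)]))
        else:                    # roughly north-south
            x1, x2 = rng.uniform(0.05, 0.95, 2) * w
            roads.append(LineString([(x1, 0), (x2, h)]))
    return roads


def _line_cells(lines: list[LineString], grid: HabitatGrid) -> np.ndarray:
    """Boolean raster of cells traversed by any of the polylines."""
    mask = np.zeros(grid.shape, dtype=bool)
    step = grid.cell_m / 2.0
    for line in lines:
        if line.is_empty:
            continue
        d = np.arange(0.0, line.length + step, step)
        pts = np.array([line.interpolate(float(t)).coords[0] for t in d])
        row, col = grid.cell_index(pts)
        ok = (row >= 0) & (row < grid.shape[0]) & (col >= 0) & (col < grid.shape[1])
        mask[row[ok], col[ok]] = True
    return mask


def _park_mask(park: Polygon, grid: HabitatGrid) -> np.ndarray:
    if park.is_empty:
        return np.zeros(grid.shape, dtype=bool)
    xs, ys = grid.cell_centers()
    xmin, ymin, xmax, ymax = park.bounds
    inx = (xs >= xmin) & (xs <= xmax)
    iny = (ys >= ymin) & (ys <= ymax)
    # park polygons are axis-aligned rectangles, so the bbox test is exact;
    # fall back to shapely if the polygon is not rectangular
    if np.isclose(park.area, (xmax - xmin) * (ymax - ymin)):
        return iny[:, None] & inx[None, :]
    import shapely

    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(gx.ravel(), gy.ravel())
    return shapely.covers(park, pts).reshape(grid.shape)


def _biased_mixes(cfg: LandscapeConfig, park_frac_actual: float) -> tuple[dict, dict]:
    """Split the global mix into park-interior and exterior mixes.

    Inside the park all pasture/agriculture mass is reassigned to natural
    classes (proportional to their global weights, defaulting to grassland);
    the exterior compensates so the area-weighted total matches the global mix.
    """
    mix = {c: cfg.class_mix.get(c, 0.0) for c in CLASS_NAMES}
    f = park_frac_actual
    developed = ("pasture", "agriculture")
    m_in = dict(mix)
    mass = sum(m_in[c] for c in developed)
    for c in developed:
        m_in[c] = 0.0
    nat_w = {c: mix[c] for c in NATURAL_CLASSES}
    tot = sum(nat_w.values())
    if tot <= 0:
        nat_w = {"grassland": 1.0}
        tot = 1.0
    for c, wgt in nat_w.items():
        m_in[c] = m_in.get(c, 0.0) + mass * wgt / tot
    s = sum(m_in.values())
    m_in = {c: v / s for c, v in m_in.items()} if s > 0 else m_in
    if f >= 1.0 - 1e-12 or f <= 0.0:
        return m_in, dict(mix)
    m_out = {c: (mix[c] - f * m_in[c]) / (1.0 - f) for c in CLASS_NAMES}
    m_out = {c: max(v, 0.0) for c, v in m_out.items()}
    s = sum(m_out.values())
    m_out = {c: v / s for c, v in m_out.items()}
    return m_in, m_out


def generate_landscape(config: LandscapeConfig) -> LandscapeBundle:
    """Generate a landscape bundle. Deterministic given ``config.seed``.

    Post-conditions: habitat class proportions within 0.05 of
    ``config.class_mix`` per class; river corridors carry riparian forest;
    the park interior is biased toward natural classes and the exterior
    toward pasture/agriculture.
    """
    config.validate()
    w, h = config.extent_m
    ncol = int(round(w / config.cell_m))
    nrow = int(round(h / config.cell_m))
    grid = HabitatGrid(np.zeros((nrow, ncol), dtype=np.int16), origin=(0.0, h), cell_m=config.cell_m)

    rng_park = stream(config.seed, "landscape/park")
    park = _park_polygon(config, rng_park)
    park_mask = _park_mask(park, grid)
    f_actual = park_mask.mean()

    rng_field = stream(config.seed, "landscape/field")
    sigma = config.patch_m / config.cell_m
    fld = _smooth_field((nrow, ncol), sigma, rng_field)
    class_order = list(CLASS_NAMES)
    rng_field.shuffle(class_order)

    m_in, m_out = _biased_mixes(config, f_actual)
    codes = grid.codes
    _assign_by_rank(fld, park_mask, m_in, class_order, codes)
    _assign_by_rank(fld, ~park_mask, m_out, class_order, codes)

    rng_riv = stream(config.seed, "landscape/rivers")
    rivers = _rivers(config, rng_riv)
    # riparian corridors only exist where the mix contains forest at all
    if rivers and config.river_buffer_m > 0 and config.class_mix.get("forest", 0.0) > 0:
        on_river = _line_cells(rivers, grid)
        if on_river.any():
            d = ndimage.distance_transform_edt(~on_river, sampling=config.cell_m)
            codes[d <= config.river_buffer_m] = CLASS_CODES["forest"]

    rng_road = stream(config.seed, "landscape/roads")
    roads = _roads(config, rng_road)
    main_roads = roads[: config.n_main_roads]

    rng_spr = stream(config.seed, "landscape/springs")
    springs = []
    for _ in range(config.n_springs):
        if rivers:
            riv = rivers[rng_spr.integers(len(rivers))]
            p = riv.interpolate(rng_spr.uniform(0, riv.length))
            off = rng_spr.normal(0, 150.0, 2)
            xy = np.clip([p.x + off[0], p.y + off[1]], [0, 0], [w, h])
        else:
            xy = rng_spr.uniform([0, 0], [w, h])
        springs.append(xy)
    springs = np.array(springs) if springs else np.empty((0, 2))

    rng_elev = stream(config.seed, "landscape/elevation")
    elev = _smooth_field((nrow, ncol), 2 * sigma, rng_elev)
    sd = elev.std()
    elev = 800.0 + 60.0 * (elev / sd if sd > 0 else elev)

    features = FeatureSet(roads=roads, main_roads=main_roads, rivers=rivers,
                          springs=springs, park=park, elevation=elev)
    return LandscapeBundle(habitat=grid, features=features, config=config)
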