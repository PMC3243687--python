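"""Survey designs: 5x5 km search quadrats walked as 30-m waypoint transects.

The field protocol this emulates is a team of scat-detection-dog handlers
walking free-form daily transects inside pre-assigned square quadrats, with a
GPS waypoint recorded every 30 m. The quadrats tile the study area without
overlap; the set of transect polylines defines the surveyed corridor against
which availability is later sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, box

from ._streams import stream
from .landscape import LandscapeBundle, LandscapeConfig

__all__ = ["SurveyDesign", "generate_survey_design"]

WAYPOINT_SPACING_M = 30.0  # GPS waypoint interval along walked transects


@dataclass
class SurveyDesign:
    """Quadrats and transects discretized as ordered 30-m waypoints."""

    quadrats: list[tuple[float, float, float, float]]  # (x0, y0, x1, y1)
    transects: list[np.ndarray]                        # each (n_i, 2) waypoints
    quadrat_of: list[int]                              # transect -> quadrat index
    extent: tuple[float, float, float, float]          # study (xmin, ymin, xmax, ymax)
    waypoint_m: float = WAYPOINT_SPACING_M

    def __post_init__(self) -> None:
        if len(self.transects) != len(self.quadrat_of):
            raise ValueError("quadrat_of must map every transect")

    @property
    def km_walked(self) -> float:
        """Total walked distance in km (sum of polyline lengths)."""
        return sum(self.transect_length_m(i) for i in range(len(self.transects))) / 1000.0

    def transect_length_m(self, i: int) -> float:
        wp = self.transects[i]
        return float(np.sum(np.hypot(*(np.diff(wp, axis=0).T))))

    def transect_lines(self) -> list[LineString]:
        return [LineString(wp) for wp in self.transects]

    def segment_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All transect segments as (starts, ends, cumulative-length) arrays.

        Used for arc-length-uniform sampling along the whole corridor.
        """
        starts, ends = [], []
        for wp in self.transects:
            starts.append(wp[:-1])
            ends.append(wp[1:])
        a = np.concatenate(starts) if starts else np.empty((0, 2))
        b = np.concatenate(ends) if ends else np.empty((0, 2))
        seglen = np.hypot(*(b - a).T)
        return a, b, np.concatenate([[0.0], np.cumsum(seglen)])

    def distance_to_transects(self, xy: np.ndarray) -> np.ndarray:
        """Euclidean distance from each point to the nearest transect."""
        import shapely

        pts = shapely.points(np.atleast_2d(xy))
        union = shapely.union_all([LineString(wp) for wp in self.transects])
        return shapely.distance(pts, union)


def _walk_transect(quad: tuple[float, float, float, float], length_m: float,
                   rng: np.random.Generator, step: float) -> np.ndarray:
    """Free-form walk inside a quadrat with exact 30-m steps.

    Headings evolve as a persistent random walk; a step that would exit the
    quadrat gets its heading resampled (the handler turns back inward).
    """
    x0, y0, x1, y1 = quad
    n_steps = max(int(round(length_m / step)), 1)
    margin = min(step, (x1 - x0) / 4, (y1 - y0) / 4)
    pos = np.array([rng.uniform(x0 + margin, x1 - margin),
                    rng.uniform(y0 + margin, y1 - margin)])
    heading = rng.uniform(0, 2 * np.pi)
    pts = np.empty((n_steps + 1, 2))
    pts[0] = pos
    for i in range(n_steps):
        h = heading + rng.normal(0.0, 0.35)
        for _ in range(200):
            cand = pos + step * np.array([np.cos(h), np.sin(h)])
            if x0 <= cand[0] <= x1 and y0 <= cand[1] <= y1:
                break
            h = rng.uniform(0, 2 * np.pi)
        else:  # pragma: no cover - quadrat >> step makes this unreachable
            cand = pos
        heading = h
        pos = cand
        pts[i + 1] = pos
    return pts


def generate_survey_design(
    landscape: LandscapeBundle,
    n_quadrats: int | None = None,
    quadrat_size_m: float | None = None,
    transects_per_quadrat: int = 6,
    mean_transect_m: float = 7_600.0,
    transect_sd_m: float | None = None,
    seed: int = 0,
) -> SurveyDesign:
    """Place non-overlapping quadrats and walk transects inside each.

    Defaults follow the study protocol: 5x5 km quadrats, each surveyed by
    several daily transects averaging 7.6 km, waypoints every 30 m.
    ``transect_sd_m`` defaults to 10% of the mean (0 gives exact lengths).
    """
    cfg: LandscapeConfig | None = landscape.config
    if n_quadrats is None:
        n_quadrats = cfg.n_quadrats if cfg is not None else 1
    if quadrat_size_m is None:
        quadrat_size_m = cfg.quadrat_size_m if cfg is not None else 5_000.0
    if transect_sd_m is None:
        transect_sd_m = 0.1 * mean_transect_m

    xmin, ymin, xmax, ymax = landscape.habitat.extent
    w, h = xmax - xmin, ymax - ymin
    if n_quadrats * quadrat_size_m ** 2 > w * h + 1e-6:
        raise ValueError("quadrats do not fit in the study area")
    nx = int(w // quadrat_size_m)
    ny = int(h // quadrat_size_m)
    if nx * ny < n_quadrats:
        raise ValueError(
            f"cannot place {n_quadrats} non-overlapping {quadrat_size_m / 1000:g} km "
            f"quadrats in a {w / 1000:g} x {h / 1000:g} km area")

    rng = stream(seed, "survey/quadrats")
    slots = rng.choice(nx * ny, size=n_quadrats, replace=False)
    quadrats = []
    for s in np.sort(slots):
        i, j = divmod(int(s), nx)
        qx0 = xmin + j * quadrat_size_m
        qy0 = ymin + i * quadrat_size_m
        quadrats.append((qx0, qy0, qx0 + quadrat_size_m, qy0 + quadrat_size_m))

    rng_t = stream(seed, "survey/transects")
    transects: list[np.ndarray] = []
    quadrat_of: list[int] = []
    for qi, quad in enumerate(quadrats):
        for _ in range(transects_per_quadrat):
            length = rng_t.normal(mean_transect_m, transect_sd_m) if transect_sd_m > 0 else mean_transect_m
            length = max(length, 10 * WAYPOINT_SPACING_M)
            transects.append(_walk_transect(quad, length, rng_t, WAYPOINT_SPACING_M))
            quadrat_of.append(qi)
    return SurveyDesign(quadrats=quadrats, transects=transects, quadrat_of=quadrat_of,
                        extent=(xmin, ymin, xmax, ymax))
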