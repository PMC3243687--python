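"""Use-available study design.

Availability is represented by random locations constrained to within 30 m
of the walked transects (20,000 by default), so used and available sites are
equally constrained to the sampled landscape. The availability sample is
shared across species by default; each species' dataset is its used rows
plus the common available rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._streams import stream
from .covariates import CovariateSpec, assemble_covariates
from .detections import DetectionSet
from .landscape import LandscapeBundle
from .survey import SurveyDesign

__all__ = ["sample_available", "build_design", "UseAvailableDataset"]

DEFAULT_N_AVAILABLE = 20_000
DEFAULT_MAX_OFFSET_M = 30.0


def sample_available(design: SurveyDesign, n: int = DEFAULT_N_AVAILABLE,
                     max_offset_m: float = DEFAULT_MAX_OFFSET_M, seed: int = 0,
                     stream_name: str = "design/available") -> np.ndarray:
    """Uniform sample of ``n`` points over the surveyed corridor.

    A location is picked uniformly by arc-length along the union of
    transects, then displaced perpendicular to its segment by a uniform
    offset in [-``max_offset_m``, ``max_offset_m``], which makes the sample
    uniform over the corridor band; draws falling outside the study extent
    are rejected and redrawn. Every output is within ``max_offset_m`` of
    some transect.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not design.transects:
        raise ValueError("design has no transects")
    a, b, cum = design.segment_arrays()
    total = cum[-1]
    if total <= 0:
        raise ValueError("transects have zero length")
    rng = stream(seed, stream_name)
    xmin, ymin, xmax, ymax = design.extent
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = int(1.2 * (n - got)) + 16
        s = rng.uniform(0.0, total, m)
        seg = np.searchsorted(cum, s, side="right") - 1
        seg = np.clip(seg, 0, len(a) - 1)
        seglen = cum[seg + 1] - cum[seg]
        frac = np.where(seglen > 0, (s - cum[seg]) / np.maximum(seglen, 1e-300), 0.0)
        dvec = b[seg] - a[seg]
        base = a[seg] + frac[:, None] * dvec
        norm = dvec / np.maximum(np.hypot(*dvec.T), 1e-300)[:, None]
        perp = np.column_stack([-norm[:, 1], norm[:, 0]])
        u = rng.uniform(-max_offset_m, max_offset_m, m)
        pts = base + u[:, None] * perp
        ok = (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax) & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
        pts = pts[ok]
        take = min(len(pts), n - got)
        out[got:got + take] = pts[:take]
        got += take
    return out


@dataclass
class UseAvailableDataset:
    """Used + available rows joined to their covariate table.

    ``rows`` has columns id, species, used, x_m, y_m; ``covariates`` is
    aligned row-for-row. Species-specific datasets (one species' used rows
    plus all available rows) come from :meth:`for_species`.
    """

    rows: pd.DataFrame
    covariates: pd.DataFrame
    unfit_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.covariates):
            raise ValueError("rows and covariates must align")
        self.rows = self.rows.reset_index(drop=True)
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n_used(self) -> int:
        return int(self.rows["used"].sum())

    @property
    def n_available(self) -> int:
        return int((1 - self.rows["used"]).sum())

    @property
    def species(self) -> list[str]:
        vals = self.rows.loc[self.rows["used"] == 1, "species"].unique()
        return sorted(v for v in vals if isinstance(v, str))

    def used_mask(self) -> np.ndarray:
        return self.rows["used"].to_numpy().astype(bool)

    def table(self) -> pd.DataFrame:
        return self.covariates

    def used_table(self) -> pd.DataFrame:
        return self.covariates[self.used_mask()]

    def available_table(self) -> pd.DataFrame:
        return self.covariates[~self.used_mask()]

    def xy(self) -> np.ndarray:
        return self.rows[["x_m", "y_m"]].to_numpy()

    def for_species(self, name: str) -> "UseAvailableDataset":
        mask = (self.rows["used"] == 0) | (self.rows["species"] == name)
        sub = UseAvailableDataset(self.rows[mask], self.covariates[mask])
        if sub.n_used == 0:
            sub.unfit_species = [name]
        return sub

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.rows, self.covariates], axis=1)


def build_design(used: DetectionSet, available: np.ndarray,
                 landscape: LandscapeBundle, specs: list[CovariateSpec]) -> UseAvailableDataset:
    """Assemble the use-available dataset with covariates.

    ``used`` should already be deduplicated. Covariates are computed in one
    pass over the distinct used+available points; a species with zero used
    rows is flagged unfit for fitting.
    """
    avail = np.atleast_2d(np.asarray(available, dtype=float))
    n_u, n_a = len(used), len(avail)
    rows = pd.DataFrame({
        "id": [f"u{i}" for i in range(n_u)] + [f"a{j}" for j in range(n_a)],
        "species": list(used.species) + [None] * n_a,
        "used": [1] * n_u + [0] * n_a,
        "x_m": np.concatenate([used.xy[:, 0], avail[:, 0]]) if n_u else avail[:, 0],
        "y_m": np.concatenate([used.xy[:, 1], avail[:, 1]]) if n_u else avail[:, 1],
    })
    pts = rows[["x_m", "y_m"]].to_numpy()
    cov = assemble_covariates(pts, landscape, specs)
    return UseAvailableDataset(rows=rows, covariates=cov)
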