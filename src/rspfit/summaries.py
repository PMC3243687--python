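"""Boxplot-style summaries of predicted selection probabilities.

Predictions from a final model are grouped by habitat class of the
containing cell, by binned focal proportion (e.g. natural or closed-canopy
habitat), or by park membership, and reduced to the five boxplot statistics:
10th percentile, lower quartile, median, upper quartile, 90th percentile.

Quantiles use linear interpolation of order statistics (position
1 + p(n-1)), the numpy default; the method is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import CLASS_NAMES, LandscapeBundle

__all__ = ["HABITAT_ABBREV", "GroupingSpec", "boxplot_stats", "summarize_selection",
           "plot_selection"]

#: Figure-style habitat abbreviations.
HABITAT_ABBREV = {
    "forest": "FO", "cerrado": "CE", "open cerrado": "OC", "grassland": "GR",
    "marsh": "MA", "pasture": "PA", "agriculture": "AG", "unknown": "UK",
}

STAT_COLS = ["n", "P10", "Q1", "median", "Q3", "P90"]


@dataclass(frozen=True)
class GroupingSpec:
    """How to group sites before summarizing.

    scheme: ``habitat-class`` | ``binned-proportion`` | ``park-membership``;
    ``covariate`` and ``bin_width`` apply to binned-proportion (bins are
    equal-width on [0, 1]).
    """

    scheme: str
    covariate: str | None = None
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        if self.scheme not in ("habitat-class", "binned-proportion", "park-membership"):
            raise ValueError(f"unknown grouping scheme {self.scheme!r}")
        if self.scheme == "binned-proportion":
            if not self.covariate:
                raise ValueError("binned-proportion grouping needs a covariate name")
            nb = 1.0 / self.bin_width
            if self.bin_width <= 0 or abs(nb - round(nb)) > 1e-9:
                raise ValueError("bin_width must evenly partition [0, 1]")


def boxplot_stats(values: np.ndarray, method: str = "linear") -> dict[str, float]:
    """The five boxplot statistics plus n for one group of predictions."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector has no boxplot statistics")
    p10, q1, med, q3, p90 = np.quantile(v, [0.10, 0.25, 0.50, 0.75, 0.90], method=method)
    return {"n": int(v.size), "P10": float(p10), "Q1": float(q1),
            "median": float(med), "Q3": float(q3), "P90": float(p90)}


def _group_labels(sites: np.ndarray, landscape: LandscapeBundle, grouping: GroupingSpec,
                  covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    if grouping.scheme == "habitat-class":
        codes = landscape.habitat.class_at(sites)
        labels = np.array([HABITAT_ABBREV[CLASS_NAMES[c]] for c in codes])
        order = [HABITAT_ABBREV[c] for c in CLASS_NAMES]
        return labels, order
    if grouping.scheme == "park-membership":
        from .covariates import park_covariates

        inside, _ = park_covariates(sites, landscape.park)
        labels = np.where(inside == 1, "inside", "outside")
        return labels, ["outside", "inside"]
    # binned proportion
    if covariates is None or grouping.covariate not in covariates.columns:
        raise ValueError(f"grouping covariate {grouping.covariate!r} absent from the table")
    v = covariates[grouping.covariate].to_numpy(dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError(f"{grouping.covariate!r} is not a proportion in [0, 1]")
    nb = int(round(1.0 / grouping.bin_width))
    idx = np.minimum((v / grouping.bin_width).astype(int), nb - 1)
    order = [f"[{i * grouping.bin_width:.2f},{(i + 1) * grouping.bin_width:.2f}"
             + ("]" if i == nb - 1 else ")") for i in range(nb)]
    labels = np.array([order[i] for i in idx])
    return labels, order


def summarize_selection(predictions: np.ndarray, sites: np.ndarray,
                        landscape: LandscapeBundle, grouping: GroupingSpec,
                        covariates: pd.DataFrame | None = None,
                        method: str = "linear") -> pd.DataFrame:
    """Per-group boxplot statistics of predicted selection probabilities.

    Returns a plot-ready frame with columns group, n, P10, Q1, median, Q3,
    P90; empty groups are omitted (noted nowhere else in the table). Group
    sizes partition the number of sites.
    """
    pred = np.asarray(predictions, dtype=float)
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    if pred.shape[0] != sites.shape[0]:
        raise ValueError("predictions must align with sites")
    labels, order = _group_labels(sites, landscape, grouping, covariates)
    rows = []
    for g in order:
        vals = pred[labels == g]
        if vals.size == 0:
            continue
        rows.append({"group": g, **boxplot_stats(vals, method=method)})
    return pd.DataFrame(rows, columns=["group"] + STAT_COLS)


def plot_selection(summary: pd.DataFrame, ax=None, title: str | None = None):
    """Render a summary frame as boxes (quartile box, median line, P10/P90
    whiskers), matching the descriptive-figure convention."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.6 * len(summary), 3.2))
    stats = [
        {"label": r["group"], "whislo": r["P10"], "q1": r["Q1"], "med": r["median"],
         "q3": r["Q3"], "whishi": r["P90"], "fliers": []}
        for _, r in summary.iterrows()
    ]
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel("predicted selection probability")
    if title:
        ax.set_title(title)
    return ax
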