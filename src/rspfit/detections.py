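"""Simulated scat/burrow detections and the field deduplication rule.

Used points are drawn from a known selection model by rejection sampling
within the surveyed corridor (the 30-m band around transects), which is also
the availability domain — used and available sites are equally constrained
to the sampled landscape. Detections carry contents/age attributes so the
field rule "scats <5 m apart with the same contents and age are one sample"
can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ._streams import stream
from .covariates import CovariateSpec, assemble_covariates
from .landscape import LandscapeBundle
from .model import ModelSpec, linear_predictor, selection_prob
from .survey import SurveyDesign

__all__ = ["TrueModel", "DetectionSet", "simulate_used_points", "deduplicate_detections"]

CONTENTS_LEVELS = ("vertebrate", "invertebrate", "fruit")
AGE_LEVELS = ("fresh", "intermediate", "old")


@dataclass(frozen=True)
class TrueModel:
    """A generating selection model: form + terms + coefficient vector.

    ``beta`` has one entry per term, preceded by an intercept for the
    logistic form.
    """

    spec: ModelSpec
    beta: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.beta) != self.spec.k:
            raise ValueError(f"beta needs {self.spec.k} entries for this spec")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")


@dataclass
class DetectionSet:
    """Detected samples: coordinates plus attributes used for dedup."""

    xy: np.ndarray          # (n, 2) meters
    species: np.ndarray     # str per point
    contents: np.ndarray
    age: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        n = self.xy.shape[0]
        for name in ("species", "contents", "age"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per point")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.xy.shape[0]

    def subset(self, idx) -> "DetectionSet":
        return DetectionSet(self.xy[idx], self.species[idx], self.contents[idx], self.age[idx])

    @staticmethod
    def concatenate(sets: list["DetectionSet"]) -> "DetectionSet":
        return DetectionSet(
            np.concatenate([s.xy for s in sets]),
            np.concatenate([s.species for s in sets]),
            np.concatenate([s.contents for s in sets]),
            np.concatenate([s.age for s in sets]),
        )


def simulate_used_points(
    landscape: LandscapeBundle,
    design: SurveyDesign,
    covspecs: list[CovariateSpec],
    model: TrueModel,
    n_target: int,
    seed: int,
    species: str = "species",
    acceptance_floor: float = 1e-4,
    batch_factor: int = 4,
    max_candidates_factor: int = 50,
) -> DetectionSet:
    """Draw exactly ``n_target`` used points from ``model`` by rejection.

    Candidates are uniform over the 30-m transect corridor; a candidate with
    linear predictor eta is accepted with probability pi(eta) / max pi, the
    maximum taken over the candidate pool (for the exponential form this
    approximates the supremum over the corridor). Contents and age attributes
    are assigned uniformly at random (they exist to exercise deduplication).
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    from .design import sample_available  # local import to avoid a cycle

    rng = stream(seed, "detections/attrs")
    accepted: list[np.ndarray] = []
    n_acc = 0
    n_seen = 0
    max_pi = 0.0
    batch = max(batch_factor * n_target, 500)
    sub = 0
    while n_acc < n_target:
        pts = sample_available(design, n=batch, max_offset_m=30.0,
                               seed=seed, stream_name=f"detections/candidates/{sub}")
        sub += 1
        if covspecs:
            table = assemble_covariates(pts, landscape, covspecs)
        else:
            import pandas as pd

            table = pd.DataFrame(index=range(len(pts)))
        eta = linear_predictor(model.spec, np.asarray(model.beta), table)
        pi = np.asarray(selection_prob(model.spec.form, eta), dtype=float)
        max_pi = max(max_pi, float(pi.max()))
        if max_pi <= 0:
            raise RuntimeError("selection probabilities are all zero; rescale beta")
        keep = rng.uniform(size=len(pts)) < pi / max_pi
        accepted.append(pts[keep])
        n_acc += int(keep.sum())
        n_seen += len(pts)
        rate = n_acc / n_seen
        if n_seen >= max_candidates_factor * n_target and rate < acceptance_floor:
            raise RuntimeError(
                f"acceptance rate {rate:.2e} below {acceptance_floor:g} after "
                f"{n_seen} candidates; rescale beta toward zero")
    xy = np.concatenate(accepted)[:n_target]
    return DetectionSet(
        xy=xy,
        species=np.full(n_target, species, dtype=object),
        contents=rng.choice(CONTENTS_LEVELS, size=n_target),
        age=rng.choice(AGE_LEVELS, size=n_target),
    )


def deduplicate_detections(dets: DetectionSet, radius_m: float = 5.0,
                           keys: tuple[str, ...] = ("contents", "age")) -> DetectionSet:
    """Merge same-sample detections: single-linkage clusters of same-species
    points with pairwise links < ``radius_m`` and equal key attributes
    collapse to their earliest-indexed member.

    Single linkage is the closure of the pairwise "<5 m apart, same contents
    and age" field rule: chains a-b-c with each link under the radius merge
    even if a and c are farther apart. Idempotent.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    n = len(dets)
    if n == 0:
        return dets.subset(np.array([], dtype=int))
    group_keys = [tuple(getattr(dets, k)[i] for k in ("species",) + tuple(keys)) for i in range(n)]
    keep = np.ones(n, dtype=bool)
    groups: dict[tuple, list[int]] = {}
    for i, gk in enumerate(group_keys):
        groups.setdefault(gk, []).append(i)
    for idx in groups.values():
        if len(idx) < 2:
            continue
        idx_arr = np.array(idx)
        tree = cKDTree(dets.xy[idx_arr])
        pairs = tree.query_pairs(radius_m, output_type="ndarray")
        if len(pairs):  # query_pairs uses <=; the field rule is strict <
            d = np.hypot(*(dets.xy[idx_arr[pairs[:, 0]]] - dets.xy[idx_arr[pairs[:, 1]]]).T)
            pairs = pairs[d < radius_m]
        if not len(pairs):
            continue
        from scipy.sparse import coo_matrix

        m = len(idx_arr)
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m))
        _, labels = connected_components(adj, directed=False)
        for lab in np.unique(labels):
            members = idx_arr[labels == lab]
            if len(members) > 1:
                keep[members[members != members.min()]] = False
    return dets.subset(np.nonzero(keep)[0])
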