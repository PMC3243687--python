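"""Two-step final-model selection: BIC ranking plus an anomaly screen.

Candidate model forms and covariate sets are compared with the Bayesian
Information Criterion; the selected model is then checked for pathological
predicted values (maximum selection probability near zero, or all predicted
probabilities confined to a narrow band). The final model is the best-BIC
candidate that passes the screen.

BIC uses n = n_used by default: the availability points are a Monte-Carlo
integration device, not observations (``bic_n="all"`` is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import UseAvailableDataset
from .model import ModelSpec, ResourceSelectionModel, RSPFResults

__all__ = [
    "CandidateSet",
    "SelectionReport",
    "bic",
    "compare_candidates",
    "anomaly_screen",
    "select_final",
]


def bic(fit: RSPFResults, n: str = "used") -> float:
    """BIC = -2 l(beta_hat) + k log n, k counting the intercept when present."""
    if not fit.converged:
        raise ValueError("BIC undefined for an unconverged fit")
    return fit.bic(n=n)


@dataclass
class CandidateSet:
    """Labelled candidate model specs sharing one dataset."""

    candidates: list[tuple[str, ModelSpec]]
    data: UseAvailableDataset

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.candidates]
        if len(set(labels)) != len(labels):
            raise ValueError("candidate labels must be unique")
        if len(self.candidates) < 2:
            raise ValueError("need at least two candidates for a comparison")


@dataclass
class SelectionReport:
    """Per-candidate BIC table, anomaly flags, and the final choice."""

    table: pd.DataFrame                  # label, form, k, loglik, BIC, dBIC, converged, flags
    fits: dict[str, RSPFResults]
    final_label: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def final(self) -> RSPFResults | None:
        return self.fits.get(self.final_label) if self.final_label else None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "final": self.final_label,
            "notes": list(self.notes),
            "candidates": self.table.to_dict(orient="records"),
        }


def _fit_all(cands: CandidateSet, bic_n: str, fit_options: dict) -> tuple[dict, list[str]]:
    fits: dict[str, RSPFResults] = {}
    notes: list[str] = []
    for label, spec in cands.candidates:
        fit = ResourceSelectionModel(cands.data, spec).fit(**fit_options)
        fits[label] = fit
        if not fit.converged:
            notes.append(f"{label}: excluded from BIC comparison (not converged)")
    return fits, notes


def compare_candidates(cands: CandidateSet, bic_n: str = "used",
                       fit_options: dict | None = None) -> SelectionReport:
    """Fit every candidate and report BIC and dBIC, sorted ascending."""
    fits, notes = _fit_all(cands, bic_n, fit_options or {})
    rows = []
    for label, spec in cands.candidates:
        fit = fits[label]
        rows.append({
            "label": label, "form": spec.form, "k": spec.k,
            "loglik": fit.llf if fit.converged else np.nan,
            "BIC": fit.bic(n=bic_n) if fit.converged else np.nan,
            "converged": fit.converged,
        })
    df = pd.DataFrame(rows)
    if df["BIC"].notna().sum() == 0:
        raise RuntimeError("no candidate converged; cannot compare")
    df["dBIC"] = df["BIC"] - df["BIC"].min()
    df = df.sort_values("dBIC", na_position="last", kind="stable").reset_index(drop=True)
    return SelectionReport(table=df, fits=fits, notes=notes)


def anomaly_screen(predictions: np.ndarray, max_near_zero: float = 0.01,
                   confined_width: float = 0.05,
                   percentiles: tuple[float, float] = (5.0, 95.0)) -> set[str]:
    """Flags for pathological predicted selection probabilities.

    ``max_near_zero``: max(pi) below the threshold; ``confined``: the P95-P5
    spread of pi below ``confined_width``. Applies to logistic-form
    predictions (probabilities); exponential weights are not screened.
    """
    pi = np.asarray(predictions, dtype=float)
    flags: set[str] = set()
    if pi.size == 0:
        return flags
    if np.nanmax(pi) < max_near_zero:
        flags.add("max_near_zero")
    lo, hi = np.nanpercentile(pi, percentiles)
    if hi - lo < confined_width:
        flags.add("confined")
    return flags


def select_final(cands: CandidateSet, bic_n: str = "used",
                 fit_options: dict | None = None,
                 screen_options: dict | None = None) -> SelectionReport:
    """Step 1: rank candidates by BIC. Step 2: walk the ranking and pick the
    first candidate whose predictions pass the anomaly screen; if none does,
    return the BIC-best with its flags attached."""
    report = compare_candidates(cands, bic_n=bic_n, fit_options=fit_options)
    screen_options = screen_options or {}
    flag_col: list[str] = []
    chosen = None
    for _, row in report.table.iterrows():
        label = row["label"]
        fit = report.fits[label]
        if not fit.converged:
            flag_col.append("unconverged")
            continue
        if fit.spec.form == "logistic":
            flags = anomaly_screen(fit.predict(), **screen_options)
        else:
            flags = set()  # relative weights: probability screens do not apply
        flag_col.append(",".join(sorted(flags)))
        if not flags and chosen is None:
            chosen = label
    report.table["flags"] = flag_col
    if chosen is None:
        converged = report.table[report.table["converged"]]
        chosen = converged.iloc[0]["label"]
        report.notes.append("all candidates anomalous; returning BIC-best with flags")
    report.final_label = chosen
    return report
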