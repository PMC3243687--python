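"""End-to-end orchestration: simulate -> design -> covariates -> fit ->
select -> summarize, from one YAML config, with persisted intermediates and
a reproducibility manifest.

Each stage writes its products under the run directory and can be re-run
from the persisted outputs of earlier stages, so the pipeline is resumable
stage by stage and byte-reproducible given the same config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .covariates import CovariateSpec, table1_specs
from .design import UseAvailableDataset, build_design, sample_available
from .detections import DetectionSet, TrueModel, deduplicate_detections, simulate_used_points
from .landscape import LandscapeConfig, generate_landscape
from .model import ModelSpec, linear_predictor, selection_prob
from .modelselect import CandidateSet, select_final
from .summaries import GroupingSpec, summarize_selection
from .survey import generate_survey_design

__all__ = ["ConfigError", "load_config", "validate_config", "Pipeline", "run_pipeline"]

STAGES = ("simulate", "design", "covariates", "fit", "select", "summarize")

_SCHEME_ALIASES = {
    "habitat-class": GroupingSpec("habitat-class"),
    "park-membership": GroupingSpec("park-membership"),
    "natural": GroupingSpec("binned-proportion", covariate="natural"),
    "closed": GroupingSpec("binned-proportion", covariate="closed"),
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _covariate_specs(config: dict) -> list[CovariateSpec]:
    decl = config.get("covariates", "table1")
    window_mode = config.get("window_mode", "area")
    all_specs = table1_specs(window_mode=window_mode)
    if decl == "table1":
        return all_specs
    by_name = {s.name: s for s in all_specs}
    missing = [n for n in decl if n not in by_name]
    if missing:
        raise ConfigError(f"undeclared covariates (not in the standard suite): {missing}")
    return [by_name[n] for n in decl]


def validate_config(config: dict) -> None:
    """Fail before compute: seed present, species well-formed, every model
    term referencing a declared covariate."""
    if "seed" not in config:
        raise ConfigError("config must declare a seed")
    specs = _covariate_specs(config)
    declared = {s.name for s in specs}
    species = config.get("species", [])
    if not species:
        raise ConfigError("config must declare at least one species")
    for sp in species:
        if "name" not in sp:
            raise ConfigError("every species needs a name")
        blocks = [("model", [sp["model"]])] if "model" in sp else []
        blocks.append(("candidates", sp.get("candidates", [])))
        for what, models in blocks:
            for m in models:
                spec = ModelSpec(m["form"], m["terms"])
                bad = spec.covariate_names() - declared
                if bad:
                    raise ConfigError(
                        f"species {sp['name']!r} {what} references undeclared "
                        f"covariates: {sorted(bad)}")
        if "model" in sp and len(sp["model"].get("beta", [])) != ModelSpec(
                sp["model"]["form"], sp["model"]["terms"]).k:
            raise ConfigError(f"species {sp['name']!r}: beta length does not match terms")


class Pipeline:
    """Stage-by-stage runner over one config and output directory.

    Stages executed out of order load their prerequisites from the run
    directory, so re-running from any persisted intermediate reproduces the
    downstream outputs.
    """

    def __init__(self, config: dict, outdir=None, seed: int | None = None) -> None:
        validate_config(config)
        self.config = dict(config)
        if seed is not None:
            self.config["seed"] = int(seed)
        self.seed = int(self.config["seed"])
        self.outdir = Path(outdir if outdir is not None else self.config.get("outdir", "run"))
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.covspecs = _covariate_specs(self.config)
        self._landscape = None
        self._design = None
        self._detections: dict[str, DetectionSet] | None = None
        self._available: np.ndarray | None = None
        self._dataset: UseAvailableDataset | None = None
        self._fits: dict[str, dict] = {}
        self._selection: dict[str, dict] = {}

    # -- lazy prerequisites (from memory, else from disk) -----------------
    @property
    def landscape(self):
        if self._landscape is None:
            self._landscape = rio.load_landscape(self.outdir / "landscape")
        return self._landscape

    @property
    def design(self):
        if self._design is None:
            self._design = rio.load_design(self.outdir / "survey")
        return self._design

    @property
    def detections(self) -> dict[str, DetectionSet]:
        if self._detections is None:
            df = pd.read_csv(self.outdir / "detections.csv")
            self._detections = {}
            for name, g in df.groupby("species", sort=True):
                self._detections[name] = DetectionSet(
                    g[["x_m", "y_m"]].to_numpy(), g["species"].to_numpy(object),
                    g["contents"].to_numpy(object), g["age"].to_numpy(object))
        return self._detections

    @property
    def available(self) -> np.ndarray:
        if self._available is None:
            df = pd.read_csv(self.outdir / "available.csv")
            self._available = df[["x_m", "y_m"]].to_numpy()
        return self._available

    @property
    def dataset(self) -> UseAvailableDataset:
        if self._dataset is None:
            df = pd.read_csv(self.outdir / "dataset.csv")
            row_cols = ["id", "species", "used", "x_m", "y_m"]
            self._dataset = UseAvailableDataset(df[row_cols], df.drop(columns=row_cols))
        return self._dataset

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> None:
        """Landscape, survey design, and deduplicated detections per species."""
        lcfg = LandscapeConfig(**{**self.config.get("landscape", {}), "seed": self.seed})
        self._landscape = generate_landscape(lcfg)
        rio.save_landscape(self.outdir / "landscape", self._landscape)
        self._design = generate_survey_design(self._landscape, seed=self.seed,
                                              **self.config.get("survey", {}))
        rio.save_design(self.outdir / "survey", self._design)
        dets = {}
        for i, sp in enumerate(self.config["species"]):
            model = TrueModel(ModelSpec(sp["model"]["form"], sp["model"]["terms"]),
                              tuple(sp["model"]["beta"]))
            needed = [s for s in self.covspecs
                      if s.name in model.spec.covariate_names()]
            raw = simulate_used_points(self._landscape, self._design, needed, model,
                                       n_target=int(sp["n_used"]),
                                       seed=self.seed + 101 * (i + 1),
                                       species=sp["name"])
            dets[sp["name"]] = deduplicate_detections(raw)
        self._detections = dets
        allsets = DetectionSet.concatenate(list(dets.values()))
        rio.write_points_csv(self.outdir / "detections.csv", allsets.xy,
                             species=allsets.species, contents=allsets.contents,
                             age=allsets.age)

    def stage_design(self) -> None:
        """The shared availability sample over the surveyed corridor."""
        n = int(self.config.get("n_available", 20_000))
        self._available = sample_available(self.design, n=n, seed=self.seed)
        rio.write_points_csv(self.outdir / "available.csv", self._available)

    def stage_covariates(self) -> None:
        """Used + available rows joined to the declared covariate table."""
        allsets = DetectionSet.concatenate(
            [self.detections[k] for k in sorted(self.detections)])
        self._dataset = build_design(allsets, self.available, self.landscape, self.covspecs)
        self._dataset.to_frame().to_csv(self.outdir / "dataset.csv", index=False)
        meta = {s.name: {"kind": s.kind, "params": {k: list(v) if isinstance(v, tuple) else v
                                                    for k, v in s.params.items()}}
                for s in self.covspecs}
        with open(self.outdir / "covariates_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    def _candidates_for(self, sp: dict) -> list[tuple[str, ModelSpec]]:
        cands = sp.get("candidates") or []
        if len(cands) < 2 and "model" in sp:
            # degenerate ladders get the generating structure as a second rung
            cands = cands + [{"label": "generating",
                              "form": sp["model"]["form"], "terms": sp["model"]["terms"]}]
        return [(c.get("label", f"cand{i}"), ModelSpec(c["form"], c["terms"]))
                for i, c in enumerate(cands)]

    def stage_fit(self) -> None:
        """Fit every candidate per species; persist the fit summaries."""
        fitdir = self.outdir / "fits"
        fitdir.mkdir(exist_ok=True)
        for sp in self.config["species"]:
            sub = self.dataset.for_species(sp["name"])
            if sub.unfit_species:
                self._fits[sp["name"]] = {"unfit": True}
                continue
            out = {}
            from .model import ResourceSelectionModel

            for label, spec in self._candidates_for(sp):
                fit = ResourceSelectionModel(sub, spec).fit(seed=self.seed)
                out[label] = fit.to_dict()
            self._fits[sp["name"]] = out
            with open(fitdir / f"{sp['name']}.json", "w") as fh:
                json.dump(out, fh, indent=2)

    def stage_select(self) -> None:
        """BIC + anomaly-screen model choice per species."""
        bic_n = self.config.get("selection", {}).get("bic_n", "used")
        for sp in self.config["species"]:
            sub = self.dataset.for_species(sp["name"])
            if sub.unfit_species:
                continue
            cands = CandidateSet(self._candidates_for(sp), sub)
            report = select_final(cands, bic_n=bic_n,
                                  fit_options={"seed": self.seed})
            report.to_tsv(self.outdir / f"selection_{sp['name']}.tsv")
            with open(self.outdir / f"selection_{sp['name']}.json", "w") as fh:
                payload = report.to_dict()
                payload["final_fit"] = report.final.to_dict()
                json.dump(payload, fh, indent=2)
            self._selection[sp["name"]] = {"report": report}

    def stage_summarize(self) -> None:
        """Boxplot statistics of the final model's predictions, per scheme."""
        schemes = self.config.get("summaries", {}).get(
            "schemes", ["habitat-class", "natural", "closed", "park-membership"])
        which = self.config.get("summaries", {}).get("sites", "used")
        for sp in self.config["species"]:
            sel = self._selection.get(sp["name"])
            if sel is None:
                self.stage_select()
                sel = self._selection.get(sp["name"])
                if sel is None:
                    continue
            fit = sel["report"].final
            sub = self.dataset.for_species(sp["name"])
            if which == "used":
                mask = sub.used_mask()
            else:
                mask = np.ones(len(sub.rows), dtype=bool)
            sites = sub.xy()[mask]
            preds = fit.predict(sub.table()[mask])
            for scheme in schemes:
                gspec = _SCHEME_ALIASES.get(scheme)
                if gspec is None:
                    raise ConfigError(f"unknown summary scheme {scheme!r}")
                summ = summarize_selection(preds, sites, self.landscape, gspec,
                                           covariates=sub.table()[mask])
                summ.to_csv(self.outdir / f"summary_{sp['name']}_{scheme}.tsv",
                            sep="\t", index=False)

    def run(self, stages=STAGES) -> dict:
        for name in stages:
            try:
                getattr(self, f"stage_{name}")()
            except ConfigError:
                raise
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        rio.write_manifest(self.outdir, self.config, self.seed,
                           extra={"stages": list(stages)})
        return {
            "outdir": str(self.outdir),
            "landscape": self._landscape,
            "design": self._design,
            "dataset": self._dataset,
            "fits": self._fits,
            "selection": self._selection,
        }


def run_pipeline(config: dict | str | Path, outdir=None, seed: int | None = None) -> dict:
    """Run every stage from a config dict or YAML path."""
    if not isinstance(config, dict):
        config = load_config(config)
    return Pipeline(config, outdir=outdir, seed=seed).run()


def predictions_from_saved(selection_json: str | Path, table: pd.DataFrame) -> np.ndarray:
    """Re-evaluate a persisted final model on a covariate table."""
    with open(selection_json) as fh:
        payload = json.load(fh)
    fit = payload["final_fit"]
    spec = ModelSpec(fit["form"], fit["terms"])
    beta = np.array([fit["params"][n] for n in spec.param_names])
    return np.asarray(selection_prob(spec.form, linear_predictor(spec, beta, table)))
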