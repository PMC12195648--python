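"""End-to-end orchestration: molecules + activities -> reports.

One :func:`run` call covers the whole modeling workflow — field assembly,
column filtering, PLS model search over field combinations, external
validation, Y-randomization, applicability domain, contour export and
(optionally) druglikeness rules — writing every artifact plus the fully
serialized configuration into a run directory so any number in any report
is reproducible from the archive.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import domain, molecules, rules, synth, validation
from .fields import (FieldConfig, assemble_fields, build_lattice, column_filter,
                     write_dx)
from .pls import contour_grid, contours_to_pdb, model_search, search_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; defaults are the standard field settings
    (2 A grid, 30 kcal/mol cutoff, alpha 0.3, column filter 2.0)."""

    sdf_path: str | None = None
    activity_path: str | None = None
    descriptor_path: str | None = None    # druglikeness table, optional
    synthetic: bool = False               # generate inputs instead of reading
    synthetic_spec: dict = field(default_factory=dict)
    method: str = "comfa"
    charge_policy: str = "from-file"
    lattice_spacing: float = 2.0
    lattice_margin: float = 4.0
    energy_cutoff: float = 30.0
    attenuation_alpha: float = 0.3
    column_filter_sigma: float = 2.0
    fields: tuple[str, ...] = ("S", "E")
    max_components: int = 6
    split_policy: str = "column"          # "column" | "stratified"
    split_seed: int = 0
    test_fraction: float = 0.2
    randomization_iterations: int = 50
    randomization_seed: int = 0
    contour_upper_pct: float = 80.0
    contour_lower_pct: float = 20.0

    def field_config(self) -> FieldConfig:
        return FieldConfig(energy_cutoff=self.energy_cutoff,
                           attenuation_alpha=self.attenuation_alpha,
                           column_filter_sigma=self.column_filter_sigma,
                           fields_enabled=tuple(self.fields))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fields" in data:
            data["fields"] = tuple(data["fields"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["fields"] = list(data["fields"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class _EventLog:
    def __init__(self, path):
        self.fh = open(path, "w")

    def emit(self, stage: str, **payload):
        rec = {"t": time.time(), "stage": stage, **payload}
        self.fh.write(json.dumps(rec) + "\n")
        self.fh.flush()
        logger.info("%s %s", stage, payload)

    def close(self):
        self.fh.close()


def run(config: RunConfig, outdir) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _EventLog(out / "run.log.jsonl")
    config.to_yaml(out / "config.yaml")
    try:
        # ---- inputs -------------------------------------------------------
        if config.synthetic:
            spec = synth.SyntheticSpec(**config.synthetic_spec)
            mols, acts, truth = synth.generate(spec)
            molecules.write_aligned_sdf(mols, out / "molecules.sdf")
            molecules.write_activity_csv(acts, out / "activities.csv")
            log.emit("generate", n=len(mols), seed=spec.seed)
        else:
            if not (config.sdf_path and config.activity_path):
                raise ValueError("sdf_path and activity_path required "
                                 "unless synthetic=true")
            mols = molecules.read_aligned_sdf(config.sdf_path,
                                              charge_policy=config.charge_policy)
            acts = molecules.read_activity_csv(config.activity_path)
            log.emit("load", n=len(mols))
        by_id = {a.compound_id: a for a in acts}
        missing = [m.id for m in mols if m.id not in by_id]
        if missing:
            raise ValueError(f"no activity for compounds: {missing[:5]}")
        y = np.array([by_id[m.id].activity for m in mols])
        if config.split_policy == "stratified" or all(
                by_id[m.id].subset == "train" for m in mols):
            test_mask = validation.stratified_split(
                y, config.test_fraction, seed=config.split_seed)
        else:
            test_mask = np.array([by_id[m.id].subset == "test" for m in mols])
        train_mask = ~test_mask

        # ---- fields -------------------------------------------------------
        cfg = config.field_config()
        lattice = build_lattice(mols, config.lattice_spacing, config.lattice_margin)
        fm_all = assemble_fields(mols, lattice, cfg, method=config.method)
        fm_train = column_filter(fm_all.subset_rows(train_mask),
                                 cfg.column_filter_sigma)
        log.emit("fields", lattice_points=lattice.n_points,
                 columns=int(fm_train.values.shape[1]),
                 retained=int(fm_train.column_mask.sum()))

        # ---- model search -------------------------------------------------
        results = model_search(fm_train, y[train_mask],
                               max_n=config.max_components)
        table = search_table(results)
        table.to_csv(out / "model_search.csv", index=False)
        best = results[0]
        fit = best.fit
        log.emit("search", best=best.label, q2=fit.q2, N=fit.n_components,
                 r2_ncv=fit.r2_ncv, see=fit.see)

        # ---- predictions & external validation ----------------------------
        pred_all = fit.predict_fieldmatrix(fm_all)
        subsets = np.where(test_mask, "test", "train")
        preds = validation.prediction_table(
            [m.id for m in mols], y, pred_all, subsets)
        preds.to_csv(out / "predictions.csv", index=False)

        report = {"best_model": best.label, "q2": fit.q2,
                  "n_components": fit.n_components, "r2_ncv": fit.r2_ncv,
                  "see": fit.see, "field_fractions": fit.field_fractions}
        if test_mask.sum() >= 3:
            ev = validation.external_metrics(y[test_mask], pred_all[test_mask])
            flags = validation.gt_conditions(ev, fit.q2)
            report["external"] = {
                "r2_test": ev.r2_test, "r2_0": ev.r2_0,
                "r2_0_prime": ev.r2_0_prime, "k": ev.k, "k_prime": ev.k_prime,
                "rm2": ev.rm2, "conditions": flags}
            log.emit("external_validation", r2_test=ev.r2_test,
                     verdict=flags["verdict"])
        else:
            warnings.warn("test subset has fewer than 3 compounds; "
                          "external validation skipped")
            report["external"] = None
            log.emit("external_validation", skipped=True)

        # ---- Y-randomization ---------------------------------------------
        rand = validation.y_randomization(
            fm_train, y[train_mask],
            n_iterations=config.randomization_iterations,
            n_components=fit.n_components, seed=config.randomization_seed)
        report["y_randomization"] = {
            "n_iterations": rand.n_iterations, "passed": rand.passed,
            "fraction_q2_below_0.5": rand.fraction_q2_below_05,
            "max_q2": float(rand.q2_values.max()),
            "max_r2_ncv": float(rand.r2_ncv_values.max())}
        log.emit("y_randomization", passed=rand.passed)

        # ---- applicability domain (latent-score space) --------------------
        train_scores = fit.x_scores()
        all_scores = fit.x_scores(fit.modeling_matrix_for(fm_all))
        ad = domain.ad_report(train_scores, all_scores, [m.id for m in mols])
        ad.to_csv(out / "ad_report.csv", index=False)
        log.emit("applicability_domain",
                 outside=int((ad["verdict"] == "outside").sum()))

        # ---- contours -----------------------------------------------------
        contours = contour_grid(fit, config.contour_upper_pct,
                                config.contour_lower_pct)
        for letter, cs in contours.items():
            grid = np.zeros(lattice.n_points)
            grid[cs.point_indices] = cs.product
            write_dx(out / f"contour_{letter}.dx", lattice, grid,
                     comment=f"coef*sd product, field {letter}")
        contours_to_pdb(contours, lattice, out / "contours.pdb")
        log.emit("contours", fields=sorted(contours))

        # ---- druglikeness -------------------------------------------------
        if config.descriptor_path:
            recs = rules.read_descriptor_csv(config.descriptor_path)
            rules.rule_report(recs).to_csv(out / "druglikeness.csv", index=False)
            log.emit("druglikeness", n=len(recs))

        with open(out / "validation.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        joblib.dump({"fit": fit, "config": config, "lattice": lattice},
                    out / "model.joblib")
        log.emit("done")
        return out
    except Exception as exc:  # stage-named diagnostics, then re-raise
        log.emit("error", message=str(exc))
        raise
    finally:
        log.close()


def predict(artifact_path, sdf_path, charge_policy: str = "from-file",
            allow_outside_lattice: bool = False) -> pd.DataFrame:
    """Predict new aligned compounds with a stored model.

    Compounds must sit inside the training lattice (the model has no
    information beyond it); ``allow_outside_lattice`` overrides the refusal.
    AD verdicts are computed in the model's latent-score space.
    """
    art = joblib.load(artifact_path)
    fit, config, lattice = art["fit"], art["config"], art["lattice"]
    mols = molecules.read_aligned_sdf(sdf_path, charge_policy=charge_policy)
    for m in mols:
        if not lattice.contains(m.coords) and not allow_outside_lattice:
            raise ValueError(f"molecule {m.id!r} lies outside the training "
                             "lattice (use allow_outside_lattice to override)")
    cfg = config.field_config()
    fm_new = assemble_fields(mols, lattice, cfg, method=config.method)
    yhat = fit.predict_fieldmatrix(fm_new)
    new_scores = fit.x_scores(fit.modeling_matrix_for(fm_new))
    ad = domain.ad_report(fit.x_scores(), new_scores, [m.id for m in mols])
    ad.insert(1, "predicted_pic50", yhat)
    return ad
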