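"""End-to-end orchestration: data -> preprocess -> selection -> models
-> clinical-utility evaluation -> reports.

For each endpoint the pipeline selects a metabolite panel on the
training cohort only, fits four predictor sets (5 clinical factors;
marker panel; panel + PSA; combined panel + clinical factors), and
evaluates ROC/AUC with DeLong comparisons, Youden and fixed-sensitivity
operating points with reweighted biopsy avoidance, and decision curves
on both cohorts.  Validation subjects never enter selection or fitting;
a leakage guard aborts if a validation id appears in any selection fold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .dca import DcaCurve, dca_curves, default_grid
from .logistic import ENDPOINTS, LogisticFit, build_endpoint_labels, fit_logistic, predict_probability
from .preprocess import PreprocessConfig, preprocess_pipeline
from .selection import SelectionConfig, select_markers
from .strata import CLINICAL_FACTORS, ENROLLMENT_WEIGHTS, analysis_stratum
from .synthetic import CohortConfig, PeakTable, generate_cohort, read_fixture

__all__ = [
    "PipelineConfig",
    "UtilityReport",
    "PREDICTOR_SETS",
    "run_pipeline",
    "load_inputs",
    "write_report",
]

logger = logging.getLogger(__name__)

PREDICTOR_SETS = ("clinical", "panel", "panel_psa", "combined")


def _plain(obj):
    """Recursively coerce numpy scalars and tuples for YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


@dataclass
class PipelineConfig:
    """Full configuration of one analysis run.

    Exactly one input source: either the three CSV paths or a synthetic
    cohort configuration.
    """

    subjects_csv: str | None = None
    peaks_csv: str | None = None
    creatinine_csv: str | None = None
    synthetic: CohortConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    endpoints: tuple = ("I", "II", "III", "GS")
    sensitivity_targets: tuple = (0.90, 0.95)
    weights: dict = field(default_factory=lambda: dict(ENROLLMENT_WEIGHTS))
    dca_grid: tuple | None = None
    outdir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        has_files = self.subjects_csv is not None
        if has_files and (self.peaks_csv is None or self.creatinine_csv is None):
            raise ValueError("file input needs subjects_csv, peaks_csv and creatinine_csv")
        if has_files == (self.synthetic is not None):
            raise ValueError("exactly one input source: CSV paths or a synthetic config")
        if not self.endpoints:
            raise ValueError("endpoints must be non-empty")
        unknown = [e for e in self.endpoints if e not in ENDPOINTS]
        if unknown:
            raise ValueError(f"unknown endpoints: {unknown}")
        for t in self.sensitivity_targets:
            if not 0.0 < t <= 1.0:
                raise ValueError(f"sensitivity target out of (0, 1]: {t}")
        self.preprocess.validate()
        self.selection.validate()

    # ---- YAML round trip -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if kw.get("synthetic") is not None:
            kw["synthetic"] = CohortConfig(**kw["synthetic"])
        if "preprocess" in kw:
            kw["preprocess"] = PreprocessConfig(**kw["preprocess"])
        if "selection" in kw:
            kw["selection"] = SelectionConfig(**kw["selection"])
        for key in ("endpoints", "sensitivity_targets", "dca_grid"):
            if kw.get(key) is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))


@dataclass
class UtilityReport:
    """Machine-readable results of one pipeline run."""

    config: dict
    panels: dict  # endpoint -> ranking/panel info
    models: dict  # endpoint -> predictor set -> fitted coefficients
    metrics: dict  # endpoint -> cohort -> predictor set -> AUC/operating points
    comparisons: dict  # endpoint -> cohort -> pair -> DeLong result
    dca: dict  # endpoint -> cohort -> predictor set -> curve dict
    selection: dict  # endpoint -> per-fold-model summary
    provenance: dict

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict) -> "UtilityReport":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})


def load_inputs(subjects_csv, peaks_csv, creatinine_csv) -> tuple[pd.DataFrame, PeakTable]:
    """Read and cross-validate the three CSV inputs."""
    subjects = pd.read_csv(subjects_csv, dtype={"risk_group": str, "cohort": str})
    values = pd.read_csv(peaks_csv, index_col=0)
    creat = pd.read_csv(creatinine_csv, index_col=0).iloc[:, 0]
    for col in ("age", "psa_ng_ml", "family_history", "prior_negative_biopsy", "abnormal_dre"):
        if col not in subjects.columns:
            raise ValueError(f"subjects.csv missing column {col!r}")
        if not np.issubdtype(subjects[col].dtype, np.number):
            raise ValueError(f"subjects.csv column {col!r} is not numeric")
    bad = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
    if bad:
        raise ValueError(f"peaks.csv has non-numeric feature columns: {bad}")
    orphan_subjects = sorted(set(subjects["id"]) - set(values.index))
    orphan_samples = sorted(set(values.index) - set(subjects["id"]))
    if orphan_subjects or orphan_samples:
        raise ValueError(
            f"id mismatch: subjects without peaks {orphan_subjects}; "
            f"peak samples without subjects {orphan_samples}"
        )
    creat = creat.reindex(values.index)
    if creat.isna().any():
        bad = list(values.index[creat.isna()])
        raise ValueError(f"samples without creatinine: {bad}")
    peaks = PeakTable(values=values, creatinine=creat)
    peaks.validate()
    logger.info("loaded %d subjects, %d features", len(subjects), values.shape[1])
    return subjects, peaks


def _predictor_frame(nm_data: pd.DataFrame, subjects: pd.DataFrame, panel, pset: str) -> pd.DataFrame:
    clin = subjects.set_index("id")[list(CLINICAL_FACTORS)].astype(float)
    clin = clin.reindex(nm_data.index)
    if pset == "clinical":
        return clin
    panel_df = nm_data[list(panel)]
    if pset == "panel":
        return panel_df
    if pset == "panel_psa":
        return panel_df.join(clin[["psa_ng_ml"]])
    if pset == "combined":
        return panel_df.join(clin)
    raise ValueError(f"unknown predictor set {pset!r}")


def _curve_dict(c: DcaCurve) -> dict:
    return {
        "grid": [float(x) for x in c.grid],
        "nb_model": [float(x) for x in c.nb_model],
        "nb_all": [float(x) for x in c.nb_all],
        "nb_none": [float(x) for x in c.nb_none],
        "avoided_per_1000": [float(x) for x in c.avoided_per_1000()],
        "prevalence": c.prevalence,
        "n": c.n,
    }


def run_pipeline(config: PipelineConfig) -> UtilityReport:
    """Execute the full analysis; see the module docstring."""
    config.validate()
    if config.synthetic is not None:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        logger.info("generating synthetic cohort (seed=%d)", config.seed)
        subjects, peaks = generate_cohort(synth)
    else:
        subjects, peaks = load_inputs(
            config.subjects_csv, config.peaks_csv, config.creatinine_csv
        )

    nm = preprocess_pipeline(peaks, subjects, config.preprocess)
    logger.info(
        "preprocess: %d of %d features retained",
        nm.data.shape[1], peaks.values.shape[1],
    )

    subjects = subjects.reset_index(drop=True)
    train_mask = subjects["cohort"] == "training"
    train_ids = subjects.loc[train_mask, "id"].to_numpy()
    valid_ids = subjects.loc[~train_mask, "id"].to_numpy()
    valid_id_set = set(valid_ids)
    strata_all = pd.Series(
        [analysis_stratum(g) for g in subjects["risk_group"]],
        index=subjects["id"].to_numpy(),
    )

    seed_seq = np.random.SeedSequence(config.seed).spawn(len(config.endpoints))
    grid = np.asarray(config.dca_grid, dtype=float) if config.dca_grid else default_grid()

    panels, models, metrics, comparisons, dca_out, sel_out = {}, {}, {}, {}, {}, {}
    for e_i, endpoint in enumerate(config.endpoints):
        logger.info("endpoint %s: selection on training cohort", endpoint)
        labels_all = pd.Series(
            build_endpoint_labels(subjects, endpoint), index=subjects["id"].to_numpy()
        )
        X_train = nm.data.loc[train_ids]
        sel_cfg = dataclasses.replace(
            config.selection,
            seed=int(seed_seq[e_i].generate_state(1)[0] % (2**31)),
        )
        panel_rank, cand_models = select_markers(X_train, labels_all.loc[train_ids], sel_cfg)
        # leakage guard: selection folds must stay inside the training cohort
        for m in cand_models:
            contaminated = valid_id_set.intersection(m.test_ids)
            if contaminated:
                raise RuntimeError(
                    "internal error: validation subjects leaked into selection "
                    f"folds: {sorted(contaminated)[:5]}"
                )
        panel = list(panel_rank.panel)
        logger.info(
            "endpoint %s: %d-marker panel at AIC nadir (of %d ranked)",
            endpoint, len(panel), len(panel_rank.ranked_features),
        )
        panels[endpoint] = {
            "panel": panel,
            "panel_size": panel_rank.panel_size,
            "ranked_features": list(panel_rank.ranked_features),
            "recurrence_counts": {k: int(v) for k, v in panel_rank.recurrence_counts.items()},
            "aic_sequence": [float(a) for a in panel_rank.aic_sequence],
        }
        sel_out[endpoint] = [
            {
                "round": m.round_index,
                "fold": m.fold_index,
                "features": list(m.features),
                "test_auc": m.test_auc,
                "train_aic": m.train_aic,
            }
            for m in cand_models
        ]

        fits: dict[str, LogisticFit] = {}
        scores = {}
        for pset in PREDICTOR_SETS:
            Xp = _predictor_frame(nm.data, subjects, panel, pset)
            fit = fit_logistic(Xp.loc[train_ids], labels_all.loc[train_ids])
            fits[pset] = fit
            prob, logit = predict_probability(fit, Xp)
            scores[pset] = pd.DataFrame({"prob": prob, "logit": logit}, index=Xp.index)
        models[endpoint] = {pset: fits[pset].to_dict() for pset in PREDICTOR_SETS}

        metrics[endpoint], comparisons[endpoint], dca_out[endpoint] = {}, {}, {}
        for cohort, ids in (("training", train_ids), ("validation", valid_ids)):
            y = labels_all.loc[ids].to_numpy()
            strata = strata_all.loc[ids].to_numpy()
            met, dcs = {}, {}
            for pset in PREDICTOR_SETS:
                s = scores[pset].loc[ids, "logit"].to_numpy()
                prob = scores[pset].loc[ids, "prob"].to_numpy()
                curve = ev.roc_auc(s, y)
                lo, hi = ev.auc_confidence_interval(curve)
                ops = {
                    "youden": ev.youden_threshold(
                        curve, s, y, strata=strata, weights=config.weights
                    ).to_dict()
                }
                for t in config.sensitivity_targets:
                    ops[f"sens_{int(round(t * 100))}"] = ev.operating_point_at_sensitivity(
                        s, y, t, strata=strata, weights=config.weights
                    ).to_dict()
                met[pset] = {
                    "auc": curve.auc,
                    "auc_ci": [lo, hi],
                    "auc_p_vs_half": ev.auc_p_vs_half(curve),
                    "delong_variance": curve.delong_variance,
                    "n": int(y.size),
                    "prevalence": float(y.mean()),
                    "operating_points": ops,
                }
                if pset in ("panel", "combined"):
                    dcs[pset] = _curve_dict(dca_curves(prob, y, grid))
            comp = {}
            for a, b in (("combined", "panel"), ("panel_psa", "panel"), ("panel", "clinical")):
                d, z, p = ev.delong_compare(
                    scores[a].loc[ids, "logit"], scores[b].loc[ids, "logit"], y
                )
                comp[f"{a}_vs_{b}"] = {"delta_auc": float(d), "z": float(z), "p": float(p)}
            metrics[endpoint][cohort] = met
            comparisons[endpoint][cohort] = comp
            dca_out[endpoint][cohort] = dcs
            logger.info(
                "endpoint %s / %s: AUC clinical %.3f, panel %.3f, combined %.3f",
                endpoint, cohort, met["clinical"]["auc"], met["panel"]["auc"],
                met["combined"]["auc"],
            )

    provenance = {
        "seed": int(config.seed),
        "n_training": int(train_mask.sum()),
        "n_validation": int((~train_mask).sum()),
        "n_raw_features": int(peaks.values.shape[1]),
        "n_retained_features": int(nm.data.shape[1]),
        "preprocess": nm.provenance,
        "ensemble_models_per_endpoint": config.selection.rounds * config.selection.k_folds,
    }
    return UtilityReport(
        config=config.to_dict(),
        panels=panels,
        models=models,
        metrics=metrics,
        comparisons=comparisons,
        dca=dca_out,
        selection=sel_out,
        provenance=provenance,
    )


def write_report(report: UtilityReport, outdir) -> dict:
    """Write report.json, metrics.csv, per-endpoint DCA CSVs and the
    selection report; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    files["report"] = outdir / "report.json"
    with open(files["report"], "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, sort_keys=True)

    rows = []
    for endpoint, by_cohort in report.metrics.items():
        for cohort, by_set in by_cohort.items():
            for pset, m in by_set.items():
                for op_name, op in m["operating_points"].items():
                    rows.append(
                        {
                            "endpoint": endpoint,
                            "cohort": cohort,
                            "predictor_set": pset,
                            "operating_point": op_name,
                            "auc": m["auc"],
                            "auc_lo": m["auc_ci"][0],
                            "auc_hi": m["auc_ci"][1],
                            "auc_p_vs_half": m["auc_p_vs_half"],
                            **op,
                        }
                    )
    files["metrics"] = outdir / "metrics.csv"
    pd.DataFrame(rows).to_csv(files["metrics"], index=False)

    for endpoint, by_cohort in report.dca.items():
        for cohort, by_set in by_cohort.items():
            if "combined" not in by_set:
                continue
            c = by_set["combined"]
            df = pd.DataFrame(
                {
                    "p_t": c["grid"],
                    "nb_model": c["nb_model"],
                    "nb_all": c["nb_all"],
                    "nb_none": c["nb_none"],
                    "avoided_per_1000": c["avoided_per_1000"],
                }
            )
            key = f"dca_{endpoint}_{cohort}"
            files[key] = outdir / f"{key}.csv"
            df.to_csv(files[key], index=False)

    files["selection"] = outdir / "selection_report.json"
    with open(files["selection"], "w") as fh:
        json.dump(
            {"panels": report.panels, "models": report.selection}, fh,
            indent=1, sort_keys=True,
        )

    files["provenance"] = outdir / "provenance.json"
    with open(files["provenance"], "w") as fh:
        json.dump(report.provenance, fh, indent=1, sort_keys=True)

    return {k: str(v) for k, v in files.items()}
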