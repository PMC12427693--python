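"""End-to-end orchestration: synthesize/load -> preprocess -> features ->
select -> group statistics -> classify, from a single config, with a
reproducible output bundle.

The config (YAML or :class:`RunConfig`) names the cohort (synthetic spec or
a manifest of recordings), the filter settings, feature layout, selection
settings, the classifier families, the class pairings to evaluate (any
subset of the group labels, plus merged classes such as cognitive decline =
Alzheimer + MCI), and one run-level seed. Every output file is listed in a
run manifest with a content hash; re-running the same config reproduces the
hashes.

Two protocols are available. ``paper`` selects features once on the full
task data before classifier CV (the apparent protocol of the original
analysis; optimistically biased). ``nested`` refits the selection inside
each training fold and is leakage-safe. Reports label the protocol used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as gstats
from .classify import (CVResult, ModelSpec, compute_metrics, evaluate_cv,
                       make_estimator, stratified_folds, tune, METRICS,
                       _scores_of)
from .errors import ConfigurationError, PipelineStageError
from .features import FeatureParams, build_matrix
from .preprocess import FilterSpec, load_recording, preprocess
from .selection import (SelectionConfig, channel_counts, choose_lambda,
                        select_features)
from .synth import CohortSpec, default_cohort_spec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    protocol: str = "paper"               # "paper" | "nested"
    cohort: CohortSpec | None = None      # synthetic cohort …
    manifest: str | None = None           # … or a cohort manifest on disk
    manifest_format: str = "csv"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    layout: str = "paper34"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fixed_lambda: float | None = None     # skip the grid when set
    models: tuple = ("svm", "lda", "ann", "rf")
    k: int = 10
    tuning_budget: int = 1
    pairings: tuple = ()                  # each: tuple of class names
    merges: dict = field(default_factory=dict)  # e.g. {"CD": ("alzheimer","mci")}

    def validate(self) -> None:
        if self.protocol not in ("paper", "nested"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        if (self.cohort is None) == (self.manifest is None):
            raise ConfigurationError(
                "config needs exactly one of 'cohort' or 'manifest'")
        if self.manifest is not None and not Path(self.manifest).exists():
            raise ConfigurationError(f"manifest {self.manifest} not found")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    kwargs = {"outdir": raw.get("outdir", "eegdx_out"),
              "seed": int(raw.get("seed", 0)),
              "protocol": raw.get("protocol", "paper"),
              "layout": raw.get("layout", "paper34"),
              "models": tuple(raw.get("models", ("svm", "lda", "ann", "rf"))),
              "k": int(raw.get("k", 10)),
              "tuning_budget": int(raw.get("tuning_budget", 1))}
    if "cohort" in raw:
        c = raw["cohort"]
        kwargs["cohort"] = default_cohort_spec(
            seed=int(c.get("seed", kwargs["seed"])),
            duration_s=float(c.get("duration_s", 120.0)),
            groups=c.get("groups"), n_subjects=c.get("n_subjects"))
    if "manifest" in raw:
        kwargs["manifest"] = raw["manifest"]
        kwargs["manifest_format"] = raw.get("manifest_format", "csv")
    if "filter" in raw:
        kwargs["filter_spec"] = FilterSpec(**raw["filter"])
    if "feature_params" in raw:
        kwargs["feature_params"] = FeatureParams(**raw["feature_params"])
    if "selection" in raw:
        sel = dict(raw["selection"])
        kwargs["fixed_lambda"] = sel.pop("fixed_lambda", None)
        if "lambda_grid" in sel:
            sel["lambda_grid"] = tuple(sel["lambda_grid"])
        kwargs["selection"] = SelectionConfig(
            **sel, seed=int(raw.get("seed", 0)))
    elif "fixed_lambda" in raw:
        kwargs["fixed_lambda"] = raw["fixed_lambda"]
    if "pairings" in raw:
        kwargs["pairings"] = tuple(tuple(p) for p in raw["pairings"])
    if "merges" in raw:
        kwargs["merges"] = {k: tuple(v) for k, v in raw["merges"].items()}
    return RunConfig(**kwargs)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:           # noqa: BLE001 - re-raised with stage
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %s: %.2f s", name, time.perf_counter() - t0)
        return out
    return wrap


def _apply_merges(labels, merges: dict) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    for merged, members in merges.items():
        labels[np.isin(labels, list(members))] = merged
    return labels.astype(str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _evaluate_nested(df_features: pd.DataFrame, y, lam, sel_cfg,
                     model: ModelSpec, folds) -> CVResult:
    """Leakage-safe CV: Lasso selection refit on each training fold."""
    names = [c for c in df_features.columns
             if c not in ("subject_id", "group")]
    X = df_features[names].to_numpy(float)
    y = np.asarray(y)
    classes = sorted(np.unique(y))
    cls_index = {c: i for i, c in enumerate(classes)}
    agg = np.zeros((len(classes), len(classes)))
    rows = []
    for fold_i, (tr, te) in enumerate(folds):
        sel = select_features(X[tr], y[tr], lam=lam, cfg=sel_cfg)
        cols = sel.selected if sel.selected.size else np.arange(X.shape[1])
        est = make_estimator(model)
        est.fit(X[np.ix_(tr, cols)], y[tr])
        pred = est.predict(X[np.ix_(te, cols)])
        conf = np.zeros_like(agg)
        for truth, hat in zip(y[te], pred):
            conf[cls_index[truth], cls_index[hat]] += 1
        scores = _scores_of(est, X[np.ix_(te, cols)], classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = compute_metrics(conf, classes, y_true=y[te],
                                      scores=scores)
        metrics.setdefault("auc", np.nan)
        rows.append({"fold": fold_i, **metrics})
        agg += conf
    per_fold = pd.DataFrame(rows)
    mean_sd = pd.DataFrame({"mean": per_fold[list(METRICS)].mean(),
                            "sd": per_fold[list(METRICS)].std(ddof=1)})
    return CVResult(model=model, classes=classes, per_fold=per_fold,
                    mean_sd=mean_sd, confusion=agg)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns a summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"protocol": config.protocol, "seed": config.seed,
                    "pairings": {}}

    # --- cohort ---------------------------------------------------------
    if config.cohort is not None:
        recordings = _stage("synth")(generate_cohort, config.cohort)
    else:
        def _load_all():
            man = pd.read_csv(config.manifest)
            base = Path(config.manifest).parent
            return [load_recording(base / r["path"],
                                   fs=r.get("fs"), subject_id=r["subject_id"],
                                   group=r["group"])
                    for r in man.to_dict("records")]
        recordings = _stage("load")(_load_all)

    # --- preprocess -----------------------------------------------------
    recordings = _stage("preprocess")(
        lambda recs: [preprocess(r, config.filter_spec) for r in recs],
        recordings)

    # --- features -------------------------------------------------------
    matrix = _stage("features")(build_matrix, recordings,
                                config.feature_params, config.layout)
    features_csv = outdir / "features.csv"
    matrix.to_csv(features_csv, params=config.feature_params)
    df = matrix.to_dataframe()

    # --- group statistics ----------------------------------------------
    labels_all = df["group"].to_numpy()
    _, counts = np.unique(labels_all, return_counts=True)
    stats_files = []
    if len(counts) >= 2 and counts.min() >= 3:
        table = _stage("stats")(gstats.run_feature_tests, matrix)
        gstats.write_results(table, outdir / "stats.csv",
                             outdir / "stats_summary.json")
        stats_files = ["stats.csv", "stats_summary.json"]
        report["stats"] = gstats.summarize(table)

    # --- per-pairing selection + classification ------------------------
    pairings = config.pairings or (tuple(sorted(set(labels_all))),)
    for pairing in pairings:
        tag = "-".join(pairing)
        y = _apply_merges(labels_all, config.merges)
        mask = np.isin(y, list(pairing))
        sub = df.loc[mask].reset_index(drop=True)
        y_sub = y[mask]
        if len(np.unique(y_sub)) < 2:
            raise PipelineStageError(
                f"pairing {tag}", ConfigurationError("fewer than two classes"))
        names = [c for c in sub.columns if c not in ("subject_id", "group")]
        X_sub = sub[names].to_numpy(float)

        sel_cfg = config.selection
        if config.fixed_lambda is not None:
            lam, curve = float(config.fixed_lambda), None
        else:
            lam, curve = _stage(f"select[{tag}]")(
                choose_lambda, X_sub, y_sub, sel_cfg)
        sel = select_features(X_sub, y_sub, lam=lam, cfg=sel_cfg)
        sel.feature_names = names
        sel.per_channel_counts = channel_counts(
            [names[i] for i in sel.selected])
        sel.cv_loss_curve = curve
        sel.to_json(outdir / f"selection_{tag}.json")
        sel.to_csv(outdir / f"selection_{tag}.csv")

        pair_report = {"lambda": lam, "n_selected": int(sel.selected.size),
                       "models": {}}
        folds = stratified_folds(y_sub, k=config.k, seed=config.seed)
        for family in config.models:
            spec = ModelSpec(family=family, tuning_budget=config.tuning_budget,
                             seed=config.seed)
            if config.protocol == "nested":
                cv = _stage(f"classify[{tag}/{family}]")(
                    _evaluate_nested, sub, y_sub, lam, sel_cfg, spec, folds)
            else:
                cols = sel.selected if sel.selected.size else np.arange(
                    X_sub.shape[1])
                X_model = X_sub[:, cols]
                if config.tuning_budget > 1:
                    spec.hyperparameters = tune(spec, X_model, y_sub)
                cv = _stage(f"classify[{tag}/{family}]")(
                    evaluate_cv, X_model, y_sub, spec, folds)
            cv.to_csv(outdir / f"cv_{tag}_{family}.csv")
            np.savetxt(outdir / f"confusion_{tag}_{family}.csv",
                       cv.confusion, fmt="%d", delimiter=",",
                       header=",".join(cv.classes), comments="")
            pair_report["models"][family] = cv.summary_dict()
        report["pairings"][tag] = pair_report

    # --- manifest -------------------------------------------------------
    files = ["features.csv", "features.params.json"] + stats_files + [
        p.name for p in sorted(outdir.glob("selection_*"))] + [
        p.name for p in sorted(outdir.glob("cv_*"))] + [
        p.name for p in sorted(outdir.glob("confusion_*"))]
    manifest = {"config": {"protocol": config.protocol, "seed": config.seed,
                           "layout": config.layout, "k": config.k,
                           "models": list(config.models),
                           "feature_params": asdict(config.feature_params)},
                "files": {f: _sha256(outdir / f) for f in sorted(set(files))
                          if (outdir / f).exists()}}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
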