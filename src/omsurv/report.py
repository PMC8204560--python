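"""Pipeline driver and run report.

Executes the configured stages in fixed order — load/split, preprocess,
feature selection, risk assessment, clustering, survival analysis — persists
every stage's outputs under the run directory, and emits a structured report
(canonical JSON plus a human-readable markdown rendering) listing every
stage's parameters, headline numbers, output files and elapsed time.

Interactive undo ("Redo"/"Clear all") is replaced by immutable per-stage
artifacts and a ``from_stage`` resume option that reloads persisted upstream
state instead of re-running it.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, feature_selection, group_survival, plots, risk_assessment, subtyping, synthetic
from .errors import OmsurvError, ParameterError
from .preprocess import fit_transform
from .tabular_io import OmicsClinicalTable, Schema, SplitSpec, load_dataset, split_train_test, write_split_membership

logger = logging.getLogger("omsurv")

STAGES = ("load", "preprocess", "feature_selection", "risk_assessment", "clustering", "survival_analysis")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run (YAML-loadable)."""

    out_dir: str = "omsurv_run"
    seed: int = 1
    input_path: str | None = None
    schema: dict = field(default_factory=dict)
    simulate: dict | None = None
    split: dict = field(default_factory=lambda: {"fraction": 0.7})
    preprocess: dict = field(
        default_factory=lambda: {
            "outlier_rule": "zscore",
            "z_threshold": 4.0,
            "impute_strategy": "median",
            "scale_method": "standard",
        }
    )
    selection: list = field(
        default_factory=lambda: [{"method": "uni_cox", "alpha": 0.05}, {"method": "lasso"}]
    )
    risk: dict = field(
        default_factory=lambda: {"horizons": [6.0, 12.0], "nomogram": True, "cv_folds": 5}
    )
    clustering: dict = field(default_factory=lambda: {"mode": "silhouette", "restarts": 10})
    survival: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.input_path is None and cfg.simulate is None:
            raise ParameterError("config needs either input_path+schema or simulate")
        if cfg.input_path is not None and not cfg.schema:
            raise ParameterError("input_path requires a schema mapping")
        frac = cfg.split.get("fraction", 0.7)
        if not (0 < frac <= 1):
            raise ParameterError("split fraction must lie in (0, 1]")
        for step in cfg.selection:
            if step.get("method") not in feature_selection._METHODS:
                raise ParameterError(f"unknown selection method {step.get('method')!r}")
        return cfg


@dataclass
class StageEntry:
    stage: str
    params: dict
    started: float
    elapsed: float
    status: str  # "ok" | "skipped" | "failed" | "resumed"
    summary: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunReport:
    version: str
    seed: int
    stages: list[StageEntry] = field(default_factory=list)
    total_elapsed: float = 0.0
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "tool": "omsurv",
            "version": self.version,
            "seed": self.seed,
            "status": self.status,
            "total_elapsed": self.total_elapsed,
            "stages": [
                {
                    "stage": s.stage,
                    "params": s.params,
                    "started": s.started,
                    "elapsed": s.elapsed,
                    "status": s.status,
                    "summary": s.summary,
                    "outputs": s.outputs,
                    "error": s.error,
                }
                for s in self.stages
            ],
        }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def render_report(report: RunReport, out_dir, formats=("json", "markdown")) -> list[Path]:
    """Write report.json (canonical, round-trippable) and/or report.md."""
    out_dir = Path(out_dir)
    written = []
    if "json" in formats:
        p = out_dir / "report.json"
        with open(p, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, default=_json_default, sort_keys=True)
        written.append(p)
    if "markdown" in formats:
        p = out_dir / "report.md"
        lines = [
            "# omsurv run report",
            "",
            f"- tool version: {report.version}",
            f"- seed: {report.seed}",
            f"- status: {report.status}",
            f"- total elapsed: {report.total_elapsed:.2f} s",
            "",
        ]
        for s in report.stages:
            lines += [f"## {s.stage}", ""]
            lines.append(f"- status: {s.status} (elapsed {s.elapsed:.2f} s)")
            for k, v in s.params.items():
                lines.append(f"- {k}: {v}")
            for k, v in s.summary.items():
                lines.append(f"- **{k}**: {v}")
            if s.outputs:
                lines.append(f"- outputs: {', '.join(s.outputs)}")
            if s.error:
                lines.append(f"- error: {s.error}")
            lines.append("")
        p.write_text("\n".join(lines))
        written.append(p)
    return written


class _PipelineState:
    """In-memory state handed from stage to stage (persisted per stage)."""

    table: OmicsClinicalTable | None = None
    train: OmicsClinicalTable | None = None
    test: OmicsClinicalTable | None = None
    selected: list[str] | None = None
    risk_model = None
    assignment = None


def run_pipeline(config: RunConfig, from_stage: str | None = None) -> RunReport:
    """Execute the configured stages in order, persisting all outputs.

    A stage failure is recorded with its error message and stops the
    pipeline after writing the report; completed stages keep their
    artifacts. ``from_stage`` resumes at the named stage by reloading the
    persisted outputs of earlier stages from ``config.out_dir``.
    """
    if from_stage is not None and from_stage not in STAGES:
        raise ParameterError(f"unknown stage {from_stage!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    report = RunReport(version=__version__, seed=config.seed)
    state = _PipelineState()
    t0 = _time.perf_counter()
    start_idx = STAGES.index(from_stage) if from_stage else 0
    try:
        for i, stage in enumerate(STAGES):
            begin = _time.perf_counter()
            try:
                if i < start_idx:
                    _resume_stage(stage, config, out, state)
                    report.stages.append(
                        StageEntry(stage, {}, begin, _time.perf_counter() - begin, "resumed")
                    )
                    continue
                params, summary, outputs, skipped = _run_stage(stage, config, out, state)
                status = "skipped" if skipped else "ok"
                report.stages.append(
                    StageEntry(stage, params, begin, _time.perf_counter() - begin, status, summary, outputs)
                )
                if skipped:
                    logger.info("stage %s skipped: %s", stage, summary)
                else:
                    logger.info("stage %s done", stage)
                if summary.get("stop_pipeline"):
                    report.status = "stopped_early"
                    break
            except OmsurvError as exc:
                report.stages.append(
                    StageEntry(
                        stage, {}, begin, _time.perf_counter() - begin, "failed", error=str(exc)
                    )
                )
                report.status = "failed"
                logger.error("stage %s failed: %s", stage, exc)
                break
    finally:
        report.total_elapsed = _time.perf_counter() - t0
        render_report(report, out)
        logger.removeHandler(fh)
        fh.close()
    return report


# ---------------------------------------------------------------------------
# stage implementations


def _run_stage(stage, config, out, state):
    if stage == "load":
        return _stage_load(config, out, state)
    if stage == "preprocess":
        return _stage_preprocess(config, out, state)
    if stage == "feature_selection":
        return _stage_selection(config, out, state)
    if stage == "risk_assessment":
        return _stage_risk(config, out, state)
    if stage == "clustering":
        return _stage_cluster(config, out, state)
    if stage == "survival_analysis":
        return _stage_survival(config, out, state)
    raise ParameterError(stage)


def _stage_load(config, out, state):
    if config.simulate is not None:
        gen_cfg = synthetic.GeneratorConfig(**{**config.simulate, "seed": config.seed})
        table, truth = synthetic.generate(gen_cfg)
        truth.to_json(out / "ground_truth.json")
        table.write_csv(out / "input.csv")
        params = {"source": "simulate", **config.simulate}
    else:
        table = load_dataset(config.input_path, config.schema)
        params = {"source": config.input_path}
    spec = SplitSpec(
        fraction=config.split.get("fraction", 0.7),
        seed=config.split.get("seed", config.seed),
        stratify_by_event=config.split.get("stratify_by_event", False),
    )
    train, test = split_train_test(table, spec)
    write_split_membership(out / "split.csv", train, test)
    state.table, state.train, state.test = table, train, test
    summary = {
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "n_events": int(table.event.sum()),
        "n_train": train.n_samples,
        "n_test": test.n_samples,
    }
    return params, summary, ["split.csv"], False


def _stage_preprocess(config, out, state):
    p = config.preprocess
    train, test, fitted = fit_transform(
        state.train,
        state.test if state.test.n_samples else None,
        outlier_rule=p.get("outlier_rule", "zscore"),
        z_threshold=p.get("z_threshold", 4.0),
        impute_strategy=p.get("impute_strategy", "median"),
        scale_method=p.get("scale_method", "standard"),
    )
    state.train = train
    state.test = test if test is not None else state.test
    train.write_csv(out / "preprocessed_train.csv")
    if test is not None:
        test.write_csv(out / "preprocessed_test.csv")
    fitted.to_frame().to_csv(out / "preprocess_params.csv")
    summary = {
        "n_outliers_flagged": fitted.n_outliers_flagged,
        "n_imputed": fitted.n_imputed,
    }
    return dict(p), summary, ["preprocessed_train.csv", "preprocess_params.csv"], False


def _stage_selection(config, out, state):
    steps = [dict(s) for s in config.selection]
    for s in steps:
        if s.get("method") == "lasso":
            s.setdefault("seed", config.seed)
    trace = feature_selection.run_selection_chain(state.train, steps)
    trace.to_frame().to_csv(out / "selection_trace.csv", index=False)
    with open(out / "selected_features.json", "w") as fh:
        json.dump({"features": trace.final_features, "steps": trace.summary()}, fh, indent=1)
    for st in trace.steps:
        cv = getattr(st, "cv_curve", None)
        if cv is not None:
            cv.to_csv(out / "lasso_cv_curve.csv", index=False)
    state.selected = trace.final_features
    summary = {
        "chain": [s["method"] for s in steps],
        "sizes": [st.n_out for st in trace.steps],
        "n_selected": len(trace.final_features),
        "status": trace.status,
    }
    if trace.status == "empty_result":
        summary["stop_pipeline"] = True
    return {"steps": steps}, summary, ["selection_trace.csv", "selected_features.json"], False


def _stage_risk(config, out, state):
    r = config.risk
    horizons = tuple(float(h) for h in r.get("horizons", (6.0, 12.0)))
    model = risk_assessment.fit_risk_model(state.train, state.selected, horizons)
    state.risk_model = model
    model.to_risk_table().to_csv(out / "risk_table.csv", index_label="sample_id")
    h0 = horizons[0]
    metrics = {"horizons": list(horizons)}
    from . import survstat

    tr_time = state.train.time.to_numpy(dtype=float)
    tr_event = state.train.event.to_numpy()
    metrics["train_cindex"] = survstat.concordance_index(
        model.radscore.to_numpy(), tr_time, tr_event
    )
    outputs = ["risk_table.csv", "metrics.json"]
    if state.test is not None and state.test.n_samples >= 2:
        Xte = state.test.subset_features(model.feature_ids).features.to_numpy(dtype=float)
        te_scores = risk_assessment.compute_radscore(model.beta, Xte)
        te_time = state.test.time.to_numpy(dtype=float)
        te_event = state.test.event.to_numpy()
        try:
            metrics["test_cindex"] = survstat.concordance_index(te_scores, te_time, te_event)
            for h in horizons:
                roc = survstat.td_roc(te_scores, te_time, te_event, h)
                metrics[f"test_auc_{h:g}"] = roc.auc
                plots.tdroc_plot(roc, out / f"tdroc_{h:g}.png")
                outputs.append(f"tdroc_{h:g}.png")
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                pred = risk_assessment.predict_survival(model, Xte, h0)
            pairs = survstat.calibration_curve(pred, te_time, te_event, h0, n_bins=5)
            plots.calibration_plot(pairs, out / "calibration.png", h0)
            pd.DataFrame(pairs, columns=["mean_predicted", "km_observed"]).to_csv(
                out / "calibration.csv", index=False
            )
            outputs += ["calibration.png", "calibration.csv"]
        except survstat.UndefinedResultError as exc:
            metrics["test_warning"] = str(exc)
    if r.get("cv_folds"):
        cv = risk_assessment.cross_validate(
            state.train, model.feature_ids, n_folds=int(r["cv_folds"]), horizon=h0, seed=config.seed
        )
        metrics["cv_cindex"] = cv.pooled_cindex
        metrics["cv_auc"] = cv.pooled_auc
    if r.get("nomogram", True) and not np.all(model.beta == 0):
        nomo = risk_assessment.build_nomogram(model, state.train, horizons)
        nomo.feature_points.to_csv(out / "nomogram.csv", index=False)
        nomo.total_to_prob.to_csv(out / "nomogram_mapping.csv", index=False)
        plots.nomogram_plot(nomo, out / "nomogram.png")
        outputs += ["nomogram.csv", "nomogram_mapping.csv", "nomogram.png"]
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, default=_json_default, sort_keys=True)
    summary = {k: v for k, v in metrics.items() if isinstance(v, (int, float))}
    summary["n_model_features"] = len(model.feature_ids)
    return dict(r), summary, outputs, False


def _cluster_matrix(state):
    feats = state.selected
    full = pd.concat([state.train.features[feats], state.test.features[feats]])
    ids = full.index
    return full.to_numpy(dtype=float), ids


def _stage_cluster(config, out, state):
    c = config.clustering
    X, ids = _cluster_matrix(state)
    labels_ref = None
    if c.get("mode") == "ami":
        lab_series = pd.concat([state.train.labels, state.test.labels])
        labels_ref = lab_series.loc[ids].to_numpy()
    assignment = subtyping.select_k(
        X,
        mode=c.get("mode", "silhouette"),
        labels=labels_ref,
        k=c.get("k"),
        seed=config.seed,
        restarts=c.get("restarts", 10),
    )
    state.assignment = assignment
    assignment.to_frame(ids).to_csv(out / "clusters.csv", index=False)
    outputs = ["clusters.csv"]
    if assignment.curve is not None:
        assignment.curve.to_csv(out / "k_curve.csv", index=False)
        plots.score_vs_k_plot(assignment.curve, out / "k_curve.png", assignment.criterion)
        outputs += ["k_curve.csv", "k_curve.png"]
    summary = {"k": assignment.k, "criterion": assignment.criterion}
    return dict(c), summary, outputs, False


def _stage_survival(config, out, state):
    s = config.survival
    X, ids = _cluster_matrix(state)
    time = pd.concat([state.train.time, state.test.time]).loc[ids].to_numpy(dtype=float)
    event = pd.concat([state.train.event, state.test.event]).loc[ids].to_numpy()
    result = group_survival.compare_groups(time, event, state.assignment.labels)
    result.km_frame().to_csv(out / "km_curves.csv", index=False)
    result.at_risk.to_csv(out / "at_risk.csv")
    summary_obj = result.summary()
    plots.km_plot(result, out / "km_by_cluster.png", "KM by subtype")
    outputs = ["km_curves.csv", "at_risk.csv", "survival_summary.json", "km_by_cluster.png"]
    if s.get("user_k"):
        cmp = group_survival.compare_user_vs_system_k(
            X, time, event, user_k=int(s["user_k"]),
            mode=config.clustering.get("mode", "silhouette"), seed=config.seed,
        )
        summary_obj["user_vs_system"] = cmp.summary()
    if s.get("category"):
        by_cat = group_survival.survival_by_category(state.table, s["category"])
        summary_obj["category"] = {"column": s["category"], **by_cat.summary()}
        plots.km_plot(by_cat, out / "km_by_category.png", f"KM by {s['category']}")
        outputs.append("km_by_category.png")
    with open(out / "survival_summary.json", "w") as fh:
        json.dump(summary_obj, fh, indent=1, default=_json_default, sort_keys=True)
    summary = {
        "logrank_p": result.logrank.p_value,
        "logrank_chi2": result.logrank.statistic,
        "n_groups": len(result.group_names),
    }
    return dict(s), summary, outputs, False


# ---------------------------------------------------------------------------
# resume support


def _resume_stage(stage, config, out, state):
    """Rebuild in-memory state from the persisted artifacts of ``stage``."""
    if stage == "load":
        if config.simulate is not None:
            schema = {"time_col": "time", "event_col": "event", "id_col": "sample_id"}
            if config.simulate.get("with_stage_label"):
                schema["label_col"] = "label"
            state.table = load_dataset(out / "input.csv", schema)
        else:
            state.table = load_dataset(config.input_path, config.schema)
        membership = pd.read_csv(out / "split.csv").set_index("sample_id")["partition"]
        tr_ids = membership[membership == "train"].index.tolist()
        te_ids = membership[membership == "test"].index.tolist()
        state.train = state.table.subset_samples(tr_ids)
        state.test = state.table.subset_samples(te_ids)
    elif stage == "preprocess":
        schema = {"time_col": "time", "event_col": "event", "id_col": "sample_id"}
        state.train = load_dataset(out / "preprocessed_train.csv", schema)
        if (out / "preprocessed_test.csv").exists():
            state.test = load_dataset(out / "preprocessed_test.csv", schema)
    elif stage == "feature_selection":
        with open(out / "selected_features.json") as fh:
            state.selected = json.load(fh)["features"]
    elif stage == "risk_assessment":
        horizons = tuple(float(h) for h in config.risk.get("horizons", (6.0, 12.0)))
        state.risk_model = risk_assessment.fit_risk_model(state.train, state.selected, horizons)
    elif stage == "clustering":
        clusters = pd.read_csv(out / "clusters.csv")
        labels = clusters["cluster"].to_numpy()
        state.assignment = subtyping.SubtypeAssignment(
            k=int(labels.max()), labels=labels, criterion="resumed", curve=None,
            seed=config.seed, restarts=0,
        )
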