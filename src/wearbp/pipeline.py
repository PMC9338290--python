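"""File-based pipeline stages: simulate -> extract -> train -> evaluate -> compare.

Each stage reads the previous stage's artifacts from the output directory,
writes its own artifacts plus a manifest (inputs, seed, config hash), and is
independently re-runnable.  The :mod:`wearbp.cli` module exposes these as
shell commands.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, feature_extraction, modeling, preprocessing
from .config import PipelineConfig
from .reference_bp import make_pairs, reconcile_observation
from .signal_io import (
    read_observations,
    read_recording,
    write_feature_matrix,
    write_observations,
    write_recording,
)
from .synthetic_data import default_protocol, generate_cohort, synthesize_recording

log = logging.getLogger(__name__)


class MissingArtifactError(FileNotFoundError):
    """A required upstream artifact is absent; names the stage to run."""

    def __init__(self, artifact: str, stage: str):
        super().__init__(f"missing artifact {artifact!r}: run the {stage!r} stage first")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(str(path), stage)
    return path


def _manifest(out_dir: Path, stage: str, config: PipelineConfig,
              extra: dict | None = None) -> None:
    payload = {"stage": stage, "seed": config.seed,
               "config_hash": config.config_hash(), **(extra or {})}
    (out_dir / f"manifest_{stage}.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate the cohort, per-subject recordings and observer readings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.n_subjects, config.generator.class_fractions,
                             config.seed, config.generator)
    obs_per_condition = max(1, config.obs_per_subject // 4)
    protocol = default_protocol(obs_per_condition)

    cohort_rows, all_obs = [], []
    rec_dir = out_dir / "recordings"
    for i, subject in enumerate(cohort):
        session = synthesize_recording(subject, protocol,
                                       seed=config.seed * 100_003 + i,
                                       config=config.generator)
        write_recording(session.recording, rec_dir / subject.subject_id)
        all_obs.extend(session.observations)
        cohort_rows.append({
            "subject_id": subject.subject_id, "age": subject.age,
            "sex": subject.sex, "height": subject.height,
            "weight": subject.weight, "entry_sbp": subject.entry_sbp,
            "entry_dbp": subject.entry_dbp, "bp_class": subject.bp_class,
        })
        session.truth.assign(subject_id=subject.subject_id).to_csv(
            out_dir / "truth.csv", mode="a" if i else "w", header=not i, index=False)
    pd.DataFrame(cohort_rows).to_csv(out_dir / "cohort.csv", index=False)
    write_observations(all_obs, out_dir / "observations.csv")
    _manifest(out_dir, "simulate", config,
              {"n_subjects": config.n_subjects, "n_observations": len(all_obs)})
    return out_dir


def stage_extract(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Quality screening, window association and feature extraction."""
    out_dir = Path(out_dir)
    obs_path = _require(out_dir / "observations.csv", "simulate")
    cohort_path = _require(out_dir / "cohort.csv", "simulate")
    observations = read_observations(obs_path)
    cohort = pd.read_csv(cohort_path).set_index("subject_id")

    references, rejections, rows = [], [], []
    for subject_id, group in _group_by_subject(observations):
        rec = read_recording(_require(out_dir / "recordings" / subject_id, "simulate"))
        mask = preprocessing.assess_quality(rec, config.quality)
        demo = cohort.loc[subject_id]
        subject = _DemoView(demo)
        for obs in group:
            ref = reconcile_observation(obs.observation_id, obs.obs1_sbp,
                                        obs.obs1_dbp, obs.obs2_sbp, obs.obs2_dbp)
            if not ref.accepted:
                rejections.append({"observation_id": obs.observation_id,
                                   "reason": ref.reason})
                continue
            window = preprocessing.associate_window(mask, rec, obs, config.window)
            if isinstance(window, preprocessing.WindowRejection):
                rejections.append({"observation_id": window.observation_id,
                                   "reason": window.reason})
                continue
            try:
                fv = feature_extraction.build_feature_vector(window, subject,
                                                             config.features)
            except feature_extraction.WindowRejectionError as e:
                rejections.append({"observation_id": obs.observation_id,
                                   "reason": str(e)})
                continue
            row = fv.to_row()
            row.update({
                "subject_id": subject_id,
                "condition": obs.condition,
                "timestamp_s": obs.timestamp_s,
                "sbp_ref": ref.sbp_ref, "dbp_ref": ref.dbp_ref,
                "cuff_sbp": obs.cuff_sbp, "cuff_dbp": obs.cuff_dbp,
            })
            rows.append(row)
            references.append({
                "observation_id": obs.observation_id, "sbp_ref": ref.sbp_ref,
                "dbp_ref": ref.dbp_ref, "status": ref.status, "reason": ref.reason,
            })
    features = pd.DataFrame(rows)
    write_feature_matrix(features, out_dir / "features.csv",
                         {"config_hash": config.config_hash(),
                          "registry": feature_extraction.FEATURE_REGISTRY})
    pd.DataFrame(references).to_csv(out_dir / "references.csv", index=False)
    pd.DataFrame(rejections, columns=["observation_id", "reason"]).to_csv(
        out_dir / "rejections.csv", index=False)
    _manifest(out_dir, "extract", config,
              {"n_features_rows": len(features), "n_rejections": len(rejections)})
    return out_dir


class _DemoView:
    """Demographics row adapter with the attributes feature building expects."""

    def __init__(self, row: pd.Series):
        self.age = int(row["age"])
        self.sex = str(row["sex"])
        self.height = float(row["height"])
        self.weight = float(row["weight"])


def _group_by_subject(observations):
    by: dict[str, list] = {}
    for o in observations:
        by.setdefault(o.subject_id, []).append(o)
    return sorted(by.items())


# --------------------------------------------------------------------------

def stage_train(config: PipelineConfig, out_dir: str | Path,
                features_df: pd.DataFrame | None = None) -> Path:
    """Split, select features, train signal + baseline ensembles, predict."""
    out_dir = Path(out_dir)
    if features_df is None:
        from .signal_io import read_feature_matrix
        features_df, _ = read_feature_matrix(_require(out_dir / "features.csv", "extract"))
    df = features_df.reset_index(drop=True)

    labels = modeling.split_dataset(
        len(df), config.model.train_fraction, seed=config.seed,
        subject_ids=df.get("subject_id"), level=config.model.split_level)
    df = df.assign(split=labels)
    train_df = df[df["split"] == "train"]

    feature_cols = modeling.registry_features(df)
    selected, importances = {}, {}
    for target in modeling.TARGETS:
        sel, imp = modeling.select_features(
            train_df[feature_cols], train_df[f"{target}_ref"],
            threshold=config.model.selection_threshold, seed=config.seed,
            n_trees=config.model.selection_n_trees)
        # demographics may be de-selected but signal models always get the
        # selected set exactly; an empty selection falls back to everything
        selected[target] = sel or feature_cols
        importances[target] = imp.to_dict()

    chash = config.config_hash()
    models = modeling.train_models(train_df, selected, seed=config.seed,
                                   config=config.model, config_hash=chash)
    baselines = modeling.train_baseline(train_df, seed=config.seed + 1000,
                                        config=config.model, config_hash=chash)

    model_dir = out_dir / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    preds = df[["observation_id", "subject_id", "condition", "split",
                "sbp_ref", "dbp_ref", "cuff_sbp", "cuff_dbp", "timestamp_s"]].copy() \
        if "timestamp_s" in df.columns else df[[
            "observation_id", "subject_id", "condition", "split",
            "sbp_ref", "dbp_ref", "cuff_sbp", "cuff_dbp"]].copy()
    for target in modeling.TARGETS:
        models[target].save(model_dir / f"{target}_model.joblib")
        baselines[target].save(model_dir / f"{target}_baseline.joblib")
        preds[f"{target}_hat"] = models[target].predict(df)
        preds[f"{target}_hat_baseline"] = baselines[target].predict(df)
    preds.to_csv(out_dir / "predictions.csv", index=False)
    (out_dir / "selected_features.json").write_text(
        json.dumps({"selected": selected, "importances": importances},
                   indent=1, sort_keys=True))
    _manifest(out_dir, "train", config,
              {"n_train": int((labels == "train").sum()),
               "n_test": int((labels == "test").sum())})
    return out_dir


def stage_evaluate(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Stratified MAD/MAPD/RMSE report with Bland–Altman agreement."""
    out_dir = Path(out_dir)
    preds = pd.read_csv(_require(out_dir / "predictions.csv", "train"))

    frames = []
    for target in modeling.TARGETS:
        frames.append(pd.DataFrame({
            "target": target, "p": preds[f"{target}_hat"],
            "y": preds[f"{target}_ref"], "condition": preds["condition"],
            "split": preds["split"],
        }))
    report = evaluation.stratified_report(pd.concat(frames, ignore_index=True))

    # wrist-cuff agreement via the adjacent-mean pairing rule
    if "timestamp_s" in preds.columns and preds["cuff_sbp"].notna().any():
        report["wrist_cuff"] = _cuff_report(preds)

    # bootstrap MAD CI on the test split
    test = preds[preds["split"] == "test"]
    for target in modeling.TARGETS:
        lo, hi = evaluation.bootstrap_mad_ci(
            test[f"{target}_hat"], test[f"{target}_ref"],
            n_iterations=config.evaluation.n_bootstrap_mad, seed=config.seed)
        report[target]["test_mad_ci"] = [lo, hi]

    payload = json.dumps(report, indent=1, sort_keys=True)
    (out_dir / "evaluation.json").write_text(payload)
    evaluation.report_to_frame(
        {t: report[t] for t in modeling.TARGETS}).to_csv(
        out_dir / "evaluation.csv", index=False)
    _manifest(out_dir, "evaluate", config, {})
    return report


def _cuff_report(preds: pd.DataFrame) -> dict:
    """Score the sequential wrist cuff against adjacent-mean references."""
    out: dict = {}
    for target in modeling.TARGETS:
        pairs = []
        for _, g in preds.groupby("subject_id"):
            g = g.sort_values("timestamp_s")
            refs = [(r.observation_id, r.timestamp_s, getattr(r, f"{target}_ref"))
                    for r in g.itertuples()]
            cuff = [(r.observation_id, r.timestamp_s + 75.0,
                     getattr(r, f"cuff_{target}"))
                    for r in g.itertuples() if np.isfinite(getattr(r, f"cuff_{target}"))]
            pairs.extend(make_pairs(cuff, refs, mode="adjacent_mean"))
        if pairs:
            p = np.array([x.p for x in pairs])
            y = np.array([x.y for x in pairs])
            out[target] = {"n": len(pairs), "mad": evaluation.mad(p, y),
                           "mapd": evaluation.mapd(p, y),
                           "rmse": evaluation.rmse(p, y)}
    return out


def stage_compare(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Paired-bootstrap RMSE comparison of signal models vs demographics."""
    out_dir = Path(out_dir)
    preds = pd.read_csv(_require(out_dir / "predictions.csv", "train"))
    test = preds[preds["split"] == "test"]
    result = {}
    for target in modeling.TARGETS:
        cmp = evaluation.bootstrap_rmse_comparison(
            test[f"{target}_hat"], test[f"{target}_hat_baseline"],
            test[f"{target}_ref"],
            n_resamples=config.evaluation.n_bootstrap_rmse,
            seed=config.seed, target=target)
        result[target] = cmp.to_dict()
    (out_dir / "comparison.json").write_text(
        json.dumps(result, indent=1, sort_keys=True))
    _manifest(out_dir, "compare", config, {})
    return result


def run_feature_study(features_df: pd.DataFrame, config: PipelineConfig,
                      seed: int | None = None) -> dict:
    """Split/select/train/evaluate/compare on an in-memory feature matrix.

    The in-memory analogue of the train/evaluate/compare stages, used for
    Monte-Carlo studies over many seeds (e.g. on feature-level synthetic
    datasets).  Returns predictions, the stratified report and the paired
    bootstrap comparison per target.
    """
    if seed is not None:
        config = PipelineConfig.from_dict({**config.to_dict(), "seed": seed})
    df = features_df.reset_index(drop=True)
    labels = modeling.split_dataset(
        len(df), config.model.train_fraction, seed=config.seed,
        subject_ids=df.get("subject_id"), level=config.model.split_level)
    df = df.assign(split=labels)
    train_df = df[df["split"] == "train"]
    feature_cols = modeling.registry_features(df)

    selected = {}
    for target in modeling.TARGETS:
        sel, _ = modeling.select_features(
            train_df[feature_cols], train_df[f"{target}_ref"],
            threshold=config.model.selection_threshold, seed=config.seed,
            n_trees=config.model.selection_n_trees)
        selected[target] = sel or feature_cols

    models = modeling.train_models(train_df, selected, seed=config.seed,
                                   config=config.model)
    baselines = modeling.train_baseline(train_df, seed=config.seed + 1000,
                                        config=config.model)
    test = df[df["split"] == "test"]
    comparison = {}
    frames = []
    for target in modeling.TARGETS:
        p = models[target].predict(test)
        pb = baselines[target].predict(test)
        y = test[f"{target}_ref"].to_numpy(dtype=float)
        comparison[target] = evaluation.bootstrap_rmse_comparison(
            p, pb, y, n_resamples=config.evaluation.n_bootstrap_rmse,
            seed=config.seed, target=target)
        frames.append(pd.DataFrame({
            "target": target, "p": p, "y": y,
            "condition": test["condition"].to_numpy(), "split": "test"}))
        tr_frame = pd.DataFrame({
            "target": target, "p": models[target].predict(train_df),
            "y": train_df[f"{target}_ref"].to_numpy(dtype=float),
            "condition": train_df["condition"].to_numpy(), "split": "train"})
        frames.append(tr_frame)
    report = evaluation.stratified_report(pd.concat(frames, ignore_index=True))
    return {"df": df, "selected": selected, "models": models,
            "baselines": baselines, "comparison": comparison, "report": report}


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage in order; returns the evaluation report + comparison."""
    stage_simulate(config, out_dir)
    stage_extract(config, out_dir)
    stage_train(config, out_dir)
    report = stage_evaluate(config, out_dir)
    comparison = stage_compare(config, out_dir)
    return {"evaluation": report, "comparison": comparison}
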