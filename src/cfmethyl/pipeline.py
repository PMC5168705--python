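"""Stage orchestration: simulate → select-markers → quantify → features →
search/score → evaluate, with persisted artifacts carrying the config hash."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import arrays, ddmsp, evaluation, features, model, synthetic
from .config import PipelineConfig
from .panel import DEFAULT_PANEL

log = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "select-markers", "quantify", "features", "search", "score", "evaluate")


def _cohort_config(config: PipelineConfig) -> synthetic.CohortSimConfig:
    if config.preset == "table1_cohort":
        return synthetic.table1_cohort_config(seed=config.seed)
    return synthetic.small_cohort_config(seed=config.seed)


def _write_meta(workdir: Path, stage: str, config: PipelineConfig, elapsed: float) -> None:
    meta = {"stage": stage, "config_hash": config.config_hash(),
            "seed": config.seed, "elapsed_s": round(elapsed, 3)}
    (workdir / f"{stage}.meta.json").write_text(json.dumps(meta, indent=2))


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in pipeline order; returns in-memory artifacts.

    An empty stage list is a no-op.  Each stage writes its artifacts plus a
    ``<stage>.meta.json`` carrying the config hash and seed under the
    configured working directory.
    """
    if stages is None:
        stages = list(STAGE_ORDER)
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]

    workdir = Path(config.paths.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    for stage in stages:
        t0 = time.monotonic()
        log.info("stage %s: starting", stage)
        if stage == "simulate":
            _stage_simulate(config, workdir, artifacts)
        elif stage == "select-markers":
            _stage_select_markers(config, workdir, artifacts)
        elif stage == "quantify":
            _stage_quantify(config, workdir, artifacts)
        elif stage == "features":
            _stage_features(config, workdir, artifacts)
        elif stage == "search":
            _stage_search(config, workdir, artifacts)
        elif stage == "score":
            _stage_score(config, workdir, artifacts)
        elif stage == "evaluate":
            _stage_evaluate(config, workdir, artifacts)
        elapsed = time.monotonic() - t0
        _write_meta(workdir, stage, config, elapsed)
        log.info("stage %s: done in %.2fs", stage, elapsed)
    return artifacts


def _stage_simulate(config: PipelineConfig, workdir: Path, artifacts: dict) -> None:
    acfg = synthetic.ArraySimConfig(seed=config.seed)
    dataset, manifest = synthetic.gen_array_dataset(acfg)
    dataset.to_files(workdir / "beta.tsv", workdir / "sample_sheet.csv")
    (workdir / "array_manifest.json").write_text(json.dumps(manifest, indent=2))

    ccfg = _cohort_config(config)
    roster = synthetic.gen_roster(ccfg)
    roster.to_csv(workdir / "roster.csv", index=False)

    wells, truth = synthetic.gen_droplet_dataset(roster, DEFAULT_PANEL, ccfg)
    ddmsp.write_droplet_csv(wells, workdir / "droplets.csv")
    truth.to_csv(workdir / "droplet_manifest.csv", index=False)

    artifacts.update(
        array=dataset, array_manifest=manifest, roster=roster,
        wells=wells, droplet_manifest=truth,
    )


def _require(artifacts: dict, key: str, producer: str):
    if key not in artifacts:
        raise RuntimeError(f"missing artifact {key!r}: run the {producer!r} stage first")
    return artifacts[key]


def _stage_select_markers(config: PipelineConfig, workdir: Path, artifacts: dict) -> None:
    dataset = _require(artifacts, "array", "simulate")
    means = arrays.compute_group_means(dataset)
    candidates = arrays.select_candidates(means)
    candidates = arrays.attach_welch_tests(candidates, dataset)
    candidates.to_csv(workdir / "candidates.csv")
    dataset.beta.loc[candidates.unique_loci].to_csv(workdir / "candidate_beta.tsv", sep="\t")
    artifacts["candidates"] = candidates


def _train_labels(roster: pd.DataFrame) -> dict[str, int]:
    train = roster[roster["split"] == "train"]
    return {s: int(c == "BC") for s, c in zip(train["sample_id"], train["class"])}


def _stage_quantify(config: PipelineConfig, workdir: Path, artifacts: dict) -> None:
    roster = _require(artifacts, "roster", "simulate")
    wells = _require(artifacts, "wells", "simulate")
    if (roster["split"] == "unassigned").all():
        roster = evaluation.stratified_split(
            roster,
            train_counts=evaluation.TABLE1_TRAIN_COUNTS if config.preset == "table1_cohort" else None,
            train_fraction=0.6,
            seed=config.seed,
        )
        artifacts["roster"] = roster
        roster.to_csv(workdir / "roster.csv", index=False)

    labels = _train_labels(roster)
    train_wells = {
        m: {s: ws for s, ws in by_sample.items() if s in labels}
        for m, by_sample in wells.items()
    }
    state = ddmsp.fit_quantification(train_wells, labels, n_grid=config.amplitude_grid)
    state.to_json(workdir / "quant_state.json")
    quants = ddmsp.quantify_cohort(wells, state)
    quants.to_csv(workdir / "marker_quant.csv", index=False)
    artifacts.update(quant_state=state, quants=quants)


def _stage_features(config: PipelineConfig, workdir: Path, artifacts: dict) -> None:
    quants = _require(artifacts, "quants", "quantify")
    roster = _require(artifacts, "roster", "simulate")
    table = features.build_feature_table(quants, DEFAULT_PANEL, epsilon=config.epsilon)
    labels = roster.set_index("sample_id")["class"]
    features.write_feature_csv(table, workdir / "features.csv", labels=labels)
    artifacts["features"] = table


def _stage_search(config: PipelineConfig, workdir: Path, artifacts: dict) -> None:
    table = _require(artifacts, "features", "features")
    roster = _require(artifacts, "roster", "simulate")
    train_ids = roster.loc[roster["split"] == "train", "sample_id"]
    train = table.loc[table.index.intersection(train_ids)]
    labels = roster.set_index("sample_id").loc[train.index, "class"]
    variables = config.search_variables or list(model.FIXED_PUBLISHED_MODEL.variable_names)
    result = model.exhaustive_search(train[variables], labels, variables, c_param=config.c_param)
    model.save_model_state(
        workdir / "model_state.json",
        result.best,
        extra={
            "best_loocv_auc": result.best_loocv_auc,
            "constraint_satisfied": result.constraint_satisfied,
            "config_hash": config.config_hash(),
        },
    )
    result.records.assign(
        variables=result.records["variables"].map(lambda t: "+".join(t))
    ).to_csv(workdir / "search_records.csv", index=False)
    artifacts["search"] = result


def _stage_score(config: PipelineConfig, workdir: Path, artifacts: dict) -> None:
    table = _require(artifacts, "features", "features")
    if "search" in artifacts:
        mdl = artifacts["search"].best
    elif config.paths.model_state_json:
        mdl, _ = model.load_model_state(config.paths.model_state_json)
    else:
        mdl = model.FIXED_PUBLISHED_MODEL
    scores = mdl.detection_index(table)
    calls = mdl.classify(scores)
    out = pd.DataFrame({"detection_index": scores, "positive_call": calls})
    out.to_csv(workdir / "scores.csv")
    artifacts.update(scores=scores, calls=calls, scoring_model=mdl)


def _stage_evaluate(config: PipelineConfig, workdir: Path, artifacts: dict) -> None:
    scores = _require(artifacts, "scores", "score")
    roster = _require(artifacts, "roster", "simulate")
    mdl = artifacts["scoring_model"]
    reports = {}
    for split in ("train", "validation"):
        sub = roster[roster["split"] == split].set_index("sample_id")
        if sub.empty or sub["class"].nunique() < 2:
            continue
        rep = evaluation.evaluate(scores, sub, cutoff=mdl.decision_cutoff)
        reports[split] = rep
    payload = {k: r.to_dict() for k, r in reports.items()}
    payload["config_hash"] = config.config_hash()
    (workdir / "evaluation.json").write_text(json.dumps(payload, indent=2, default=float))
    artifacts["evaluation"] = reports
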