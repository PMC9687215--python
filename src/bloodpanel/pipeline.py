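"""End-to-end orchestration: simulate/ingest -> normalize -> select -> validate.

The pipeline mirrors the two discovery workflows the package supports:

* single-cohort: stratified 80/20 split, transcript selection on the
  training split, discriminant validation of the winning panel on the
  reserved test split;
* paired-cohort: two cohorts with matched feature lists, each used in turn
  as training set with the other as independent test set, plus the
  entry-level overlap of the two winning panels.

All randomness flows from one global seed through fixed, named per-stage
derivations, and the metrics bundle is written with sorted keys so a rerun
under the same configuration is byte-identical (timings are kept in a
separate file).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .expression import (
    ExpressionDataset,
    ProbeAnnotation,
    collapse_to_genes,
    match_probe_ids,
    normalize_to_reference,
    read_expression_matrix,
    stratified_split,
    verify_log2_scale,
)
from .forest import (
    SessionConfig,
    SessionResult,
    run_selection,
    write_panel_tsv,
    write_sessions_json,
)
from .lda import evaluation_report, fit_lda, roc_curve_auc, score_samples, wilks_lambda_test
from .panels import Panel, write_panel
from .simulate import SimulationParams, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_paired_datasets"]

_STAGE_OFFSETS = {"simulate": 0, "split": 1, "selection": 2}
_MOD = 2**31 - 1


def _stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 101 + _STAGE_OFFSETS[stage]) % _MOD


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; exactly one input source."""

    simulation: SimulationParams | None = None
    matrix_path: str | None = None
    labels_path: str | None = None
    annotation_path: str | None = None
    normalize: bool = True
    reference_probe_id: str = "GUSB"
    collapse_genes: bool = False
    test_fraction: float = 0.2
    session: SessionConfig = field(default_factory=SessionConfig.reduced)
    lda_mode: str = "holdout"
    output_dir: str = "bloodpanel_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = self.matrix_path is not None or self.labels_path is not None
        if self.simulation is not None and has_files:
            raise ValueError("supply either simulation parameters or input paths, not both")
        if self.simulation is None and not (self.matrix_path and self.labels_path):
            raise ValueError("supply simulation parameters or both matrix and label paths")
        if self.lda_mode not in ("holdout", "resubstitution"):
            raise ValueError("lda_mode must be 'holdout' or 'resubstitution'")

    @classmethod
    def from_yaml(cls, path, full_profile: bool = False) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        inputs = raw.pop("input", {}) or {}
        session_raw = raw.pop("session", {}) or {}
        seed = int(raw.pop("seed", 0))
        if full_profile:
            session = SessionConfig(base_seed=seed, **session_raw)
        else:
            session = SessionConfig.reduced(base_seed=seed, **session_raw)
        sim_params = None
        if sim is not None:
            sim.setdefault("seed", seed)
            sim_params = SimulationParams(**sim)
        return cls(
            simulation=sim_params,
            matrix_path=inputs.get("matrix"),
            labels_path=inputs.get("labels"),
            annotation_path=inputs.get("annotation"),
            session=session,
            seed=seed,
            **raw,
        )

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            out["simulation"] = dataclasses.asdict(self.simulation)
        out["session"] = dataclasses.asdict(self.session)
        return out


class _Timings:
    def __init__(self) -> None:
        self.stages: dict[str, float] = {}

    def run(self, name, fn):
        t0 = time.perf_counter()
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        finally:
            self.stages[name] = round(time.perf_counter() - t0, 3)


def _prepare(dataset: ExpressionDataset, config: PipelineConfig, timings: _Timings) -> tuple[ExpressionDataset, dict]:
    report = timings.run("verify_log2", lambda: verify_log2_scale(dataset))
    if config.normalize and config.reference_probe_id in dataset.probe_ids:
        dataset = timings.run(
            "normalize", lambda: normalize_to_reference(dataset, config.reference_probe_id)
        )
    elif config.normalize:
        logger.warning(
            "reference probe %r not present; skipping reference normalization",
            config.reference_probe_id,
        )
    if config.collapse_genes:
        if config.annotation_path is None:
            raise ValueError("collapse_genes requires an annotation_path")
        annotation = ProbeAnnotation.read(config.annotation_path)
        dataset = timings.run("collapse", lambda: collapse_to_genes(dataset, annotation))
    scale = {"min": report.minimum, "max": report.maximum, "suspect": report.suspect}
    return dataset, scale


def _validate_panel(
    best: SessionResult,
    train: ExpressionDataset,
    test: ExpressionDataset,
    mode: str,
) -> dict:
    """Discriminant validation of the winning panel.

    Holdout fits on the training split and scores the reserved test split;
    resubstitution fits and scores the pooled samples. Panels wider than
    the evaluation cohort supports (N <= p + 1) are truncated to the
    top-ranked usable features, mirroring how undersized validation
    cohorts are handled in practice.
    """
    panel = best.panel_features
    if mode == "resubstitution":
        pooled_values = train.values.join(test.values)
        fit_data = eval_data = dataclasses.replace(
            train,
            values=pooled_values,
            labels=train.labels.reindex(pooled_values.columns).fillna(test.labels),
        )
    else:
        fit_data, eval_data = train, test
    max_p = min(len(panel), fit_data.n_samples - 2, eval_data.n_samples - 2)
    truncated = False
    if max_p < len(panel):
        panel = panel[:max_p]
        truncated = True
        logger.info("panel truncated to top %d features for LDA validation", max_p)
    model = fit_lda(fit_data, panel)
    scores = score_samples(model, eval_data)
    roc = roc_curve_auc(scores.to_numpy(), eval_data.y, model_threshold=model.threshold)
    sep = wilks_lambda_test(eval_data, panel) if eval_data.n_samples > len(panel) + 1 else None
    report = evaluation_report(model, roc, sep, eval_data)
    report["mode"] = mode
    report["panel_truncated"] = truncated
    return report


def _write_bundle(outdir: Path, name: str, payload: dict) -> Path:
    path = outdir / name
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Execute one single-cohort run and write the report bundle.

    Returns the metrics dictionary; files written: ``config.json``,
    ``seeds.json``, ``metrics.json``, ``sessions.json``, ``panel.tsv``,
    ``timings.json``.
    """
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    timings = _Timings()
    seeds = {stage: _stage_seed(config.seed, stage) for stage in ("simulate", "split", "selection")}

    if config.simulation is not None:
        params = dataclasses.replace(config.simulation, seed=seeds["simulate"])
        dataset, truth = timings.run("simulate", lambda: generate_dataset(params))
        truth_ids = sorted(truth.informative_probe_ids)
    else:
        dataset = timings.run(
            "ingest",
            lambda: read_expression_matrix(config.matrix_path, config.labels_path),
        )
        truth_ids = None

    dataset, scale = _prepare(dataset, config, timings)
    train, test = timings.run(
        "split", lambda: stratified_split(dataset, config.test_fraction, seeds["split"])
    )

    session_config = dataclasses.replace(config.session, base_seed=seeds["selection"])
    sessions, best = timings.run(
        "selection", lambda: run_selection(train, test, session_config)
    )
    lda_report = timings.run("lda_validation", lambda: _validate_panel(best, train, test, config.lda_mode))

    metrics = {
        "config": config.echo(),
        "seeds": seeds,
        "scale_check": scale,
        "n_probes": dataset.n_probes,
        "n_samples": dataset.n_samples,
        "train_sample_ids": list(map(str, train.sample_ids)),
        "test_sample_ids": list(map(str, test.sample_ids)),
        "sessions": [
            {
                "session_index": s.session_index,
                "seed": s.seed,
                "confusion": s.confusion.as_dict(),
                "oob_error": s.oob_error,
            }
            for s in sessions
        ],
        "best_session": {
            "session_index": best.session_index,
            "seed": best.seed,
            "sensitivity": best.sensitivity,
            "specificity": best.specificity,
            "oob_error": best.oob_error,
            "panel": best.panel_features,
        },
        "lda": lda_report,
    }
    if truth_ids is not None:
        planted_in_panel = sorted(set(truth_ids) & set(best.panel_features))
        metrics["ground_truth"] = {
            "informative_probe_ids": truth_ids,
            "planted_in_best_panel": planted_in_panel,
            "n_planted_in_best_panel": len(planted_in_panel),
        }

    _write_bundle(outdir, "config.json", metrics["config"])
    _write_bundle(outdir, "seeds.json", seeds)
    _write_bundle(outdir, "metrics.json", metrics)
    write_sessions_json(sessions, outdir / "sessions.json")
    write_panel_tsv(best, outdir / "panel.tsv")
    _write_bundle(outdir, "timings.json", timings.stages)
    logger.info("pipeline complete; bundle written to %s", outdir)
    return metrics


def run_paired_datasets(
    config: PipelineConfig,
    dataset_a: ExpressionDataset,
    dataset_b: ExpressionDataset,
    output_dir=None,
) -> dict:
    """Paired-cohort selection: train on A / test on B, then the reverse.

    Feature lists are matched first (collapse to genes beforehand when the
    cohorts come from different manufacturers); the report carries both
    winning panels and their entry-level overlap.
    """
    from .lda import intersect_panels

    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = _Timings()
    a, b = timings.run("match", lambda: match_probe_ids(dataset_a, dataset_b))

    bundles = {}
    panels = {}
    # both directions share the session seeds: identical cohorts then yield
    # identical panels, and neither direction is privileged
    session_config = dataclasses.replace(
        config.session, base_seed=_stage_seed(config.seed, "selection")
    )
    for direction, (train, test) in {
        "a_to_b": (a, b),
        "b_to_a": (b, a),
    }.items():
        sessions, best = timings.run(
            f"selection_{direction}",
            lambda tr=train, te=test: run_selection(tr, te, session_config),
        )
        lda_report = _validate_panel(best, train, test, config.lda_mode)
        panels[direction] = Panel.from_ids(best.panel_features, name=direction)
        bundles[direction] = {
            "best_session": {
                "session_index": best.session_index,
                "seed": best.seed,
                "sensitivity": best.sensitivity,
                "specificity": best.specificity,
                "panel": best.panel_features,
            },
            "lda": lda_report,
            "sessions": [
                {"session_index": s.session_index, "confusion": s.confusion.as_dict()}
                for s in sessions
            ],
        }
        write_sessions_json(sessions, outdir / f"sessions_{direction}.json")
        write_panel(panels[direction], outdir / f"panel_{direction}.tsv")

    overlap = intersect_panels(panels["a_to_b"], panels["b_to_a"])
    metrics = {
        "config": config.echo(),
        "directions": bundles,
        "panel_overlap": {
            "n_entries": overlap.n_entries,
            "matched_entries": [e.feature_id for e in overlap.matched_entries],
            "unique_symbols": overlap.unique_symbols,
        },
    }
    _write_bundle(outdir, "metrics.json", metrics)
    _write_bundle(outdir, "timings.json", timings.stages)
    return metrics
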