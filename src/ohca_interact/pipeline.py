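"""End-to-end orchestration: simulate/load -> filter -> encode -> split ->
calibrate + train the four CV models -> evaluate -> counterfactual sweeps.

Every stage derives its seed from the master seed, every written artifact is
recorded in a manifest with its SHA-256 content hash, and identical
(config, seed) pairs reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import cohort as cohort_mod
from . import counterfactual as cf
from .mlp import ClassWeights, NetConfig
from .plotting import render_heatmap
from .predictor import RecordPredictor
from .preprocess import apply_inclusion_filters, default_schema, fit_encode
from .prognet import evaluate, run_cv
from .split import cv_folds, stratified_split

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str | Path = "results"
    cohort_csv: str | Path | None = None          # load this file ...
    cohort: cohort_mod.CohortConfig | None = None  # ... or simulate
    net: NetConfig | None = None                   # input_width filled in later
    seed: int = 0
    target_sensitivity: float = 0.80
    calibrate: bool = True
    class_weights: ClassWeights | None = None
    sweep_axes: dict = field(default_factory=lambda: {
        # transport deltas -10..+10 min step 2; intervention deltas -5..+5 step 1
        "contact_to_arrival": [float(d) for d in range(-10, 11, 2)],
        "contact_to_first_defib": [float(d) for d in range(-5, 6)],
        "contact_to_first_drug": [float(d) for d in range(-5, 6)],
    })
    summary_mode: str = "mean_probability"
    color_limit_percent: float = 6.0
    render: bool = True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence([master, k]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("cohort")
        if config.cohort_csv is not None:
            records = cohort_mod.read_cohort_csv(config.cohort_csv)
        elif config.cohort is not None:
            ccfg = config.cohort
            if config.seed:
                ccfg = replace(ccfg, seed=_derive_seed(config.seed, 0))
            records = cohort_mod.generate_cohort(ccfg)
            cohort_path = out / "cohort.csv"
            cohort_mod.write_cohort_csv(records, cohort_path)
            record("cohort", cohort_path)
        else:
            raise PipelineError(
                "stage cohort: config provides neither a cohort CSV nor a "
                "simulation CohortConfig"
            )

        stage("filter")
        included, tally = apply_inclusion_filters(records)
        included = included.reset_index(drop=True)
        (out / "inclusion.json").write_text(json.dumps(tally, indent=1))
        record("inclusion", out / "inclusion.json")

        stage("encode")
        schema = default_schema()
        labels = included["outcome_cpc12"].to_numpy(dtype=int)

        stage("split")
        plan = stratified_split(labels, k=5, seed=_derive_seed(config.seed, 1))
        (out / "split.json").write_text(plan.to_json())
        record("split", out / "split.json")
        folds = cv_folds(plan)

        # leakage guard: standardization fitted on the non-test records only
        non_test = np.sort(np.concatenate(
            [plan.group_indices(g) for g in range(plan.k) if g != plan.test_group]
        ))
        fit_matrix = fit_encode(included.iloc[non_test], schema)
        predictor_stats = fit_matrix.standardization
        from .preprocess import transform as _transform
        X = _transform(included, schema, predictor_stats).values

        stage("train")
        net = config.net or NetConfig(input_width=schema.width)
        if net.input_width != schema.width:
            raise PipelineError(
                f"stage train: NetConfig.input_width {net.input_width} != schema width {schema.width}"
            )
        net = replace(net, seed=_derive_seed(config.seed, 2))
        ensemble, fold_reports, calibrations = run_cv(
            X, labels, folds, net,
            target_sensitivity=config.target_sensitivity,
            calibrate=config.calibrate,
            class_weights=config.class_weights,
        )
        for i, model in enumerate(ensemble.models):
            p = out / f"model_fold{i}.json"
            p.write_text(json.dumps(model.state_dict()))
            record(f"model_fold{i}", p)

        stage("evaluate")
        test_idx = plan.test_indices
        test_report = evaluate(ensemble, X[test_idx], labels[test_idx])
        report = {
            "folds": [r.as_dict() for r in fold_reports],
            "test": test_report.as_dict(),
            "calibration": [
                None if c is None else
                {"w_pos": c.weights.w_pos, "converged": c.converged, "trace": c.trace}
                for c in calibrations
            ],
        }
        (out / "metrics.json").write_text(json.dumps(report, indent=1))
        record("metrics", out / "metrics.json")

        stage("sweeps")
        test_records = included.iloc[test_idx]
        train_records = included.iloc[non_test]
        predictor = RecordPredictor(ensemble, schema, predictor_stats)

        sweeps = {
            f: cf.single_factor_sweep(predictor, test_records, f,
                                      summary_mode=config.summary_mode)
            for f in cf.DEFAULT_SINGLE_FACTOR_DELTAS
        }
        (out / "single_factor_sweeps.json").write_text(json.dumps(sweeps, indent=1))
        record("single_factor_sweeps", out / "single_factor_sweeps.json")

        transport = config.sweep_axes["contact_to_arrival"]
        for other in ("contact_to_first_defib", "contact_to_first_drug"):
            grid = cf.two_factor_grid(
                predictor, test_records,
                "contact_to_arrival", transport,
                other, config.sweep_axes[other],
                summary_mode=config.summary_mode,
                train_records=train_records,
            )
            tag = "defib" if "defib" in other else "drug"
            grid.to_csv(out / f"grid_{tag}.csv")
            record(f"grid_{tag}", out / f"grid_{tag}.csv")
            (out / f"grid_{tag}.json").write_text(json.dumps(grid.sidecar(), indent=1))
            record(f"grid_{tag}_sidecar", out / f"grid_{tag}.json")
            if config.render:
                render_heatmap(grid, out / f"grid_{tag}.svg",
                               color_limit_percent=config.color_limit_percent)
                record(f"grid_{tag}_svg", out / f"grid_{tag}.svg")
    except PipelineError:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    except Exception as exc:  # annotate with the failing stage, keep partial manifest
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(f"stage {manifest['stages'][-1]}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
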