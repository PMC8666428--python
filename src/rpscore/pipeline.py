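"""End-to-end pipeline: synthesize -> benchmark -> derive -> compare -> stratify.

``run_pipeline`` executes the whole workflow from one
:class:`PipelineConfig` and writes deterministic artifacts (CSV/JSON) plus
a manifest recording the config hash and seed, so a rerun with the same
config reproduces identical numbers.  The single master seed fans out to
stage seeds by fixed offsets of a seed sequence, so partial reruns stay
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import BenchConfig, run_benchmark
from .cohort import SynthConfig, generate_cohort, read_cohort, write_cohort
from .score import (
    PUBLISHED_RPS,
    compare_predictors,
    derive_score,
    score_frame,
    stratify_quartiles,
)
from .splitting import SplitConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings; sub-configs validate themselves."""

    outdir: str = "results"
    cohort_csv: str | None = None  # load instead of synthesizing when set
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    bench: BenchConfig = field(default_factory=BenchConfig)
    score_model_kind: str = "ridge"
    score_feature_set: str = "clinical_early"
    k_max: int = 10
    use_published_rps: bool = False

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        d = _jsonable(asdict(self))
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest (also written).

    Artifacts: cohort CSV, benchmark table, importance table, score JSON,
    comparison CSV, stratification CSV, P-value curve CSV, manifest JSON.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "synth"
    try:
        if config.cohort_csv:
            cohort = read_cohort(config.cohort_csv)
        else:
            seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)
            synth = SynthConfig(**{**asdict(config.synth), "seed": int(seeds[0])})
            cohort = generate_cohort(synth).table
        path = out / "cohort.csv"
        write_cohort(cohort, path)
        artifacts["cohort"] = str(path)
        logger.info("stage=synth n=%d seed=%d", len(cohort), config.seed)

        stage = "bench"
        bench_cfg = BenchConfig(
            **{**_bench_kwargs(config.bench), "master_seed": config.seed,
               "split": config.split}
        )
        table, _ = run_benchmark(cohort, bench_cfg)
        path = out / "benchmark.csv"
        table.to_csv(path, index=False)
        artifacts["benchmark"] = str(path)

        stage = "derive-score"
        if config.use_published_rps:
            defn = PUBLISHED_RPS
            importance_df = pd.DataFrame(
                {"feature": [f for f, _ in defn.terms],
                 "beta_raw": [w for _, w in defn.terms]}
            )
            curve = pd.DataFrame({"K": [defn.k_o], "p_value": [np.nan]})
            logger.info("stage=derive-score skipped: published constants in use")
        else:
            defn, importance, curve, _ = derive_score(
                cohort,
                n_repeats=bench_cfg.n_repeats,
                master_seed=config.seed,
                model_kind=config.score_model_kind,
                feature_set=config.score_feature_set,
                k_max=config.k_max,
                split=config.split,
            )
            importance_df = importance.table
        (out / "score.json").write_text(defn.to_json())
        artifacts["score"] = str(out / "score.json")
        importance_df.to_csv(out / "importance.csv", index=False)
        artifacts["importance"] = str(out / "importance.csv")
        curve.to_csv(out / "pvalue_curve.csv", index=False)
        artifacts["pvalue_curve"] = str(out / "pvalue_curve.csv")

        stage = "compare"
        comparison = compare_predictors(cohort, defn)
        comparison.to_csv(out / "comparison.csv", index=False)
        artifacts["comparison"] = str(out / "comparison.csv")

        stage = "stratify"
        report = stratify_quartiles(score_frame(defn, cohort), cohort)
        strat = report.to_frame()
        strat.insert(0, "threshold_q1", report.thresholds[0])
        strat.insert(1, "threshold_median", report.thresholds[1])
        strat.insert(2, "threshold_q3", report.thresholds[2])
        strat.to_csv(out / "stratification.csv", index=False)
        artifacts["stratification"] = str(out / "stratification.csv")
    except Exception as exc:
        manifest = _manifest(config, artifacts, failed_stage=stage, error=str(exc))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest = _manifest(config, artifacts)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    manifest["artifacts"]["manifest"] = str(path)
    return manifest


def _bench_kwargs(bench: BenchConfig) -> dict:
    return {
        "n_repeats": bench.n_repeats,
        "model_kinds": bench.model_kinds,
        "feature_sets": bench.feature_sets,
        "selection_p": bench.selection_p,
        "grids": bench.grids,
    }


def _manifest(config, artifacts, failed_stage=None, error=None) -> dict:
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "rpscore_version": __version__,
        "artifacts": dict(artifacts),
    }
    if failed_stage is not None:
        manifest["failed_stage"] = failed_stage
        manifest["error"] = error
    return manifest
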