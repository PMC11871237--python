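"""End-to-end orchestration with one config, consistent seeding and a manifest.

A run executes the requested stages in dependency order on synthetic data
(or user-supplied files), writes every stage's outputs under the run
directory, and records a manifest (config hash, per-stage seeds, output
checksums) so a rerun with the same config reproduces the deterministic
stages bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import riskmodel, silicon, spatialcoloc, syndata, validation
from .lrpairs import CutoffSearchConfig

logger = logging.getLogger("lrscape")

__all__ = ["RunConfig", "run_all", "stage_seed"]

_STAGE_ORDER = ["bulk", "spatial", "wsi"]

# declared counter scheme: one global seed expands to per-stage seeds
_SEED_STRIDE = 1_000_003


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global_seed + stride * stage index."""
    return (int(global_seed) + _SEED_STRIDE * (_STAGE_ORDER.index(stage) + 1)) % (2**31 - 1)


@dataclass
class RunConfig:
    out_dir: str = "lrscape_run"
    seed: int = 666
    stages: tuple = ("bulk", "spatial", "wsi")
    bulk: dict = field(default_factory=dict)       # BulkCohortSpec overrides
    spatial: dict = field(default_factory=dict)    # SpatialSlideSpec overrides
    wsi: dict = field(default_factory=dict)        # SyntheticWsiSpec overrides
    alpha: float = 0.05
    ntree: int = 300
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path):
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config: RunConfig) -> dict:
    """Execute the requested stages and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.digest(), "seed": config.seed,
                      "stages": {}, "outputs": {}}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _checksum(path)}

    for stage in config.stages:
        if stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}")

    stage = "setup"
    try:
        if "bulk" in config.stages:
            stage = "bulk"
            seed = stage_seed(config.seed, "bulk")
            manifest["stages"]["bulk"] = {"seed": seed}
            logger.info("bulk stage: screening cascade (seed %d)", seed)
            spec = syndata.BulkCohortSpec(**{"seed": seed, **config.bulk})
            model, cohort, screened, retained = validation.run_cascade(
                spec, alpha=config.alpha, ntree=config.ntree, seed=seed)
            _write_tsv(cohort.scores.to_frame().reset_index(names="pair"),
                       out / "pair_scores.tsv")
            _write_tsv(cohort.survival_frame(), out / "survival.tsv")
            pd.Series(screened, name="pair").to_csv(out / "screened_pairs.tsv",
                                                    sep="\t", index=False)
            record("pair_scores", out / "pair_scores.tsv")
            record("survival", out / "survival.tsv")
            record("screened_pairs", out / "screened_pairs.tsv")
            if model is not None:
                (out / "cox_model.json").write_text(
                    json.dumps(model.to_json_dict(), indent=2, sort_keys=True))
                record("cox_model", out / "cox_model.json")
                eta = riskmodel.risk_score(cohort.scores, model)
                strat = riskmodel.stratify(eta, cohort.os,
                                           CutoffSearchConfig(), seed=seed)
                comparison = riskmodel.compare_groups(strat, cohort.os)
                _write_tsv(strat.to_frame(), out / "risk_groups.tsv")
                record("risk_groups", out / "risk_groups.tsv")
                (out / "group_comparison.json").write_text(json.dumps({
                    "logrank_stat": comparison.logrank_stat,
                    "p_value": comparison.p_value,
                    "cutoff": strat.cutoff,
                    "n_high": int(np.sum(strat.group == "high")),
                    "n_low": int(np.sum(strat.group == "low")),
                }, indent=2))
                record("group_comparison", out / "group_comparison.json")
            manifest["stages"]["bulk"]["screened"] = screened
            manifest["stages"]["bulk"]["retained"] = retained

        if "spatial" in config.stages:
            stage = "spatial"
            seed = stage_seed(config.seed, "spatial")
            manifest["stages"]["spatial"] = {"seed": seed}
            logger.info("spatial stage: colocalization (seed %d)", seed)
            spec = syndata.SpatialSlideSpec(**{"seed": seed, **config.spatial})
            slide = syndata.gen_spatial_slide(spec)
            result = spatialcoloc.knn_interaction_score(slide)
            slide.to_frame().to_csv(out / "spots.csv", index=False)
            result.to_frame().to_csv(out / "coloc_result.csv", index=False)
            _write_tsv(spatialcoloc.coloc_summary(result).reset_index(),
                       out / "coloc_summary.tsv")
            spatialcoloc.plot_coloc(slide, result, out / "coloc_plot.png")
            record("spots", out / "spots.csv")
            record("coloc_result", out / "coloc_result.csv")
            record("coloc_summary", out / "coloc_summary.tsv")

        if "wsi" in config.stages:
            stage = "wsi"
            seed = stage_seed(config.seed, "wsi")
            manifest["stages"]["wsi"] = {"seed": seed}
            logger.info("wsi stage: Silicon pipeline (seed %d)", seed)
            spec = syndata.SyntheticWsiSpec(
                **{"seed": seed, **{**validation.WSI_SPEC, **config.wsi}})
            wsi = syndata.gen_synthetic_wsis(spec)
            dataset = validation.build_silicon_dataset(wsi)
            result = silicon.run_silicon_pipeline(
                dataset, split_cfg=silicon.SplitConfig(seed=seed), seed=seed)
            _write_tsv(result["cluster_accuracy"], out / "cluster_accuracy.tsv")
            record("cluster_accuracy", out / "cluster_accuracy.tsv")
            report = {}
            for arm in ("selection", "no_selection"):
                rep = result[arm]["report"]
                report[arm] = {"accuracy": rep.accuracy, "auc": rep.auc,
                               "confusion": rep.confusion,
                               "clusters": result[arm]["clusters"]}
                _write_tsv(rep.predictions, out / f"predictions_{arm}.tsv")
                record(f"predictions_{arm}", out / f"predictions_{arm}.tsv")
            (out / "silicon_report.json").write_text(json.dumps(report, indent=2))
            record("silicon_report", out / "silicon_report.json")
            manifest["stages"]["wsi"]["selected_clusters"] = result["selected_clusters"]
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
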