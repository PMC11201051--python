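"""End-to-end orchestration: thin → screen → fit replicates → map → report.

One declarative configuration drives the whole analysis and every
artifact lands under one output directory with fixed names, so re-running
with the same configuration and seed reproduces every CSV/ASC byte for
byte.  A single master seed fans out to per-stage seeds through the
documented counter scheme ``stage_seed(master, k) = (master·1000 + k)
mod 2³¹``, keeping stages reproducible independently of each other.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import SplitSpec, replicate_runs
from .grid_io import GridStack, align_stack, read_asc, write_asc
from .habitat import (binary_map, centroid, change_map, classify,
                      class_areas, migration_vector)
from .maxent import (TrainConfig, fit, jackknife_gains, permutation_importance,
                     response_curve)
from .occurrence import read_occurrences, thin
from .screening import screen_variables

logger = logging.getLogger("nichemax")

STAGE_THIN, STAGE_SCREEN, STAGE_EVAL, STAGE_IMPORTANCE = 0, 1, 2, 3
STAGE_RESPONSE, STAGE_PERMUTATION = 4, 5


def stage_seed(master: int, k: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (master * 1000 + k) % (2 ** 31)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    occurrences: str
    scenarios: dict[str, str]          # scenario name -> directory of .asc
    baseline: str = "current"
    out_dir: str = "nichemax_run"
    seed: int = 0
    thin_radius_km: float = 5.0
    correlation_threshold: float = 0.8
    suitability_thresholds: tuple[float, float, float] = (0.1, 0.3, 0.5)
    presence_threshold: float = 0.5
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    response_variables: int = 6        # top-contribution variables to curve

    def __post_init__(self) -> None:
        if self.baseline not in self.scenarios:
            raise ValueError(f"baseline '{self.baseline}' not among scenarios "
                             f"{list(self.scenarios)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        train = TrainConfig(**raw.pop("train", {}))
        split = SplitSpec(**raw.pop("split", {}))
        if "suitability_thresholds" in raw:
            raw["suitability_thresholds"] = tuple(raw["suitability_thresholds"])
        return cls(train=train, split=split, **raw)


def load_scenario_stack(directory: str | Path) -> GridStack:
    """Read every .asc layer in a directory (sorted by file name)."""
    paths = sorted(Path(directory).glob("*.asc"))
    if not paths:
        raise FileNotFoundError(f"no .asc layers in {directory}")
    return align_stack([read_asc(p) for p in paths])


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the artifact directory.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: dict[str, float] = {}

    def timed(stage: str):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", stage)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                timings[stage] = time.perf_counter() - self_.t0
                if exc is None:
                    logger.info("stage %s: done in %.2fs", stage, timings[stage])
                    return False
                logger.error("stage %s: FAILED (%s)", stage, exc)
                raise PipelineError(stage, exc) from exc
        return _T()

    master = config.seed
    try:
        with timed("thin"):
            occ = read_occurrences(config.occurrences)
            occ = thin(occ, config.thin_radius_km)
            occ.write_csv(out / "thinned_occurrences.csv")

        with timed("load_layers"):
            stacks = {name: load_scenario_stack(d)
                      for name, d in config.scenarios.items()}
            baseline_stack = stacks[config.baseline]

        with timed("screen"):
            train_cfg = dataclasses.replace(
                config.train, seed=stage_seed(master, STAGE_SCREEN))
            report = screen_variables(baseline_stack, occ, train_cfg,
                                      threshold=config.correlation_threshold)
            report.rounds_frame().to_csv(out / "screening_rounds.csv",
                                         index=False)
            (out / "screening_decisions.json").write_text(
                json.dumps({"final_variables": report.final_variables,
                            "decisions": report.decision_log()}, indent=2))
            variables = report.final_variables
            model_stacks = {n: s.subset(variables) for n, s in stacks.items()}

        with timed("evaluate"):
            eval_cfg = dataclasses.replace(
                train_cfg, seed=stage_seed(master, STAGE_EVAL))
            split = dataclasses.replace(
                config.split, seed=stage_seed(master, STAGE_EVAL))
            result = replicate_runs(model_stacks[config.baseline], occ,
                                    eval_cfg, split, keep_models=True)
            df = result.to_frame()
            df.to_csv(out / "evaluation.csv", index=False,
                      float_format="%.3f")
            (out / "evaluation_summary.json").write_text(json.dumps(
                {"mean_auc": result.mean_auc, "grade": result.grade,
                 "replicates": split.replicates}, indent=2))

        with timed("project"):
            mean_maps = {}
            for name, s in model_stacks.items():
                total = None
                for r, model in enumerate(result.models):
                    grid = model.project(s)
                    write_asc(grid, out / f"suitability_{name}_rep{r:03d}.asc")
                    total = grid.values if total is None else total + grid.values
                mean = grid.with_values(total / len(result.models),
                                        name=f"suitability_{name}_mean")
                write_asc(mean, out / f"suitability_{name}_mean.asc")
                mean_maps[name] = mean

        with timed("importance"):
            imp_cfg = dataclasses.replace(
                eval_cfg, seed=stage_seed(master, STAGE_IMPORTANCE))
            full_model, full_data = fit(model_stacks[config.baseline], occ,
                                        imp_cfg)
            contrib = full_model.percent_contribution()
            perm = permutation_importance(
                full_model, full_data,
                seed=stage_seed(master, STAGE_PERMUTATION))
            pd.DataFrame({"percent_contribution": contrib,
                          "permutation_importance": perm}
                         ).rename_axis("variable").to_csv(
                out / "importance.csv", float_format="%.4f")
            full_model.to_json(out / "model.json")
            jk = jackknife_gains(model_stacks[config.baseline], occ, imp_cfg)
            jk_df = jk.to_frame()
            jk_df["gain_full"] = jk.gain_full
            jk_df.rename_axis("variable").to_csv(out / "jackknife.csv",
                                                 float_format="%.6f")

        with timed("response_curves"):
            top = contrib.sort_values(ascending=False) \
                         .head(config.response_variables).index
            resp_cfg = dataclasses.replace(
                imp_cfg, seed=stage_seed(master, STAGE_RESPONSE))
            curve_rows, range_rows = [], []
            for v in top:
                curve = response_curve(v, model_stacks[config.baseline], occ,
                                       resp_cfg)
                for x, p in zip(curve.values, curve.probability):
                    curve_rows.append({"variable": v, "value": x,
                                       "probability": p})
                for lo, hi in curve.optimal_range():
                    range_rows.append({"variable": v, "lower": lo, "upper": hi})
            pd.DataFrame(curve_rows).to_csv(out / "response_curves.csv",
                                            index=False, float_format="%.6f")
            pd.DataFrame(range_rows,
                         columns=["variable", "lower", "upper"]).to_csv(
                out / "optimal_ranges.csv", index=False, float_format="%.6f")

        with timed("classify"):
            classifications = {
                name: classify(mean_maps[name], config.suitability_thresholds)
                for name in mean_maps}
            for name, cl in classifications.items():
                write_asc(cl.class_grid, out / f"classification_{name}.asc")
            base_summary = class_areas(classifications[config.baseline],
                                       period=config.baseline)
            rows = [base_summary.delta_vs(base_summary).to_row()]
            for name, cl in classifications.items():
                if name == config.baseline:
                    continue
                rows.append(class_areas(cl, baseline=base_summary,
                                        period=name).to_row())
            pd.DataFrame(rows).to_csv(out / "areas.csv", index=False)

        with timed("change"):
            ranges = {name: binary_map(mean_maps[name],
                                       config.presence_threshold)
                      for name in mean_maps}
            change_rows = []
            for name in mean_maps:
                if name == config.baseline:
                    continue
                cm = change_map(ranges[config.baseline], ranges[name],
                                current_period=config.baseline,
                                future_period=name)
                write_asc(cm.grid, out / f"change_{name}.asc")
                change_rows.append(cm.to_row())
            pd.DataFrame(change_rows,
                         columns=["period", "expansion", "retention",
                                  "contraction", "net_change"]).to_csv(
                out / "changes.csv", index=False)

        with timed("centroid"):
            cents, migr_rows = {}, []
            for name in mean_maps:
                try:
                    cents[name] = centroid(ranges[name], period=name)
                except ValueError:
                    logger.info("scenario %s: empty range, no centroid", name)
            pd.DataFrame([{"period": n, "longitude": c.longitude,
                           "latitude": c.latitude}
                          for n, c in cents.items()]).to_csv(
                out / "centroids.csv", index=False, float_format="%.6f")
            for name, c in cents.items():
                if name == config.baseline or config.baseline not in cents:
                    continue
                mv = migration_vector(cents[config.baseline], c)
                migr_rows.append({"from": config.baseline, "to": name,
                                  "distance_km": round(mv.distance_km, 3),
                                  "bearing_deg": round(mv.bearing_deg, 3)})
            pd.DataFrame(migr_rows,
                         columns=["from", "to", "distance_km",
                                  "bearing_deg"]).to_csv(
                out / "migration.csv", index=False)

        provenance = {
            "nichemax_version": __version__,
            "numpy_version": np.__version__,
            "master_seed": master,
            "stage_seeds": {s: stage_seed(master, k) for s, k in
                            [("screen", STAGE_SCREEN), ("evaluate", STAGE_EVAL),
                             ("importance", STAGE_IMPORTANCE),
                             ("response", STAGE_RESPONSE),
                             ("permutation", STAGE_PERMUTATION)]},
            "config": _config_dict(config),
            "final_variables": variables,
            "n_occurrences_thinned": len(occ),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["train"]["feature_classes"] = sorted(config.train.feature_classes)
    return d
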