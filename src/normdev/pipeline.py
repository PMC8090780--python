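"""End-to-end orchestration: simulate -> fit -> deviate -> groupstats ->
glm -> overlap, with a YAML-round-trippable configuration and an output
manifest carrying checksums of every artifact."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .glm import DesignSpec, build_group_design, permutation_inference
from .gpr import (compute_z, crossvalidated_z, evaluate_model, fit_normative,
                  forward_model_slopes)
from .metrics import extreme_score_table, threshold_npm
from .group_stats import group_comparisons, prevalence_ratio, symptom_correlations
from .overlap import overlap_map, peak_table, stratified_overlap
from .simulate import GeneratorConfig, generate_cohort, generate_voxel_data

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("normdev")

_STAGES = ("simulate", "fit", "deviate", "groupstats", "glm", "overlap")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips through YAML."""

    out_dir: str = "normdev_out"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    stages: tuple[str, ...] = _STAGES
    thresholds: tuple[float, ...] = (1.96, 2.6, 3.1)
    fdr_q: float = 0.05
    primary_threshold: float = 2.6
    k_folds: int = 10
    n_permutations: int = 1000
    gp_voxel_subsample: int = 15
    gp_restarts: int = 2
    seeds: dict = field(default_factory=lambda: {
        "simulate": 0, "fit": 1, "cv": 2, "glm": 3,
    })
    log_level: str = "INFO"

    def to_yaml(self, path) -> Path:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(d), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d and not isinstance(d["generator"], GeneratorConfig):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key in ("stages", "thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _plain(obj):
    """Recursively convert numpy/tuple values to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the output manifest.

    Every file written is listed in the manifest with its sha256; the
    manifest also records the full configuration (defaults included) so a
    rerun with the same config and seeds is bit-reproducible.  A stage
    failure raises :class:`PipelineError` carrying the partial manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _plain({**asdict(config),
                          "generator": config.generator.to_dict()}),
        "files": {},
        "stages_completed": [],
        "summary": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": str(path), "sha256": nio.sha256_of(path),
        }

    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.time()
            log.info("stage %s ...", stage)
            _run_stage(stage, config, out, state, manifest, record)
            manifest["stages_completed"].append(stage)
            log.info("stage %s done in %.1fs", stage, time.time() - t0)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        stage = next(s for s in config.stages
                     if s not in manifest["stages_completed"])
        nio.write_manifest(manifest, out / "manifest.partial.json")
        raise PipelineError(stage, manifest, exc) from exc

    path = nio.write_manifest(manifest, out / "manifest.json")
    manifest["manifest_path"] = str(path)
    return manifest


def _run_stage(stage, config, out, state, manifest, record):
    gen = config.generator
    if stage == "simulate":
        gen_cfg = GeneratorConfig.from_dict(
            {**gen.to_dict(), "seed": config.seeds.get("simulate", gen.seed)}
        )
        cohort = generate_cohort(gen_cfg)
        space, Y, truth = generate_voxel_data(cohort, gen_cfg)
        state.update(cohort=cohort, space=space, Y=Y, truth=truth)
        record("cohort", nio.write_cohort(
            cohort.drop(columns=["lesion_burden_true"]), out / "cohort.tsv"))
        record("mask", nio.write_mask(space, out / "mask.nii"))
        record("gm_stack", nio.write_stack(Y, space, out / "gm.nii",
                                           dtype=np.float32))
        return

    cohort, space, Y = state["cohort"], state["space"], state["Y"]
    healthy = cohort["group"].to_numpy() == "HC"
    X = cohort[["age", "sex"]].to_numpy(float)

    if stage == "fit":
        model = fit_normative(
            Y[healthy], X[healthy],
            n_voxel_subsample=config.gp_voxel_subsample,
            n_restarts=config.gp_restarts,
            seed=config.seeds.get("fit", 1),
        )
        state["model"] = model
        slopes = forward_model_slopes(model)
        for name, vals in slopes.items():
            record(name, nio.write_map(vals, space, out / f"{name}.nii"))
        return

    if stage == "deviate":
        model = state["model"]
        cv, cv_pred = crossvalidated_z(
            Y[healthy], X[healthy], k=config.k_folds,
            seed=config.seeds.get("cv", 2),
            n_voxel_subsample=config.gp_voxel_subsample,
            n_restarts=config.gp_restarts,
            return_predictions=True,
        )
        pred_patients = model.predict(X[~healthy], warn_extrapolation=False)
        transfer = compute_z(Y[~healthy], pred_patients)
        Z = np.empty_like(Y)
        Z[healthy] = cv.Z
        Z[~healthy] = transfer.Z
        state["Z"] = Z
        state["cv_folds"] = cv.cv_folds
        scores = extreme_score_table(
            Z, cohort["subject_id"], thresholds=config.thresholds,
            fdr_q=config.fdr_q,
        )
        state["scores"] = scores
        record("z_stack", nio.write_stack(Z, space, out / "zmaps.nii",
                                          dtype=np.float32))
        scores.to_csv(out / "extreme_scores.tsv", sep="\t", index=False)
        record("extreme_scores", out / "extreme_scores.tsv")
        # out-of-fold predicted vs observed performance map (healthy)
        r_map = evaluate_model(cv_pred.mean, Y[healthy])
        state["model_r_map"] = r_map
        record("model_r_map", nio.write_map(np.nan_to_num(r_map), space,
                                            out / "model_r.nii"))
        return

    scores = state["scores"]
    primary = scores[scores["threshold"] == f"|Z|>{config.primary_threshold:g}"]

    if stage == "groupstats":
        comp = group_comparisons(primary, cohort)
        comp.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
        record("group_comparisons", out / "group_comparisons.tsv")
        corr = symptom_correlations(primary, cohort)
        corr.to_csv(out / "symptom_correlations.tsv", sep="\t", index=False)
        record("symptom_correlations", out / "symptom_correlations.tsv")
        means = primary.merge(cohort[["subject_id", "group"]],
                              on="subject_id").groupby("group")["pct_negative"].mean()
        if "SZ" in means and "HC" in means and means["HC"] > 0:
            manifest["summary"]["prevalence_ratio_sz_hc"] = prevalence_ratio(
                means["SZ"], means["HC"])
        return

    if stage == "glm":
        spec = build_group_design(cohort["group"].to_numpy())
        spec = DesignSpec(
            design=spec.design, contrasts=spec.contrasts,
            n_permutations=config.n_permutations,
            seed=config.seeds.get("glm", 3),
            column_names=spec.column_names,
        )
        res = permutation_inference(state["Z"], spec)
        state["glm"] = res
        for name, pvals in res.p_fwer.items():
            record(f"glm_1mp_{name}", nio.write_map(
                1.0 - pvals, space, out / f"glm_1mp_{name}.nii"))
        for gname, mz in res.group_mean_z.items():
            record(f"mean_z_{gname}", nio.write_map(
                mz, space, out / f"mean_z_{gname}.nii"))
        return

    if stage == "overlap":
        neg, pos = threshold_npm(state["Z"], config.primary_threshold)
        groups = cohort["group"].to_numpy()
        thr_label = f"|Z|>{config.primary_threshold:g}"
        maps = {}
        for tail, masks in (("negative", neg), ("positive", pos)):
            omaps = overlap_map(masks, groups, space, tail=tail,
                                threshold=thr_label)
            maps.update({f"{g}_{tail}": m for g, m in omaps.items()})
            for g, m in omaps.items():
                record(f"overlap_{g}_{tail}", nio.write_map(
                    100.0 * m.proportion, space,
                    out / f"overlap_{g}_{tail}.nii"))
        strat = stratified_overlap(neg, groups, cohort["sex"].to_numpy(),
                                   space, tail="negative", threshold=thr_label)
        state["overlap"] = maps
        state["overlap_stratified"] = strat
        table = peak_table(maps)
        table.to_csv(out / "overlap_peaks.tsv", sep="\t", index=False)
        record("overlap_peaks", out / "overlap_peaks.tsv")
        manifest["summary"]["peak_overlap_pct"] = {
            k: m.peak_value for k, m in maps.items()
        }
        return

    raise ValueError(f"unknown stage {stage!r}")
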