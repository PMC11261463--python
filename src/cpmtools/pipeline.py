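"""End-to-end workflow: simulate -> CPM -> seed comparison -> partial
correlation -> subtype classification.

Stage outputs are plain TSV/JSON files; ``manifest.json`` captures the
configuration, seeds, package version and per-stage products so a run
can be reproduced exactly from its manifest. Stage order follows the
analysis dependencies: the CPM consensus network's hub nodes seed the
group comparison, and the group comparison's top edge is the default
classification feature.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortSpec, generate_cohort, read_cohort, write_cohort
from .cpm import CPMConfig, CPMResult, permutation_test, run_cpm
from .stats import partial_correlation, seed_fc_compare
from .svm import DEFAULT_C_GRID, DEFAULT_G_GRID, grid_search_cv

log = logging.getLogger("cpmtools")

ALL_STAGES = ("simulate", "cpm", "groupdiff", "partialcorr", "classify")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: str | Path = "cpm_out"
    cohort_dir: str | Path | None = None       # None -> simulate
    stages: tuple[str, ...] = ALL_STAGES
    spec: CohortSpec = field(default_factory=CohortSpec)
    cpm: CPMConfig = field(default_factory=CPMConfig)
    seeds_override: tuple[int, ...] | None = None  # group-comparison seed nodes
    classify_edge: tuple[int, int] | None = None
    partialcorr_scores: tuple[str, ...] = ("teps_consummatory", "teps_total")
    partialcorr_covariates: tuple[str, ...] = (
        "age", "education", "illness_duration", "fd")
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    g_grid: tuple[float, ...] = DEFAULT_G_GRID
    svm_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        if self.cohort_dir is not None and not Path(self.cohort_dir).exists():
            raise ValueError(f"cohort directory {self.cohort_dir} does not exist")
        if self.cohort_dir is None and "simulate" not in self.stages:
            raise ValueError("no cohort_dir given and 'simulate' not among stages")


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = ALL_STAGES.index(stage)
    return int(np.random.default_rng([int(master), idx]).integers(0, 2**31 - 1))


def _write_cpm_outputs(out: Path, result: CPMResult, cohort: Cohort) -> list[str]:
    out.mkdir(parents=True, exist_ok=True)
    files = []
    df = pd.DataFrame({"id": result.predictions.index,
                       "observed": result.observed.to_numpy(),
                       "predicted": result.predictions.to_numpy()})
    df.to_csv(out / "predictions.tsv", sep="\t", index=False)
    files.append("predictions.tsv")
    names = cohort.atlas.df["name"].to_numpy()
    edges = result.consensus_mask.edge_list()
    pd.DataFrame([{"node_i": i, "node_j": j,
                   "name_i": names[i], "name_j": names[j]}
                  for i, j in edges]).to_csv(
        out / "edges_positive.tsv", sep="\t", index=False)
    files.append("edges_positive.tsv")
    pd.DataFrame([{"node": d.node, "name": names[d.node], "degree": d.degree,
                   "is_hub": d.is_hub} for d in result.degrees]).to_csv(
        out / "degrees.tsv", sep="\t", index=False)
    files.append("degrees.tsv")
    payload = {
        "r_obs": result.r_obs, "mse": result.mse, "p_perm": result.p_perm,
        "n_consensus_edges": result.consensus_mask.n_selected,
        "empty_mask_folds": result.empty_mask_folds,
        "n_null_failures": result.n_null_failures,
        "hubs": result.hubs(),
        "config": dataclasses.asdict(result.config),
    }
    (out / "result.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    files.append("result.json")
    if result.null_distribution is not None:
        np.savetxt(out / "null_r.tsv", result.null_distribution, fmt="%.10g")
        files.append("null_r.tsv")
    return files


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config.validate()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "stage_seeds": {},
        "outputs": {},
    }

    cohort: Cohort | None = None
    stage = "simulate"
    try:
        if "simulate" in config.stages and config.cohort_dir is None:
            spec = dataclasses.replace(config.spec,
                                       seed=_stage_seed(config.seed, "simulate"))
            manifest["stage_seeds"]["simulate"] = spec.seed
            log.info("simulate: generating cohort (seed %d)", spec.seed)
            cohort = generate_cohort(spec)
            cdir = out_root / "cohort"
            write_cohort(cohort, cdir)
            manifest["outputs"]["simulate"] = str(cdir)
        else:
            cohort = read_cohort(config.cohort_dir)
            manifest["outputs"]["simulate"] = str(config.cohort_dir)

        cpm_result: CPMResult | None = None
        hubs: list[int] = []
        if "cpm" in config.stages:
            stage = "cpm"
            cpm_cfg = dataclasses.replace(config.cpm,
                                          seed=_stage_seed(config.seed, "cpm"))
            manifest["stage_seeds"]["cpm"] = cpm_cfg.seed
            log.info("cpm: LOOCV + %d permutations", cpm_cfg.n_permutations)
            cpm_result = run_cpm(cohort, cpm_cfg)
            cpm_result = permutation_test(cohort, cpm_cfg, result=cpm_result)
            files = _write_cpm_outputs(out_root / "cpm", cpm_result, cohort)
            manifest["outputs"]["cpm"] = files
            hubs = cpm_result.hubs()
            if not hubs:  # fall back to the two highest-degree nodes
                hubs = [d.node for d in cpm_result.degrees[:2] if d.degree > 0]

        top_edge: tuple[int, int] | None = config.classify_edge
        if "groupdiff" in config.stages:
            stage = "groupdiff"
            seeds = (list(config.seeds_override)
                     if config.seeds_override is not None else hubs)
            if not seeds:
                raise PipelineError(
                    "groupdiff: no seed nodes (no hubs found and no override)")
            log.info("groupdiff: seeds %s", seeds)
            comps = seed_fc_compare(cohort, seeds)
            gdir = out_root / "groupdiff"
            gdir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame([dataclasses.asdict(c) for c in comps]).to_csv(
                gdir / "seed_fc.tsv", sep="\t", index=False)
            manifest["outputs"]["groupdiff"] = ["seed_fc.tsv"]
            if top_edge is None and comps:
                best = comps[0]
                top_edge = (min(best.seed, best.target), max(best.seed, best.target))

        if "partialcorr" in config.stages:
            stage = "partialcorr"
            if top_edge is None:
                raise PipelineError("partialcorr: no edge selected (run groupdiff "
                                    "or set classify_edge)")
            patients = cohort.patients()
            x = patients.edge_values(*top_edge)
            Z = patients.covariate_matrix(config.partialcorr_covariates)
            rows = []
            for score in config.partialcorr_scores:
                res = partial_correlation(
                    x, patients.behavior_vector(score), Z,
                    x_name=f"fc_{top_edge[0]}_{top_edge[1]}", y_name=score,
                    covariate_names=config.partialcorr_covariates,
                    family_size=len(config.partialcorr_scores))
                rows.append(dataclasses.asdict(res))
            pdir = out_root / "partialcorr"
            pdir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(rows).to_csv(pdir / "partial_corr.tsv", sep="\t",
                                      index=False)
            manifest["outputs"]["partialcorr"] = ["partial_corr.tsv"]

        if "classify" in config.stages:
            stage = "classify"
            if top_edge is None:
                raise PipelineError("classify: no feature edge (run groupdiff or "
                                    "set classify_edge)")
            svm_seed = _stage_seed(config.seed, "classify")
            manifest["stage_seeds"]["classify"] = svm_seed
            patients = cohort.patients()
            log.info("classify: edge %s, %d-fold CV", top_edge, config.svm_k)
            res = grid_search_cv(
                patients.edge_values(*top_edge), patients.group_labels(),
                c_grid=config.c_grid, g_grid=config.g_grid, k=config.svm_k,
                seed=svm_seed, subject_ids=patients.ids(),
                positive_label="melancholic")
            cdir = out_root / "classify"
            cdir.mkdir(parents=True, exist_ok=True)
            payload = {
                "feature_edge": list(top_edge),
                "confusion": dataclasses.asdict(res.confusion),
                "sensitivity": res.sensitivity, "specificity": res.specificity,
                "accuracy": res.accuracy,
                "se_accuracy": res.se_accuracy,
                "se_sensitivity": res.se_sensitivity,
                "se_specificity": res.se_specificity,
                "se_definition": "sd of per-fold metric / sqrt(k)",
                "best_c": res.best_c, "best_g": res.best_g,
                "seed": res.seed,
                **res.as_percentages(),
            }
            (cdir / "classification.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True))
            pd.DataFrame(sorted(res.fold_assignments.items()),
                         columns=["id", "fold"]).to_csv(
                cdir / "folds.tsv", sep="\t", index=False)
            manifest["outputs"]["classify"] = ["classification.json", "folds.tsv"]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out_root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (keys mirror the dataclass)."""
    d = yaml.safe_load(Path(path).read_text()) or {}
    if "spec" in d:
        d["spec"] = CohortSpec(**d["spec"])
    if "cpm" in d:
        d["cpm"] = CPMConfig(**d["cpm"])
    for key in ("stages", "partialcorr_scores", "partialcorr_covariates",
                "c_grid", "g_grid", "seeds_override"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    if d.get("classify_edge") is not None:
        d["classify_edge"] = tuple(d["classify_edge"])
    return RunConfig(**d)
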