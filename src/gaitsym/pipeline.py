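"""End-to-end orchestration: simulate -> preprocess -> symmetry -> SPM ->
classify, with one root seed, a validated config, and a JSON-serializable
run report.

Per-stage randomness is derived from the root seed through fixed offsets,
so any stage re-run from its intermediate files reproduces the full-run
output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from . import classify, preprocess, spm_field, symmetry, synthetic_grf

log = logging.getLogger("gaitsym")

AXES = synthetic_grf.AXES

# fixed per-stage seed offsets (root seed + offset, kept below 2**31)
SEED_SIMULATE = 0
SEED_SPM = 101
SEED_CLASSIFY = 211

#: compact grids for routine end-to-end runs; the full libsvm-style ranges
#: in classify.DEFAULT_C_GRID / DEFAULT_G_GRID remain available per config.
PIPELINE_C_GRID = (0.125, 1.0, 8.0, 64.0)
PIPELINE_G_GRID = (0.001, 0.01, 0.1, 1.0)


@dataclass
class RunConfig:
    out_dir: str = "gaitsym_run"
    seed: int = 0
    n_subjects: int = 14
    n_trials: int = 3
    asym_profile: str = "dominance+fatigue"
    noise_sd: float = 0.02
    noise_fwhm: float = 12.0
    stance_threshold_N: float = 30.0
    min_stance_s: float = 0.1
    sf_threshold: float = 0.05
    alpha: float = 0.05
    tails: int = 2
    n_perm: int = 999
    kernels: tuple[str, ...] = ("LINEAR", "RBF", "POLY")
    tasks: tuple[str, ...] = ("LR", "fatigue")
    C_grid: tuple[float, ...] = PIPELINE_C_GRID
    G_grid: tuple[float, ...] = PIPELINE_G_GRID
    poly_degree: int = 3
    cv_folds: int = 5
    grouped_split: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Collect every invariant violation at once; empty list means OK."""
    errors = []
    if not 0.0 < config.alpha < 1.0:
        errors.append(f"alpha must be in (0, 1), got {config.alpha}")
    if config.tails not in (1, 2):
        errors.append(f"tails must be 1 or 2, got {config.tails}")
    if config.n_subjects < 2:
        errors.append(f"n_subjects must be >= 2, got {config.n_subjects}")
    if config.n_trials < 1:
        errors.append(f"n_trials must be >= 1, got {config.n_trials}")
    if config.asym_profile not in synthetic_grf.PROFILES:
        errors.append(f"unknown asym_profile {config.asym_profile!r}; "
                      f"choose from {sorted(synthetic_grf.PROFILES)}")
    if config.noise_sd < 0:
        errors.append(f"noise_sd must be >= 0, got {config.noise_sd}")
    if config.noise_fwhm < 1:
        errors.append(f"noise_fwhm must be >= 1, got {config.noise_fwhm}")
    if config.sf_threshold < 0:
        errors.append(f"sf_threshold must be >= 0, got {config.sf_threshold}")
    if config.n_perm < 100:
        errors.append(f"n_perm must be >= 100, got {config.n_perm}")
    if config.cv_folds < 2:
        errors.append(f"cv_folds must be >= 2, got {config.cv_folds}")
    bad_kernels = set(config.kernels) - {"LINEAR", "RBF", "POLY"}
    if bad_kernels:
        errors.append(f"unknown kernels {sorted(bad_kernels)}")
    bad_tasks = set(config.tasks) - {"LR", "fatigue"}
    if bad_tasks:
        errors.append(f"unknown tasks {sorted(bad_tasks)}")
    if not config.C_grid or min(config.C_grid) <= 0:
        errors.append("C_grid must be non-empty and positive")
    if not config.G_grid or min(config.G_grid) <= 0:
        errors.append("G_grid must be non-empty and positive")
    return errors


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("simulate")
def stage_simulate(config: RunConfig, out_dir: Path) -> synthetic_grf.DatasetManifest:
    profile = synthetic_grf.PROFILES[config.asym_profile]()
    noise = synthetic_grf.NoiseSpec(sd=config.noise_sd,
                                    smooth_fwhm=config.noise_fwhm)
    return synthetic_grf.make_dataset(
        out_dir / "trials", n_subjects=config.n_subjects,
        n_trials=config.n_trials, asymmetry=profile, noise=noise,
        seed=config.seed + SEED_SIMULATE,
    )


@_stage("preprocess")
def stage_preprocess(config: RunConfig, out_dir: Path) -> pd.DataFrame:
    trials = gio.load_dataset(out_dir / "trials" / "manifest.json")
    curves = preprocess.preprocess_dataset(
        trials, threshold_N=config.stance_threshold_N,
        min_duration_s=config.min_stance_s,
    )
    gio.write_curves_csv(out_dir / "curves.csv", curves)
    return curves


@_stage("symmetry")
def stage_symmetry(config: RunConfig, curves: pd.DataFrame,
                   out_dir: Path) -> tuple[pd.DataFrame, dict]:
    sf_curves = symmetry.sf_dataset(curves, threshold=config.sf_threshold)
    sf = symmetry.sf_table(sf_curves)
    gio.write_sf_csv(out_dir / "sf.csv", sf)
    summary: dict = {}
    for axis in AXES:
        per_cond = {}
        for condition in ("pre", "post"):
            mean_curve = (sf[(sf["axis"] == axis) & (sf["condition"] == condition)]
                          .groupby("node")["sf"].mean().to_numpy())
            intervals = symmetry.asymmetric_intervals(mean_curve,
                                                      config.sf_threshold)
            per_cond[condition] = {
                "mean_sf_integral": round(float(symmetry.sf_integral(mean_curve)), 5),
                "peak_sf": round(float(mean_curve.max()), 5),
                "asymmetric_intervals": intervals,
            }
        summary[axis] = per_cond
    (out_dir / "sf_summary.json").write_text(json.dumps(summary, indent=2))
    return sf, summary


def _subject_mean_curves(df: pd.DataFrame, value_col: str,
                         filters: dict) -> np.ndarray:
    sub = df
    for col, val in filters.items():
        sub = sub[sub[col] == val]
    pivot = (sub.groupby(["subject", "node"])[value_col].mean()
             .unstack("node").sort_index())
    return pivot.to_numpy(float)


@_stage("spm")
def stage_spm(config: RunConfig, curves: pd.DataFrame, sf: pd.DataFrame,
              out_dir: Path) -> dict:
    """Three paired comparisons per axis on subject-mean curves: left vs
    right within each condition, and SF pre vs post."""
    results: dict = {}
    seed = config.seed + SEED_SPM
    for axis in AXES:
        per_axis = {}
        for condition in ("pre", "post"):
            left = _subject_mean_curves(curves, "value_bw",
                                        {"axis": axis, "condition": condition,
                                         "side": "L"})
            right = _subject_mean_curves(curves, "value_bw",
                                         {"axis": axis, "condition": condition,
                                          "side": "R"})
            res = spm_field.spm_paired_test(
                left, right, alpha=config.alpha, tails=config.tails,
                n_perm=config.n_perm, seed=seed)
            per_axis[f"LR_{condition}"] = res.to_dict()
        pre = _subject_mean_curves(sf, "sf", {"axis": axis, "condition": "pre"})
        post = _subject_mean_curves(sf, "sf", {"axis": axis, "condition": "post"})
        res = spm_field.spm_paired_test(
            post, pre, alpha=config.alpha, tails=config.tails,
            n_perm=config.n_perm, seed=seed)
        per_axis["SF_post_vs_pre"] = res.to_dict()
        results[axis] = per_axis
    (out_dir / "spm.json").write_text(json.dumps(results, indent=2))
    return results


@_stage("classify")
def stage_classify(config: RunConfig, curves: pd.DataFrame, sf: pd.DataFrame,
                   out_dir: Path) -> dict:
    results: dict = {}
    seed = config.seed + SEED_CLASSIFY
    for task in config.tasks:
        table = curves if task == "LR" else sf
        per_task = {}
        for axis in AXES:
            per_axis = {}
            for kind in config.kernels:
                report = classify.evaluate_task(
                    table, task, axis, kind,
                    C_grid=config.C_grid, G_grid=config.G_grid,
                    d=config.poly_degree, k=config.cv_folds, seed=seed,
                    grouped_split=config.grouped_split,
                )
                per_axis[kind] = report.to_dict()
            per_task[axis] = per_axis
        results[task] = per_task
    (out_dir / "classify.json").write_text(json.dumps(results, indent=2))
    return results


def run_full(config: RunConfig) -> dict:
    """Execute every stage and return the serializable run report."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, out_dir)
    curves = stage_preprocess(config, out_dir)
    sf, sf_summary = stage_symmetry(config, curves, out_dir)
    spm_results = stage_spm(config, curves, sf, out_dir)
    clf_results = stage_classify(config, curves, sf, out_dir)
    report = {
        "provenance": {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "symmetry": sf_summary,
        "spm": spm_results,
        "classification": clf_results,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
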