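"""Readers/writers for the package's plain-text dialects.

Trial files are CSV with header ``time_s,fx_N,fy_N,fz_N``; a dataset manifest
is JSON; processed stance curves travel as a tidy table
``subject,side,condition,trial,axis,node,value_bw`` and symmetry-function
curves as ``subject,condition,trial,axis,node,sf``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_grf import DatasetManifest, GrfTrial

TRIAL_COLUMNS = ["time_s", "fx_N", "fy_N", "fz_N"]
CURVE_COLUMNS = ["subject", "side", "condition", "trial", "axis", "node", "value_bw"]
SF_COLUMNS = ["subject", "condition", "trial", "axis", "node", "sf"]


def write_trial_csv(path: str | Path, trial: GrfTrial) -> None:
    df = pd.DataFrame({
        "time_s": trial.time_s, "fx_N": trial.fx_N,
        "fy_N": trial.fy_N, "fz_N": trial.fz_N,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_trial_csv(path: str | Path, *, mass_kg: float, side: str,
                   condition: str, subject: str, trial: int,
                   age_years: float = float("nan")) -> GrfTrial:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} missing columns {missing}")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError(f"trial file {path}: time must be strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return GrfTrial(
        time_s=t, fx_N=df["fx_N"].to_numpy(float),
        fy_N=df["fy_N"].to_numpy(float), fz_N=df["fz_N"].to_numpy(float),
        sampling_rate=fs, mass_kg=mass_kg, side=side, condition=condition,
        subject=subject, trial=trial, age_years=age_years,
    )


def read_manifest(path: str | Path) -> DatasetManifest:
    return DatasetManifest.from_json(Path(path).read_text())


def load_dataset(manifest_path: str | Path) -> list[GrfTrial]:
    """Load every trial listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    trials = []
    for rec in manifest.records:
        trials.append(read_trial_csv(
            base / rec["path"], mass_kg=rec["mass_kg"], side=rec["side"],
            condition=rec["condition"], subject=rec["subject"],
            trial=rec["trial"], age_years=rec.get("age_years", float("nan")),
        ))
    return trials


def write_curves_csv(path: str | Path, curves: pd.DataFrame) -> None:
    curves[CURVE_COLUMNS].to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curves table {path} missing columns {missing}")
    return df


def write_sf_csv(path: str | Path, sf: pd.DataFrame) -> None:
    sf[SF_COLUMNS].to_csv(path, index=False)


def read_sf_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SF table {path} missing columns {missing}")
    return df
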