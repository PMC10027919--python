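"""Raw force-plate series -> 101-node body-weight-normalized stance curves.

The stance phase is the longest run of samples with vertical force at or
above 30 N (inclusive at both ends); all three axes are cropped with that
one window, resampled to 101 nodes (0-100% stance) with an interpolating
cubic spline, and scaled to body-weight units as force / (10 x mass kg).
No filtering is applied by default; an optional low-pass hook exists for
recordings that need it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .synthetic_grf import AXES, GrfTrial

N_NODES = 101
DEFAULT_THRESHOLD_N = 30.0
DEFAULT_MIN_DURATION_S = 0.1


class NoContact(ValueError):
    """No suprathreshold run of at least the minimum stance duration."""


@dataclass(frozen=True)
class StanceCurve:
    """One axis of one stance phase on the 0-100% node grid, BW units."""

    axis: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_NODES,):
            raise ValueError(f"expected {N_NODES} nodes, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("stance curve contains non-finite values")
        object.__setattr__(self, "values", v)


def detect_stance(
    vertical_N: np.ndarray,
    sampling_rate: float,
    threshold_N: float = DEFAULT_THRESHOLD_N,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
) -> tuple[int, int]:
    """Locate foot contact as the longest run with Fz >= threshold.

    Returns inclusive (start, end) sample indices. Runs shorter than
    ``min_duration_s`` (aiming steps, plate-edge grazes) are discarded;
    ties between equally long runs go to the earliest.
    """
    fz = np.asarray(vertical_N, dtype=float)
    if fz.size == 0:
        raise NoContact("empty series")
    above = fz >= threshold_N
    if not above.any():
        raise NoContact(f"no sample reaches {threshold_N} N")
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges, [fz.size - 1]])
    runs = [(s, e) for s, e in zip(starts, ends) if above[s]]
    min_len = min_duration_s * sampling_rate
    runs = [(s, e) for s, e in runs if (e - s + 1) >= min_len]
    if not runs:
        raise NoContact(
            f"no suprathreshold run of at least {min_duration_s} s"
        )
    start, end = max(runs, key=lambda se: (se[1] - se[0], -se[0]))
    return int(start), int(end)


def time_normalize(segment: np.ndarray, n_nodes: int = N_NODES) -> np.ndarray:
    """Resample a stance segment to ``n_nodes`` with an interpolating cubic
    spline over normalized time; endpoint samples are reproduced exactly."""
    seg = np.asarray(segment, dtype=float)
    if seg.size < 4:
        raise ValueError(f"segment too short for a cubic spline: {seg.size} < 4")
    x = np.linspace(0.0, 1.0, seg.size)
    spline = CubicSpline(x, seg)
    out = spline(np.linspace(0.0, 1.0, n_nodes))
    out[0], out[-1] = seg[0], seg[-1]
    return out


def normalize_bw(force_N: np.ndarray | float, mass_kg: float) -> np.ndarray | float:
    """Body-weight units: force divided by 10 x body mass (kg)."""
    if mass_kg <= 0:
        raise ValueError(f"mass must be > 0, got {mass_kg}")
    return np.asarray(force_N, dtype=float) / (10.0 * mass_kg) if np.ndim(force_N) else float(force_N) / (10.0 * mass_kg)


def lowpass(series: np.ndarray, sampling_rate: float, cutoff_hz: float,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; disabled by default in the pipeline."""
    b, a = butter(order, cutoff_hz, fs=sampling_rate)
    return filtfilt(b, a, series)


def preprocess_trial(
    trial: GrfTrial,
    threshold_N: float = DEFAULT_THRESHOLD_N,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    lowpass_hz: float | None = None,
) -> dict[str, StanceCurve]:
    """Crop, resample and scale one trial; all axes share the vertical
    stance window. Returns ``{"X": ..., "Y": ..., "Z": ...}``."""
    series = {"X": trial.fx_N, "Y": trial.fy_N, "Z": trial.fz_N}
    if lowpass_hz is not None:
        series = {a: lowpass(s, trial.sampling_rate, lowpass_hz)
                  for a, s in series.items()}
    start, end = detect_stance(series["Z"], trial.sampling_rate,
                               threshold_N, min_duration_s)
    curves = {}
    for axis in AXES:
        seg = series[axis][start:end + 1]
        values = normalize_bw(time_normalize(seg), trial.mass_kg)
        curves[axis] = StanceCurve(axis=axis, values=values)
    return curves


def preprocess_dataset(trials, **kwargs):
    """Preprocess many trials into the tidy curves table
    ``subject,side,condition,trial,axis,node,value_bw``."""
    import pandas as pd

    rows = []
    for t in trials:
        curves = preprocess_trial(t, **kwargs)
        for axis, curve in curves.items():
            for node, value in enumerate(curve.values):
                rows.append((t.subject, t.side, t.condition, t.trial,
                             axis, node, value))
    return pd.DataFrame(rows, columns=["subject", "side", "condition",
                                       "trial", "axis", "node", "value_bw"])
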