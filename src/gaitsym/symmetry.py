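"""Symmetry Function (SF) for paired left/right stance curves.

For right and left waveforms x_r(t), x_l(t) on the 101-node stance grid,

    SF(t) = A * |x_r(t) - x_l(t)|,   A = 2 / (range(x_r) + range(x_l)),

so SF is unitless, zero for perfect symmetry, and invariant to a common
rescaling of both limbs. A scalar summary is the trapezoidal integral of
SF over normalized stance time in [0, 1], and stance intervals where SF
exceeds an asymmetry threshold (default 0.05) are reported as inclusive
node-percentage ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import N_NODES

DEFAULT_SF_THRESHOLD = 0.05


class DegenerateAmplitude(ValueError):
    """Both limb curves are constant: the SF amplitude 2/(0+0) is undefined."""


class UnpairedTrial(ValueError):
    """A left trial has no matching right trial (or vice versa)."""


def amplitude_A(right: np.ndarray, left: np.ndarray) -> float:
    """A = 2 / (range(right) + range(left)), range = max - min."""
    right = _check_nodes(right)
    left = _check_nodes(left)
    denom = np.ptp(right) + np.ptp(left)
    if denom == 0:
        raise DegenerateAmplitude("both curves are constant; amplitude undefined")
    return 2.0 / float(denom)


def sf_curve(right: np.ndarray, left: np.ndarray) -> np.ndarray:
    """Pointwise symmetry function A * |right - left| on the node grid."""
    right = _check_nodes(right)
    left = _check_nodes(left)
    return amplitude_A(right, left) * np.abs(right - left)


def sf_integral(sf_values: np.ndarray) -> float:
    """Trapezoidal integral of SF over normalized stance time in [0, 1]."""
    sf_values = _check_nodes(sf_values)
    return float(np.trapezoid(sf_values, np.linspace(0.0, 1.0, sf_values.size)))


def asymmetric_intervals(
    sf_values: np.ndarray, threshold: float = DEFAULT_SF_THRESHOLD
) -> list[tuple[int, int]]:
    """Maximal runs of nodes with SF strictly above threshold, as inclusive
    (start %, end %) stance percentages."""
    sf_values = _check_nodes(sf_values)
    above = sf_values > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges, [sf_values.size - 1]])
    return [(int(s), int(e)) for s, e in zip(starts, ends) if above[s]]


@dataclass(frozen=True)
class SymmetryCurve:
    """SF result for one (subject, condition, trial, axis) limb pair."""

    axis: str
    sf_values: np.ndarray
    sf_integral: float
    amplitude: float
    asymmetric_intervals: list[tuple[int, int]] = field(default_factory=list)
    subject: str = ""
    condition: str = ""
    trial: int = 0


def sf_pair(right: np.ndarray, left: np.ndarray, axis: str = "",
            threshold: float = DEFAULT_SF_THRESHOLD, **provenance) -> SymmetryCurve:
    values = sf_curve(right, left)
    return SymmetryCurve(
        axis=axis, sf_values=values, sf_integral=sf_integral(values),
        amplitude=amplitude_A(right, left),
        asymmetric_intervals=asymmetric_intervals(values, threshold),
        **provenance,
    )


def sf_dataset(curves: pd.DataFrame,
               threshold: float = DEFAULT_SF_THRESHOLD) -> list[SymmetryCurve]:
    """Compute one SymmetryCurve per (subject, condition, trial, axis).

    Pairing rule: the i-th left trial is paired with the i-th right trial
    within each (subject, condition), in trial-index order. Raises
    UnpairedTrial naming the first record without a partner.
    """
    results = []
    for (subject, condition, axis), grp in curves.groupby(
        ["subject", "condition", "axis"], sort=True
    ):
        sides = {}
        for side in ("L", "R"):
            sub = grp[grp["side"] == side].sort_values(["trial", "node"])
            sides[side] = [
                (int(trial), tg["value_bw"].to_numpy(float))
                for trial, tg in sub.groupby("trial", sort=True)
            ]
        n_l, n_r = len(sides["L"]), len(sides["R"])
        if n_l != n_r:
            short, n_min = ("R", n_r) if n_r < n_l else ("L", n_l)
            long_side = "L" if short == "R" else "R"
            orphan = sides[long_side][n_min][0]
            raise UnpairedTrial(
                f"subject {subject}, condition {condition}, axis {axis}: "
                f"{long_side} trial {orphan} has no paired {short} trial"
            )
        for (lt, lv), (rt, rv) in zip(sides["L"], sides["R"]):
            results.append(sf_pair(
                rv, lv, axis=axis, threshold=threshold,
                subject=subject, condition=condition, trial=lt,
            ))
    return results


def sf_table(symmetry_curves: list[SymmetryCurve]) -> pd.DataFrame:
    """Tidy SF table ``subject,condition,trial,axis,node,sf``."""
    rows = []
    for sc in symmetry_curves:
        for node, value in enumerate(sc.sf_values):
            rows.append((sc.subject, sc.condition, sc.trial, sc.axis, node, value))
    return pd.DataFrame(rows, columns=["subject", "condition", "trial",
                                       "axis", "node", "sf"])


def mean_sf_by_axis(sf: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """Trial-mean SF curve per axis (node grid columns), optionally within
    one condition. Trial-mean is the default aggregation for summary plots."""
    df = sf if condition is None else sf[sf["condition"] == condition]
    return df.groupby(["axis", "node"])["sf"].mean().unstack("node")


def _check_nodes(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (N_NODES,):
        raise ValueError(f"expected {N_NODES} nodes, got shape {values.shape}")
    return values
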