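"""One-dimensional statistical parametric mapping (SPM) for paired designs.

A paired t statistic is computed at each of the 101 stance nodes, the
smoothness (FWHM) of the residual field is estimated from normalized
residual gradients, and a familywise critical threshold is obtained from
the random-field-theory (RFT) expected Euler characteristic of a t field:

    E[EC](t) = P(T_nu >= t) + resels * sqrt(4 ln 2) / (2 pi)
                              * (1 + t^2 / nu) ** (-(nu - 1) / 2)

with resels = (nodes - 1) / FWHM. The critical value t* solves
E[EC](t*) = alpha (alpha/2 per tail for two-tailed inference). Maximal runs
of nodes with |t| > t* are reported as suprathreshold clusters; cluster
p-values come from a sign-flip permutation null of the maximum cluster
extent (exact enumeration when 2^n does not exceed the permutation budget).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import optimize, stats

N_NODES = 101
FWHM_MIN, FWHM_MAX = 1.0, 1000.0


class ZeroVariance(UserWarning):
    """Some node had zero paired-difference variance with nonzero mean."""


@dataclass(frozen=True)
class Cluster:
    start_pct: int
    end_pct: int
    extent: int
    p_value: float = float("nan")


@dataclass(frozen=True)
class TFieldResult:
    t_values: np.ndarray
    dof: int
    fwhm: float
    resels: float
    alpha: float
    t_critical: float
    clusters: list[Cluster] = field(default_factory=list)
    tails: int = 2
    zero_variance_nodes: list[int] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0

    def to_dict(self) -> dict:
        return {
            "dof": self.dof, "fwhm": round(self.fwhm, 4),
            "resels": round(self.resels, 4), "alpha": self.alpha,
            "t_critical": round(self.t_critical, 4), "tails": self.tails,
            "zero_variance_nodes": list(self.zero_variance_nodes),
            "clusters": [
                {"start_pct": c.start_pct, "end_pct": c.end_pct,
                 "extent": c.extent,
                 "p": None if np.isnan(c.p_value) else round(c.p_value, 5)}
                for c in self.clusters
            ],
        }


def paired_t(curves_a: np.ndarray, curves_b: np.ndarray
             ) -> tuple[np.ndarray, int, np.ndarray]:
    """Node-wise paired t statistic for n x 101 matched curve sets.

    Returns (t field, dof = n-1, centered difference residuals). Nodes with
    zero difference variance and nonzero mean get +/-inf; zero mean gives 0.
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t needs n >= 2 pairs")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero = sd == 0
    t[zero & (mean > 0)] = np.inf
    t[zero & (mean < 0)] = -np.inf
    t[zero & (mean == 0)] = 0.0
    residuals = d - mean
    return t, n - 1, residuals


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Residual-gradient (Kiebel-style) smoothness estimate, in nodes.

    Residuals are scaled to unit variance per node; FWHM =
    sqrt(4 ln 2 / <grad^2>) over all rows and nodes, clipped to [1, 1000].
    All-zero residuals estimate as the upper clip (infinitely smooth).
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    if r.shape[0] < 2:
        raise ValueError("need >= 2 residual rows")
    sd = r.std(axis=0, ddof=1)
    ok = (sd > 0) & np.isfinite(sd)
    if not ok.any():
        return FWHM_MAX
    u = r[:, ok] / sd[ok]
    if u.shape[1] < 2:
        return FWHM_MAX
    grad = np.gradient(u, axis=1)
    v = float(np.mean(grad**2))
    if v <= 0:
        return FWHM_MAX
    return float(np.clip(np.sqrt(4.0 * np.log(2.0) / v), FWHM_MIN, FWHM_MAX))


def expected_euler_char(t: float, dof: int, resels: float) -> float:
    """Expected EC of a thresholded 1D t field (one tail)."""
    ec0 = stats.t.sf(t, dof)
    ec1 = (resels * np.sqrt(4.0 * np.log(2.0)) / (2.0 * np.pi)
           * (1.0 + t**2 / dof) ** (-(dof - 1) / 2.0))
    return float(ec0 + ec1)


def rft_threshold(alpha: float, dof: int, resels: float, tails: int = 2) -> float:
    """Smallest t* with E[EC](t*) = alpha (alpha/2 per tail if two-tailed)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if resels < 0:
        raise ValueError("resels must be >= 0")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    target = alpha / tails
    f = lambda t: expected_euler_char(t, dof, resels) - target
    lo, hi = 0.0, 100.0
    if f(hi) > 0:
        raise ValueError("no root in [0, 100]: alpha too small or field too rough")
    if f(lo) < 0:
        # E[EC](0) < alpha can occur for tiny resels and large alpha;
        # fall back to the Student quantile bound
        return float(stats.t.isf(target, dof))
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def implied_resels(t_critical: float, alpha: float, dof: int,
                   tails: int = 2) -> float:
    """Invert the EC equation for resels at a known critical value."""
    target = alpha / tails
    ec1_unit = (np.sqrt(4.0 * np.log(2.0)) / (2.0 * np.pi)
                * (1.0 + t_critical**2 / dof) ** (-(dof - 1) / 2.0))
    return float((target - stats.t.sf(t_critical, dof)) / ec1_unit)


def suprathreshold_clusters(t_values: np.ndarray, t_critical: float,
                            tails: int = 2) -> list[Cluster]:
    """Maximal runs with |t| > t* (two-tailed) or t > t* (one-tailed),
    reported as inclusive node-percent intervals with node extents."""
    t = np.asarray(t_values, dtype=float)
    above = (np.abs(t) if tails == 2 else t) > t_critical
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges, [t.size - 1]])
    return [Cluster(int(s), int(e), int(e - s + 1))
            for s, e in zip(starts, ends) if above[s]]


def _max_cluster_extent(t: np.ndarray, t_critical: float, tails: int) -> int:
    clusters = suprathreshold_clusters(t, t_critical, tails)
    return max((c.extent for c in clusters), default=0)


def permutation_cluster_p(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    t_critical: float,
    n_perm: int = 999,
    seed: int | None = None,
    tails: int = 2,
) -> list[Cluster]:
    """Sign-flip permutation p-values for the observed suprathreshold clusters.

    The null distribution is the maximum cluster extent over sign-flipped
    paired differences. With a Monte Carlo sample, p = (1 + #{null >= obs})
    / (n_perm + 1); when 2^n <= n_perm all sign patterns are enumerated and
    p is the exact proportion #{null >= obs} / 2^n.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    d = a - b
    n = d.shape[0]
    t_obs, _, _ = paired_t(a, b)
    observed = suprathreshold_clusters(t_obs, t_critical, tails)
    if not observed:
        return []

    def t_of(signed: np.ndarray) -> np.ndarray:
        mean = signed.mean(axis=0)
        sd = signed.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)

    exact = 2**n <= n_perm
    if exact:
        null = np.array([
            _max_cluster_extent(t_of(d * np.array(signs)[:, None]),
                                t_critical, tails)
            for signs in product((1.0, -1.0), repeat=n)
        ])
        p_of = lambda ext: float(np.mean(null >= ext))
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for k in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)[:, None]
            null[k] = _max_cluster_extent(t_of(d * signs), t_critical, tails)
        p_of = lambda ext: float((1 + np.sum(null >= ext)) / (n_perm + 1))

    return [Cluster(c.start_pct, c.end_pct, c.extent, p_of(c.extent))
            for c in observed]


def spm_paired_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    alpha: float = 0.05,
    tails: int = 2,
    n_perm: int = 999,
    seed: int | None = None,
) -> TFieldResult:
    """Full paired SPM: t field -> smoothness -> RFT threshold -> clusters
    -> permutation cluster p-values."""
    t, dof, residuals = paired_t(curves_a, curves_b)
    finite = np.isfinite(t)
    zero_var_nodes = list(np.flatnonzero(~finite))
    fwhm = estimate_fwhm(residuals[:, finite] if finite.any() else residuals)
    resels = (t.size - 1) / fwhm
    t_crit = rft_threshold(alpha, dof, resels, tails)
    clusters = permutation_cluster_p(curves_a, curves_b, t_crit,
                                     n_perm=n_perm, seed=seed, tails=tails)
    return TFieldResult(
        t_values=t, dof=dof, fwhm=fwhm, resels=resels, alpha=alpha,
        t_critical=t_crit, clusters=clusters, tails=tails,
        zero_variance_nodes=zero_var_nodes,
    )
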