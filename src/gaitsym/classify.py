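"""Soft-margin kernel SVM for gait-curve recognition, with grid search,
stratified five-fold cross-validation, ACC/SEN/SEP evaluation, and an
exhaustive confusion-matrix consistency solver.

The classifier solves the standard soft-margin dual

    min_beta  1/2 beta^T Q beta - 1^T beta,
    s.t.      y^T beta = 0,  0 <= beta_i <= C,   Q_ij = y_i y_j K(x_i, x_j)

with a maximal-violating-pair SMO loop, and predicts
f(x) = sign(sum_i beta_i y_i K(x_i, x) + b). Kernels: LINEAR u.v,
RBF exp(-||u-v||^2 / (2 sigma^2)) with sigma^2 = 1/(2G) (libsvm-style
gamma G), and POLY (u.v + 1)^d.

Class coding follows the gait-recognition convention: feature 1 (left limb,
or pre-fatigue) is -1 and feature 2 (right limb, or post-fatigue) is +1.
Performance metrics are computed exactly as

    ACC = (T1+T2)/(T1+F1+T2+F2),  SEN = T1/(T1+F2),  SEP = T2/(T2+F1)

where T1/T2 count correctly recognized feature-1/feature-2 samples and
F1/F2 count feature-1/feature-2 samples misrecognized. Note SEN and SEP as
defined here share their denominators with the *predicted* class counts,
not the true class counts; the inversion solver relies on these exact
formulas, so they are not "corrected" to textbook recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TOL = 1e-3  # libsvm's default KKT stopping tolerance
MAX_ITER = 30_000
DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_G_GRID = tuple(2.0**k for k in range(-15, 4, 2))


class ConvergenceError(RuntimeError):
    """SMO failed to reduce the KKT violation below the acceptance level."""


class MetricUndefined(ValueError):
    """SEN or SEP has an empty denominator for this confusion matrix."""


class NoSolution(ValueError):
    """No integer confusion matrix reproduces the stated metrics."""


class AmbiguousSolution(ValueError):
    """Several confusion matrices reproduce the stated metrics."""

    def __init__(self, solutions):
        self.solutions = solutions
        super().__init__(f"{len(solutions)} confusion matrices match: {solutions}")


@dataclass(frozen=True)
class KernelSpec:
    """kind LINEAR | RBF | POLY; G is the RBF width parameter
    (sigma^2 = 1/(2G)); d the polynomial order."""

    kind: str = "LINEAR"
    G: float = 1.0
    d: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("LINEAR", "RBF", "POLY"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "RBF" and self.G <= 0:
            raise ValueError("RBF requires G > 0")
        if self.kind == "POLY" and self.d < 1:
            raise ValueError("POLY requires d >= 1")


def kernel_eval(spec: KernelSpec, u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(_kernel_matrix(spec, u[None, :], v[None, :])[0, 0])


def _kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    dot = A @ B.T
    if spec.kind == "LINEAR":
        return dot
    if spec.kind == "POLY":
        return (dot + 1.0) ** spec.d
    sq = (np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :]
          - 2.0 * dot)
    return np.exp(-spec.G * np.maximum(sq, 0.0))


@dataclass
class Standardizer:
    """Per-feature (per-node) mean/sd learned on training data only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


@dataclass
class SvmModel:
    beta: np.ndarray
    y: np.ndarray
    X: np.ndarray
    b: float
    C: float
    kernel: KernelSpec
    standardizer: Standardizer | None = None
    converged: bool = True
    kkt_violation: float = 0.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"feature length mismatch: {X.shape[1]} vs {self.X.shape[1]}")
        if self.standardizer is not None:
            X = self.standardizer.transform(X)
        K = _kernel_matrix(self.kernel, X, self.X)
        return K @ (self.beta * self.y) + self.b


def train_svm(X: np.ndarray, y: np.ndarray, kernel: KernelSpec, C: float,
              standardize: bool = True, tol: float = TOL,
              max_iter: int = MAX_ITER, strict: bool = False) -> SvmModel:
    """Fit the soft-margin dual with maximal-violating-pair SMO.

    Deterministic for a fixed input order (beta initialized at 0, violating
    pair chosen by first-order i / second-order j selection). The returned
    model satisfies 0 <= beta_i <= C and |sum beta_i y_i| <= 1e-6 at every
    iteration by construction. If the maximal KKT violation is still above
    ``tol`` after ``max_iter`` pair updates — which happens for strongly
    overlapping classes at large C, where exact dual solutions take millions
    of working-set steps — the current feasible iterate is returned with
    ``converged=False`` and a RuntimeWarning, or ConvergenceError when
    ``strict=True``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be m x p with one label per row")
    if C <= 0:
        raise ValueError("C must be > 0")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1.0, 1.0]):
        raise ValueError(f"labels must contain both -1 and +1, got {classes}")

    std = Standardizer.fit(X) if standardize else None
    Xs = std.transform(X) if std is not None else X
    m = Xs.shape[0]
    K = _kernel_matrix(kernel, Xs, Xs)
    Q = K * np.outer(y, y)

    beta = np.zeros(m)
    grad = -np.ones(m)  # gradient of 1/2 b'Qb - 1'b at beta = 0
    Qdiag = np.diag(Q)
    violation = np.inf
    for _ in range(max_iter):
        yg = -y * grad
        up = ((y > 0) & (beta < C - 1e-12)) | ((y < 0) & (beta > 1e-12))
        low = ((y < 0) & (beta < C - 1e-12)) | ((y > 0) & (beta > 1e-12))
        if not up.any() or not low.any():
            violation = 0.0
            break
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        violation = yg[i] - yg[low].min()
        if violation <= tol:
            break
        # second-order (libsvm-style) choice of j: maximal decrease of the
        # dual objective among sufficiently violating candidates
        cand = low & (yg < yg[i] - 1e-12)
        if not cand.any():
            cand = low
        idx = np.flatnonzero(cand)
        b_it = yg[i] - yg[idx]
        a_it = np.maximum(Qdiag[i] + Qdiag[idx] - 2.0 * y[i] * y[idx] * Q[i, idx],
                          1e-12)
        j = int(idx[np.argmin(-(b_it**2) / a_it)])
        # analytic update of the (i, j) pair along the equality constraint
        quad = max(Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j], 1e-12)
        delta = (yg[i] - yg[j]) / quad
        # box limits for beta_i (and the coupled move of beta_j)
        if y[i] > 0:
            di_max = C - beta[i]
        else:
            di_max = beta[i]
        if y[j] > 0:
            dj_max = beta[j]
        else:
            dj_max = C - beta[j]
        step = min(delta, di_max, dj_max)
        dbeta_i = step if y[i] > 0 else -step
        dbeta_j = -step if y[j] > 0 else step
        beta[i] += dbeta_i
        beta[j] += dbeta_j
        grad += Q[:, i] * dbeta_i + Q[:, j] * dbeta_j

    converged = violation <= tol
    if not converged:
        msg = (f"SMO stopped after {max_iter} iterations with KKT violation "
               f"{violation:.3g}")
        if strict:
            raise ConvergenceError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    # bias from the midpoint of the violating-pair bounds (free-SV average
    # when strictly interior support vectors exist)
    yg = -y * grad
    free = (beta > 1e-9) & (beta < C - 1e-9)
    if free.any():
        b = float(np.mean(yg[free]))
    else:
        up = ((y > 0) & (beta < C - 1e-12)) | ((y < 0) & (beta > 1e-12))
        low = ((y < 0) & (beta < C - 1e-12)) | ((y > 0) & (beta > 1e-12))
        hi = yg[up].max() if up.any() else yg[low].min()
        lo = yg[low].min() if low.any() else hi
        b = float((hi + lo) / 2.0)

    beta = np.clip(beta, 0.0, C)
    return SvmModel(beta=beta, y=y, X=Xs, b=b, C=C, kernel=kernel,
                    standardizer=std, converged=converged,
                    kkt_violation=float(max(violation, 0.0)))


def predict(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Hard labels in {-1, +1}; a decision value of exactly 0 maps to +1."""
    f = model.decision_function(X)
    return np.where(f >= 0.0, 1.0, -1.0)


@dataclass(frozen=True)
class ConfusionMatrix:
    """T1/T2: correctly recognized feature-1/-2; F1/F2: feature-1/-2
    misrecognized."""

    T1: int
    T2: int
    F1: int
    F2: int

    def __post_init__(self) -> None:
        if min(self.T1, self.T2, self.F1, self.F2) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.T1 + self.T2 + self.F1 + self.F2

    @property
    def acc(self) -> float:
        return (self.T1 + self.T2) / self.total

    @property
    def sen(self) -> float:
        if self.T1 + self.F2 == 0:
            raise MetricUndefined("SEN undefined: T1 + F2 = 0")
        return self.T1 / (self.T1 + self.F2)

    @property
    def sep(self) -> float:
        if self.T2 + self.F1 == 0:
            raise MetricUndefined("SEP undefined: T2 + F1 = 0")
        return self.T2 / (self.T2 + self.F1)


def evaluate(true_labels: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    """Confusion counts with feature 1 coded -1 and feature 2 coded +1."""
    t = np.asarray(true_labels, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape:
        raise ValueError("label arrays differ in length")
    bad = set(np.unique(np.concatenate([t, p]))) - {-1.0, 1.0}
    if bad:
        raise ValueError(f"labels must be in {{-1, +1}}, got extras {bad}")
    return ConfusionMatrix(
        T1=int(np.sum((t == -1) & (p == -1))),
        T2=int(np.sum((t == 1) & (p == 1))),
        F1=int(np.sum((t == -1) & (p == 1))),
        F2=int(np.sum((t == 1) & (p == -1))),
    )


def stratified_folds(y: np.ndarray, k: int, seed: int | None) -> list[np.ndarray]:
    """Deterministic seeded stratified k-fold assignment (index arrays)."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls} has {idx.size} samples, too few for {k} folds")
        rng.shuffle(idx)
        for pos, sample in enumerate(idx):
            folds[pos % k].append(int(sample))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(X: np.ndarray, y: np.ndarray, kernel: KernelSpec, C: float,
                   k: int = 5, seed: int | None = 0) -> float:
    """Mean held-out accuracy over seeded stratified k folds; features are
    standardized with training-fold statistics only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = stratified_folds(y, k, seed)
    accs = []
    for test_idx in folds:
        mask = np.ones(y.size, dtype=bool)
        mask[test_idx] = False
        model = train_svm(X[mask], y[mask], kernel, C)
        accs.append(float(np.mean(predict(model, X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def grid_search(X: np.ndarray, y: np.ndarray, kind: str,
                C_grid=DEFAULT_C_GRID, G_grid=DEFAULT_G_GRID,
                d: int = 3, k: int = 5, seed: int | None = 0
                ) -> tuple[float, float, float]:
    """Argmax of CV accuracy over (C, G); ties go to smaller C then smaller G.

    G only parameterizes the RBF kernel; for LINEAR/POLY the G grid
    collapses to a single placeholder value.
    """
    C_grid = sorted(C_grid)
    G_grid = sorted(G_grid) if kind == "RBF" else [1.0]
    if not C_grid or not G_grid:
        raise ValueError("grids must be non-empty")
    best = None
    for C in C_grid:
        for G in G_grid:
            spec = KernelSpec(kind=kind, G=G, d=d)
            acc = cross_validate(X, y, spec, C, k=k, seed=seed)
            if best is None or acc > best[2] + 1e-12:
                best = (C, G, acc)
    return best


@dataclass(frozen=True)
class SvmEvalReport:
    task: str
    axis: str
    kernel: KernelSpec
    best_C: float
    best_G: float
    cv_accuracy: float
    confusion: ConfusionMatrix
    acc: float
    sen: float | None
    sep: float | None

    def to_dict(self) -> dict:
        return {
            "task": self.task, "axis": self.axis,
            "kernel": self.kernel.kind, "d": self.kernel.d,
            "best_C": self.best_C, "best_G": self.best_G,
            "cv_accuracy": round(self.cv_accuracy, 4),
            "confusion": {"T1": self.confusion.T1, "T2": self.confusion.T2,
                          "F1": self.confusion.F1, "F2": self.confusion.F2},
            "ACC": round(self.acc, 4),
            "SEN": None if self.sen is None else round(self.sen, 4),
            "SEP": None if self.sep is None else round(self.sep, 4),
        }


def build_feature_sets(table: pd.DataFrame, task: str, axis: str,
                       conditions: tuple[str, ...] = ("pre", "post")
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrices for the two recognition tasks.

    LR: rows are per-trial 101-node GRF stance curves (both conditions
    pooled by default), y = -1 left / +1 right. fatigue: rows are per-trial
    101-node SF curves, y = -1 pre / +1 post. Group ids are subjects, for
    optional subject-grouped splitting.
    """
    if task == "LR":
        sub = table[(table["axis"] == axis)
                    & (table["condition"].isin(conditions))]
        if sub.empty:
            raise ValueError(f"no rows for axis {axis!r}")
        value_col = "value_bw"
        keys = ["subject", "condition", "trial", "side"]
        label = lambda rec: -1.0 if rec["side"] == "L" else 1.0
        required = {"L", "R"}
        present = set(sub["side"].unique())
    elif task == "fatigue":
        sub = table[table["axis"] == axis]
        if sub.empty:
            raise ValueError(f"no rows for axis {axis!r}")
        value_col = "sf"
        keys = ["subject", "condition", "trial"]
        label = lambda rec: -1.0 if rec["condition"] == "pre" else 1.0
        required = {"pre", "post"}
        present = set(sub["condition"].unique())
    else:
        raise ValueError(f"task must be 'LR' or 'fatigue', got {task!r}")
    if not required <= present:
        raise ValueError(f"missing {sorted(required - present)} rows for task {task}")

    X, y, groups = [], [], []
    for key_vals, grp in sub.groupby(keys, sort=True):
        rec = dict(zip(keys, key_vals))
        curve = grp.sort_values("node")[value_col].to_numpy(float)
        X.append(curve)
        y.append(label(rec))
        groups.append(rec["subject"])
    return np.array(X), np.array(y), np.array(groups)


def holdout_split(y: np.ndarray, test_fraction: float, seed: int | None,
                  groups: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified (default) or subject-grouped hold-out index split."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    if groups is None:
        test = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n_test = max(1, int(round(test_fraction * idx.size)))
            test.extend(idx[:n_test])
        test = np.sort(np.array(test, dtype=int))
    else:
        groups = np.asarray(groups)
        uniq = np.array(sorted(set(groups)))
        rng.shuffle(uniq)
        n_test = max(1, int(round(test_fraction * uniq.size)))
        test = np.sort(np.flatnonzero(np.isin(groups, uniq[:n_test])))
    train = np.setdiff1d(np.arange(y.size), test)
    return train, test


def evaluate_task(table: pd.DataFrame, task: str, axis: str, kind: str,
                  C_grid=DEFAULT_C_GRID, G_grid=DEFAULT_G_GRID, d: int = 3,
                  test_fraction: float | None = None, k: int = 5,
                  seed: int | None = 0, grouped_split: bool = False
                  ) -> SvmEvalReport:
    """Grid-search, fit on the training split, evaluate ACC/SEN/SEP on the
    hold-out. Hold-out sizes default to ~20% (LR) / ~29% (fatigue)."""
    X, y, groups = build_feature_sets(table, task, axis)
    if test_fraction is None:
        test_fraction = 0.2 if task == "LR" else 0.29
    train, test = holdout_split(y, test_fraction, seed,
                                groups if grouped_split else None)
    best_C, best_G, cv_acc = grid_search(X[train], y[train], kind,
                                         C_grid, G_grid, d=d, k=k, seed=seed)
    spec = KernelSpec(kind=kind, G=best_G, d=d)
    model = train_svm(X[train], y[train], spec, best_C)
    cm = evaluate(y[test], predict(model, X[test]))
    try:
        sen = cm.sen
    except MetricUndefined:
        sen = None
    try:
        sep = cm.sep
    except MetricUndefined:
        sep = None
    return SvmEvalReport(task=task, axis=axis, kernel=spec, best_C=best_C,
                         best_G=best_G, cv_accuracy=cv_acc, confusion=cm,
                         acc=cm.acc, sen=sen, sep=sep)


def _rounds_to(value: float, stated: float, decimals: int) -> bool:
    return abs(value - stated) <= 0.5 * 10.0**(-decimals) + 1e-12


def recover_confusion_from_metrics(
    total_n: int, known: dict[str, tuple[float, int]]
) -> tuple[ConfusionMatrix, dict[str, float]]:
    """Invert ACC/SEN/SEP (as fractions with printed decimal places) to the
    confusion matrix that produced them.

    ``known`` maps a subset of {"ACC", "SEN", "SEP"} to (value, decimals),
    e.g. {"ACC": (0.54167, 5), "SEP": (0.522, 3)}. All non-negative integer
    (T1, T2, F1, F2) summing to ``total_n`` are enumerated; a matrix matches
    when every stated metric, computed exactly, rounds to the stated value
    at its printed precision. Returns the unique solution plus the values of
    the remaining metrics, or raises NoSolution / AmbiguousSolution.
    """
    if len(known) < 2:
        raise ValueError("need at least two metrics to invert")
    unknown_keys = set(known) - {"ACC", "SEN", "SEP"}
    if unknown_keys:
        raise ValueError(f"unknown metrics {unknown_keys}")
    solutions = []
    for T1 in range(total_n + 1):
        for T2 in range(total_n + 1 - T1):
            for F1 in range(total_n + 1 - T1 - T2):
                F2 = total_n - T1 - T2 - F1
                cm = ConfusionMatrix(T1, T2, F1, F2)
                ok = True
                for name, (value, decimals) in known.items():
                    try:
                        metric = {"ACC": cm.acc, "SEN": cm.sen,
                                  "SEP": cm.sep}[name]
                    except MetricUndefined:
                        ok = False
                        break
                    if not _rounds_to(metric, value, decimals):
                        ok = False
                        break
                if ok:
                    solutions.append(cm)
    if not solutions:
        raise NoSolution(
            f"no confusion matrix with total {total_n} matches {known}")
    if len(solutions) > 1:
        raise AmbiguousSolution(solutions)
    cm = solutions[0]
    remaining = {}
    for name in ("ACC", "SEN", "SEP"):
        if name not in known:
            try:
                remaining[name] = {"ACC": cm.acc, "SEN": cm.sen,
                                   "SEP": cm.sep}[name]
            except MetricUndefined:
                remaining[name] = float("nan")
    return cm, remaining
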