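"""Soft-margin SVM with a third-order polynomial kernel, trained in the dual.

Each retained fluorescence spectrum is a 750-dimensional point; the
classifier separates melanoma-type from nevus-type spectra.  The kernel is
the inhomogeneous scaled polynomial

    K(x, z) = (1 + <x, z> / sigma^2)^d        (d = 3 by default)

and the solver minimizes the standard dual

    1/2 a' Q a - e' a    s.t.   y' a = 0,  0 <= a_i <= C,

with Q_ij = y_i y_j K(x_i, x_j), by coordinate ascent on
maximal-violating pairs (two dual variables per update — the smallest move
that respects the equality constraint).  Convergence is declared when the
maximal KKT violation m(a) - M(a) drops below ``tol``; correctness is
pinned to a direct quadratic-program oracle in the test suite, not to any
library's internals.

Class labels are 0 (benign) / 1 (malignant), mapped internally to -1 / +1.
Cross-validation folds partition *lesions*, never spectra: spectra from one
lesion share a label source and are spatially correlated, so spectrum-level
folds would leak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra_core import (
    ConvergenceError,
    DegenerateTrainingError,
    InvalidInputError,
)

__all__ = [
    "SVMModel",
    "TrainingReport",
    "poly_kernel",
    "kernel_matrix",
    "train_svm",
    "predict_spectrum",
    "kkt_residuals",
    "kfold_cv",
    "group_kfold_indices",
]

DEFAULT_C = 0.165
DEFAULT_DEGREE = 3
DEFAULT_SCALE = 1.0
DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 1_000_000

#: dual variables below this fraction of C are treated as zero
_SV_EPS = 1e-10


def poly_kernel(x: np.ndarray, z: np.ndarray, scale: float = DEFAULT_SCALE,
                degree: int = DEFAULT_DEGREE) -> float:
    """Inhomogeneous polynomial kernel ``(1 + <x,z>/scale^2)^degree``."""
    if scale <= 0:
        raise InvalidInputError(f"kernel scale must be positive, got {scale}")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise InvalidInputError("kernel arguments must have equal length")
    return float((1.0 + x @ z / scale**2) ** degree)


def kernel_matrix(X: np.ndarray, Z: np.ndarray, scale: float = DEFAULT_SCALE,
                  degree: int = DEFAULT_DEGREE) -> np.ndarray:
    """Pairwise kernel values, shape (len(X), len(Z))."""
    if scale <= 0:
        raise InvalidInputError(f"kernel scale must be positive, got {scale}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return (1.0 + X @ Z.T / scale**2) ** degree


@dataclass
class SVMModel:
    """Trained classifier: support vectors and dual solution.

    ``dual_coef[i]`` is ``alpha_i * y_i`` with ``y_i`` in {-1, +1}; the
    decision function is ``f(x) = sum_i dual_coef[i] K(sv_i, x) + bias`` and
    class 1 is predicted iff ``f(x) > 0`` (an exactly-zero margin is benign).
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    kernel_degree: int = DEFAULT_DEGREE
    kernel_scale: float = DEFAULT_SCALE
    box_constraint: float = DEFAULT_C

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise InvalidInputError(
                f"expected {self.support_vectors.shape[1]} features, "
                f"got {X.shape[1]}"
            )
        K = kernel_matrix(self.support_vectors, X, self.kernel_scale,
                          self.kernel_degree)
        return self.dual_coef @ K + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    # -- portable text serialization -------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "dermafluor-svm",
            "version": 1,
            "kernel_degree": int(self.kernel_degree),
            "kernel_scale": float(self.kernel_scale),
            "box_constraint": float(self.box_constraint),
            "bias": float(self.bias),
            "dual_coef": self.dual_coef.tolist(),
            "support_vectors": self.support_vectors.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVMModel":
        if d.get("format") != "dermafluor-svm":
            raise InvalidInputError("not a dermafluor SVM model document")
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            bias=float(d["bias"]),
            kernel_degree=int(d["kernel_degree"]),
            kernel_scale=float(d["kernel_scale"]),
            box_constraint=float(d["box_constraint"]),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SVMModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainingReport:
    """Per-fold cross-validation errors plus solver bookkeeping."""

    fold_errors: list[float]
    mean_cv_error: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        assert all(0.0 <= e <= 1.0 for e in self.fold_errors)
        if self.fold_errors:
            assert abs(self.mean_cv_error - float(np.mean(self.fold_errors))) < 1e-12


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_C,
    scale: float = DEFAULT_SCALE,
    degree: int = DEFAULT_DEGREE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    class_weight: str | dict[int, float] | None = None,
    seed: int = 0,
) -> SVMModel:
    """Solve the dual SVM by maximal-violating-pair coordinate ascent.

    Parameters
    ----------
    X, y:
        Training spectra (n x p) and binary labels in {0, 1}.
    C:
        Box constraint: upper bound on every dual variable.
    tol:
        Stopping threshold on the maximal KKT violation.
    class_weight:
        ``None`` (every point bounded by ``C``), ``"balanced"`` (per-class
        bound ``C * n / (2 * n_class)``, equalizing the total weight of the
        two classes), or an explicit ``{0: w0, 1: w1}`` multiplier map.
        Spectra inherit their lesion's diagnosis, so melanoma-looking
        spectra inside nevi are mislabelled by construction; balancing keeps
        the abundant benign class from swamping them (see docs/methods.md).
    seed:
        Unused by the deterministic solver; kept so callers can treat all
        trainers uniformly.

    Raises
    ------
    DegenerateTrainingError
        If only one class is present.
    ConvergenceError
        If the KKT gap is still above ``tol`` after ``max_iter`` updates;
        the error carries the remaining gap.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    n = X.shape[0]
    if y.shape[0] != n:
        raise InvalidInputError("X and y length mismatch")
    if not set(np.unique(y)) <= {0, 1}:
        raise InvalidInputError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training data contains a single class")
    if C <= 0:
        raise InvalidInputError(f"box constraint must be positive, got {C}")

    if class_weight is None:
        weights = {0: 1.0, 1: 1.0}
    elif class_weight == "balanced":
        weights = {c: n / (2.0 * np.sum(y == c)) for c in (0, 1)}
    elif isinstance(class_weight, dict):
        weights = {int(c): float(w) for c, w in class_weight.items()}
    else:
        raise InvalidInputError(f"unknown class_weight {class_weight!r}")
    Cs = C * np.array([weights[int(c)] for c in y])  # per-point box bound

    ys = np.where(y == 1, 1.0, -1.0)  # 0 -> -1, 1 -> +1
    K = kernel_matrix(X, X, scale, degree)
    Q = (ys[:, None] * ys[None, :]) * K

    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of 1/2 a'Qa - e'a
    it = 0
    while True:
        # m = max over I_up of -y_i g_i ; M = min over I_low of -y_j g_j
        yg = -ys * grad
        below_c = alpha < Cs * (1 - _SV_EPS)
        above_0 = alpha > _SV_EPS * Cs
        up = ((ys > 0) & below_c) | ((ys < 0) & above_0)
        low = ((ys > 0) & above_0) | ((ys < 0) & below_c)
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        j = int(np.flatnonzero(low)[np.argmin(yg[low])])
        gap = yg[i] - yg[j]
        if gap <= tol:
            break
        if it >= max_iter:
            raise ConvergenceError(
                f"dual solver: KKT gap {gap:.3e} > tol {tol:.1e} after "
                f"{max_iter} updates",
                gap=gap,
            )
        s = ys[i] * ys[j]
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        quad = max(quad, 1e-12)
        g_dir = grad[i] - s * grad[j]  # df/dt along (da_i, da_j) = (t, -s t)
        t = -g_dir / quad
        # feasibility bounds on t from both box constraints
        lo, hi = -alpha[i], Cs[i] - alpha[i]
        if s > 0:
            lo, hi = max(lo, alpha[j] - Cs[j]), min(hi, alpha[j])
        else:
            lo, hi = max(lo, -alpha[j]), min(hi, Cs[j] - alpha[j])
        t = float(np.clip(t, lo, hi))
        alpha[i] += t
        alpha[j] -= s * t
        grad += t * (Q[:, i] - s * Q[:, j])
        it += 1

    # bias from free support vectors, else midpoint of the KKT interval
    free = (alpha > _SV_EPS * Cs) & (alpha < Cs * (1 - _SV_EPS))
    yg = -ys * grad
    if np.any(free):
        bias = float(np.mean(yg[free]))
    else:
        bias = float((yg[i] + yg[j]) / 2.0)

    sv = alpha > _SV_EPS * Cs
    model = SVMModel(
        support_vectors=X[sv].copy(),
        dual_coef=(alpha * ys)[sv].copy(),
        bias=bias,
        kernel_degree=degree,
        kernel_scale=scale,
        box_constraint=C,
    )
    model.alpha_ = alpha  # full dual vector, for KKT diagnostics
    model.box_bounds_ = Cs  # per-point upper bounds (class weighting)
    model.n_iter_ = it
    return model


def predict_spectrum(model: SVMModel, x: np.ndarray) -> tuple[int, float]:
    """Class (0/1) and decision value for one spectrum; 1 iff f(x) > 0."""
    decision = float(model.decision_function(np.atleast_2d(x))[0])
    return (1 if decision > 0 else 0), decision


def kkt_residuals(model: SVMModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-training-point KKT residual of a trained model.

    Uses the full dual vector stored on the model: residual is
    ``max(0, 1 - y f)`` at ``alpha = 0``, ``max(0, y f - 1)`` at
    ``alpha = C``, and ``|y f - 1|`` for free support vectors.
    """
    alpha = getattr(model, "alpha_", None)
    if alpha is None:
        raise InvalidInputError("model does not carry its full dual vector")
    ys = np.where(np.asarray(y).ravel() == 1, 1.0, -1.0)
    yf = ys * model.decision_function(X)
    C = getattr(model, "box_bounds_", np.full(len(yf), model.box_constraint))
    res = np.empty_like(yf)
    at_zero = alpha <= _SV_EPS * C
    at_c = alpha >= C * (1 - _SV_EPS)
    free = ~(at_zero | at_c)
    res[at_zero] = np.maximum(0.0, 1.0 - yf[at_zero])
    res[at_c] = np.maximum(0.0, yf[at_c] - 1.0)
    res[free] = np.abs(yf[free] - 1.0)
    return res


def group_kfold_indices(
    groups: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Partition samples into k folds by group (lesion), sizes within 1.

    Returns a list of index arrays, one per validation fold.
    """
    groups = np.asarray(groups)
    unique = np.unique(groups)
    if k < 2:
        raise InvalidInputError(f"k must be >= 2, got {k}")
    if len(unique) < k:
        raise InvalidInputError(
            f"need at least k={k} groups, got {len(unique)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique)
    folds = np.array_split(order, k)
    return [np.flatnonzero(np.isin(groups, fold)) for fold in folds]


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    k: int = 20,
    C: float = DEFAULT_C,
    scale: float = DEFAULT_SCALE,
    degree: int = DEFAULT_DEGREE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    class_weight: str | dict[int, float] | None = None,
    seed: int = 0,
) -> TrainingReport:
    """Lesion-wise k-fold cross-validation of per-spectrum error.

    Each fold holds out whole lesions; the model is trained on the rest and
    the fold error is the misclassified fraction of held-out spectra.  The
    mean fold error estimates generalization to unseen lesions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    folds = group_kfold_indices(np.asarray(groups), k, seed)
    errors: list[float] = []
    total_iter = 0
    converged = True
    for val_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[val_idx] = False
        try:
            model = train_svm(
                X[train_mask], y[train_mask], C=C, scale=scale, degree=degree,
                tol=tol, max_iter=max_iter, class_weight=class_weight,
            )
        except ConvergenceError:
            converged = False
            continue
        total_iter += model.n_iter_
        pred = model.predict(X[val_idx])
        errors.append(float(np.mean(pred != y[val_idx])))
    return TrainingReport(
        fold_errors=errors,
        mean_cv_error=float(np.mean(errors)) if errors else 1.0,
        iterations=total_iter,
        converged=converged,
    )
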