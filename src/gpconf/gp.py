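"""Gaussian-process regression on descriptor vectors.

The surrogate is standard GP regression with observation-noise hyperparameter
``lambda``: with kernel matrices K (train/train), L (train/test) and M
(test/test),

    mean     = y_center + L^T (K + lambda*I)^{-1} (y - y_center)
             = y_center + L^T alpha
    variance = diag(M) - diag(L^T (K + lambda*I)^{-1} L)

The predictive variance is the epistemic (function) uncertainty only; the
noise term ``lambda`` is not added back, because the adaptive gate compares
test variances against training-point variances and a constant offset would
cancel. For the linear kernel the predictions coincide with kernel ridge
regression.

``lambda`` is selected by stratified k-fold cross-validated MAE over a
logarithmic grid (default 1e-8 .. 1e4, 13 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.spatial.distance import cdist

DEFAULT_LAMBDA_GRID = np.logspace(-8, 4, 13)
_JITTER = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """Covariance function: ``linear`` (dot product) or ``squared_exponential``
    with length scale ``l``, k(a,b) = exp(-||a-b||^2 / (2 l^2))."""

    kind: str = "linear"
    length_scale: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "squared_exponential"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "squared_exponential":
            if self.length_scale is None or self.length_scale <= 0:
                raise ValueError("squared_exponential kernel needs length_scale > 0")


LINEAR = KernelSpec("linear")


def kernel_eval(a: np.ndarray, b: np.ndarray, spec: KernelSpec = LINEAR) -> float:
    """Evaluate the kernel on a single pair of vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"kernel arguments must be equal-length vectors, got {a.shape} vs {b.shape}")
    return float(kernel_matrix(a[None, :], b[None, :], spec)[0, 0])


def kernel_matrix(A: np.ndarray, B: np.ndarray, spec: KernelSpec = LINEAR) -> np.ndarray:
    """Kernel matrix between the rows of A (n x d) and B (m x d)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if spec.kind == "linear":
        return A @ B.T
    sq = cdist(A, B, "sqeuclidean")
    return np.exp(-sq / (2.0 * spec.length_scale**2))


def _kernel_diag(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.kind == "linear":
        return (X**2).sum(axis=1)
    return np.ones(len(X))


@dataclass
class GPModel:
    """Fitted GP surrogate.

    ``alpha`` solves (K + lambda*I) alpha = y - y_center; ``train_variances``
    holds the predictive variances of the training points themselves (the
    reference distribution for the adaptive gate). The Cholesky factor of
    (K + lambda*I) is cached for prediction.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    alpha: np.ndarray
    lam: float
    kernel: KernelSpec
    y_center: float = 0.0
    train_variances: np.ndarray | None = None
    _factor: tuple = field(default=None, repr=False, compare=False)

    @property
    def n_train(self) -> int:
        return len(self.y_train)


def _factorize(K: np.ndarray, lam: float):
    A = K + lam * np.eye(len(K))
    try:
        return cho_factor(A, lower=True)
    except LinAlgError:
        try:
            return cho_factor(A + _JITTER * np.eye(len(K)), lower=True)
        except LinAlgError:
            raise LinAlgError(
                "kernel matrix factorization failed; use a noise level lambda > 0"
            ) from None


def fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    spec: KernelSpec = LINEAR,
    center: bool = False,
    with_train_variance: bool = True,
) -> GPModel:
    """Fit the GP: solve (K + lambda*I) alpha = y - y_center.

    ``center=True`` subtracts the training-energy mean before solving (and
    adds it back at prediction time). ``with_train_variance=False`` skips the
    O(n^3) training-variance pass for inner loops that never gate on variance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y) or len(y) < 1:
        raise ValueError("X and y must have matching nonzero length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("fit requires finite inputs")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y_center = float(y.mean()) if center else 0.0
    K = kernel_matrix(X, X, spec)
    factor = _factorize(K, lam)
    alpha = cho_solve(factor, y - y_center)
    model = GPModel(X, y, alpha, float(lam), spec, y_center=y_center, _factor=factor)
    if with_train_variance:
        model.train_variances = predict_variance(model, X)
    return model


def predict_mean(model: GPModel, Xs: np.ndarray) -> np.ndarray:
    """Posterior mean at the rows of Xs (kJ/mol)."""
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    if Xs.shape[0] == 0:
        return np.empty(0)
    L = kernel_matrix(model.X_train, Xs, model.kernel)
    return model.y_center + L.T @ model.alpha


def predict_variance(model: GPModel, Xs: np.ndarray) -> np.ndarray:
    """Posterior (epistemic) variance at the rows of Xs.

    Values in [-1e-8, 0) are clipped to 0; anything more negative signals a
    broken factorization and raises.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    if Xs.shape[0] == 0:
        return np.empty(0)
    L = kernel_matrix(model.X_train, Xs, model.kernel)
    S = cho_solve(model._factor, L)
    var = _kernel_diag(Xs, model.kernel) - np.einsum("ij,ij->j", L, S)
    if np.any(var < -1e-8):
        raise FloatingPointError(
            f"predictive variance {var.min():.3e} below numerical tolerance"
        )
    return np.clip(var, 0.0, None)


def _cv_mae_table(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    spec: KernelSpec,
    fold_of: np.ndarray,
    k: int,
) -> np.ndarray:
    """Mean CV MAE per grid value. Uses one eigendecomposition per fold (of the
    d x d Gram matrix for the linear kernel when d < n, else of K) so the whole
    lambda grid costs a single factorization."""
    n, d = X.shape
    maes = np.zeros((k, len(grid)))
    primal = spec.kind == "linear" and d < n
    K = None if primal else kernel_matrix(X, X, spec)
    for f in range(k):
        te = fold_of == f
        tr = ~te
        ytr = y[tr]
        if primal:
            Xtr, Xte = X[tr], X[te]
            w, V = np.linalg.eigh(Xtr.T @ Xtr)
            w = np.clip(w, 0.0, None)
            b = V.T @ (Xtr.T @ ytr)
            for g, lam in enumerate(grid):
                coef = V @ (b / (w + lam))
                maes[f, g] = np.abs(Xte @ coef - y[te]).mean()
        else:
            Ktr = K[np.ix_(tr, tr)]
            Lte = K[np.ix_(te, tr)]
            w, V = np.linalg.eigh(Ktr)
            w = np.clip(w, 0.0, None)
            b = V.T @ ytr
            for g, lam in enumerate(grid):
                alpha = V @ (b / (w + lam))
                maes[f, g] = np.abs(Lte @ alpha - y[te]).mean()
    return maes.mean(axis=0)


def select_noise(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray | None = None,
    spec: KernelSpec = LINEAR,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Choose lambda minimizing stratified k-fold CV MAE over a log grid.

    Returns the chosen value (ties break toward the smallest lambda) and the
    per-lambda CV MAE table.
    """
    from .validation import stratified_folds

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("lambda grid must be non-empty and strictly increasing")
    if np.any(grid <= 0):
        raise ValueError("lambda grid values must be positive")
    if len(y) < k:
        raise ValueError(f"n={len(y)} < k={k} folds; use a smaller k")
    folds = stratified_folds(y, k, seed)
    mae = _cv_mae_table(X, y, grid, spec, folds.fold_of, k)
    best = int(np.argmin(mae))  # argmin takes the first (smallest-lambda) tie
    table = pd.DataFrame({"lambda": grid, "cv_mae": mae})
    return float(grid[best]), table


def save_model(model: GPModel, path: str | Path) -> None:
    """Serialize a fitted model to an .npz archive."""
    np.savez(
        path,
        X_train=model.X_train,
        y_train=model.y_train,
        alpha=model.alpha,
        lam=model.lam,
        y_center=model.y_center,
        train_variances=(
            np.empty(0) if model.train_variances is None else model.train_variances
        ),
        kernel_kind=model.kernel.kind,
        length_scale=(
            np.nan if model.kernel.length_scale is None else model.kernel.length_scale
        ),
    )


def load_model(path: str | Path) -> GPModel:
    """Load a model saved by :func:`save_model`, re-deriving the factorization."""
    z = np.load(path)
    ls = float(z["length_scale"])
    spec = KernelSpec(str(z["kernel_kind"]), None if np.isnan(ls) else ls)
    K = kernel_matrix(z["X_train"], z["X_train"], spec)
    tv = z["train_variances"]
    return GPModel(
        X_train=z["X_train"],
        y_train=z["y_train"],
        alpha=z["alpha"],
        lam=float(z["lam"]),
        kernel=spec,
        y_center=float(z["y_center"]),
        train_variances=None if tv.size == 0 else tv,
        _factor=_factorize(K, float(z["lam"])),
    )
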