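"""Energy-stratified cross-validation, error metrics and randomization tests.

Folds are stratified by the response: samples are sorted by energy, cut into
consecutive blocks of k, and the members of each block are dealt to distinct
folds in a seeded random order, so every fold sees the full energy range.

Reported metrics follow the conventions of the surrogate-modelling literature:
RMSE and MAE in kJ/mol, MAE(%) as a percentage of the *training* energy range,
and R^2 as the squared Pearson correlation between predicted and reference
values — note this is not the coefficient of determination and the two differ
for biased predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import gp
from .gp import DEFAULT_LAMBDA_GRID, LINEAR, KernelSpec


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per sample; fold sizes differ by at most one."""

    fold_of: np.ndarray
    k: int
    seed: int

    def fold_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == f)


@dataclass(frozen=True)
class MetricReport:
    """RMSE/MAE (kJ/mol), MAE as % of training range, squared Pearson r, n."""

    rmse: float
    mae: float
    mae_pct: float
    r2: float
    n: int


def stratified_folds(y, k: int, seed: int) -> FoldAssignment:
    """Sort-and-deal stratification of n samples into k folds by response value."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    fold_of = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = order[start : start + k]
        fold_of[block] = rng.permutation(k)[: len(block)]
    return FoldAssignment(fold_of, k, seed)


def stratified_sample(y, size: int, seed: int) -> np.ndarray:
    """Indices of an energy-stratified sample: one seeded pick per quantile block."""
    y = np.asarray(y, dtype=float).ravel()
    if not 1 <= size <= len(y):
        raise ValueError(f"need 1 <= size <= n, got size={size}, n={len(y)}")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    bounds = np.linspace(0, len(y), size + 1).round().astype(int)
    return np.array([rng.choice(order[a:b]) for a, b in zip(bounds[:-1], bounds[1:])])


def compute_metrics(y_true, y_pred, train_range: float) -> MetricReport:
    """Error metrics of one evaluation; r2 is NaN when either side is constant."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    if train_range <= 0:
        raise ValueError("train_range must be positive")
    err = y_pred - y_true
    rmse = float(np.sqrt((err**2).mean()))
    mae = float(np.abs(err).mean())
    if y_true.size < 2 or np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        r2 = float("nan")
    else:
        r2 = float(stats.pearsonr(y_true, y_pred).statistic ** 2)
    return MetricReport(rmse, mae, 100.0 * mae / train_range, r2, int(y_true.size))


def summarize(reports: list[MetricReport]) -> dict[str, float]:
    """Mean and std of each metric over a list of fold reports."""
    out = {}
    for name in ("rmse", "mae", "mae_pct", "r2"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[f"{name}_mean"] = float(np.nanmean(vals))
        out[f"{name}_std"] = float(np.nanstd(vals))
    out["n_reports"] = len(reports)
    return out


@dataclass
class NestedCVResult:
    """Fold-level reports plus pooled out-of-fold predictions per repetition."""

    reports: list[MetricReport]
    oof_predictions: np.ndarray  # (reps, n)
    lambdas: np.ndarray  # (reps, k) chosen noise level per outer fold
    k: int
    reps: int

    def summary(self) -> dict[str, float]:
        """Mean +/- std over all fold reports and over repetition means."""
        out = summarize(self.reports)
        per_rep = np.array(
            [
                [
                    np.nanmean(
                        [getattr(r, m) for r in self.reports[rep * self.k : (rep + 1) * self.k]]
                    )
                    for rep in range(self.reps)
                ]
                for m in ("rmse", "mae", "mae_pct", "r2")
            ]
        )
        for i, m in enumerate(("rmse", "mae", "mae_pct", "r2")):
            out[f"{m}_rep_std"] = float(np.nanstd(per_rep[i]))
        return out

    @property
    def fold_maes(self) -> np.ndarray:
        return np.array([r.mae for r in self.reports])


def nested_cv(
    X,
    y,
    k: int = 10,
    reps: int = 10,
    grid=None,
    spec: KernelSpec = LINEAR,
    seed: int = 0,
    center: bool = False,
    standardize: bool = False,
    inner_k: int = 10,
) -> NestedCVResult:
    """Repeated stratified k-fold CV with inner-loop noise selection.

    Per repetition (seed + rep) and outer fold, ``lambda`` is chosen by
    :func:`gpconf.gp.select_noise` on the training portion only, the model is
    fit on that portion, and metrics are computed on the held-out fold with
    the training portion's energy range. All preprocessing (centering,
    standardization) is likewise fit on the training portion only.
    """
    from .descriptor import standardize_features

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 2 * k:
        raise ValueError(f"nested CV needs n >= 2k (n={len(y)}, k={k})")
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    reports: list[MetricReport] = []
    oof = np.full((reps, len(y)), np.nan)
    lambdas = np.zeros((reps, k))
    for rep in range(reps):
        folds = stratified_folds(y, k, seed + rep)
        for f in range(k):
            te = folds.fold_of == f
            tr = ~te
            Xtr, Xte = X[tr], X[te]
            if standardize:
                Xtr, Xte, _ = standardize_features(Xtr, Xte)
            lam, _ = gp.select_noise(Xtr, y[tr], grid, spec, k=inner_k, seed=seed + rep)
            model = gp.fit(Xtr, y[tr], lam, spec, center=center, with_train_variance=False)
            pred = gp.predict_mean(model, Xte)
            reports.append(compute_metrics(y[te], pred, float(np.ptp(y[tr]))))
            oof[rep, te] = pred
            lambdas[rep, f] = lam
    return NestedCVResult(reports, oof, lambdas, k, reps)


@dataclass
class RandomizationResult:
    """Real vs randomized CV performance and the Mann-Whitney comparison."""

    mode: str
    real: NestedCVResult
    randomized: NestedCVResult
    p_value: float
    real_lambda: float
    randomized_lambdas: np.ndarray

    def summary(self) -> dict[str, float]:
        return {
            "mode": self.mode,
            "p_value": self.p_value,
            "real_mae_mean": float(self.real.fold_maes.mean()),
            "randomized_mae_mean": float(self.randomized.fold_maes.mean()),
            "real_lambda": self.real_lambda,
            "randomized_lambda_median": float(np.median(self.randomized_lambdas)),
        }


def y_randomization(
    X,
    y,
    mode: str = "permute_labels",
    k: int = 10,
    reps: int = 10,
    cv_seed: int = 0,
    perm_seed: int = 0,
    grid=None,
    spec: KernelSpec = LINEAR,
    real_result: NestedCVResult | None = None,
    permutation: np.ndarray | None = None,
) -> RandomizationResult:
    """Chance-correlation control by scrambling labels or descriptors.

    ``permute_labels`` shuffles the response as a block; ``permute_descriptors``
    shuffles every descriptor column independently across samples, destroying
    the joint structure while preserving marginals. The same CV protocol is run
    on real and scrambled data and the two sets of fold-level MAEs are compared
    with a two-sided Mann-Whitney U test (normal approximation with tie
    correction). ``permutation`` overrides the seeded shuffles (e.g. the
    identity, as a self-check that scrambled == real under no-op scrambling).

    Also reported: the noise level the grid search selects on real data versus
    on scrambled data — scrambling should drive the selected noise level up.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if mode not in ("permute_labels", "permute_descriptors"):
        raise ValueError(f"unknown randomization mode {mode!r}")
    rng = np.random.default_rng(perm_seed)
    n = len(y)
    if mode == "permute_labels":
        perm = rng.permutation(n) if permutation is None else np.asarray(permutation)
        Xr, yr = X, y[perm]
    else:
        Xr = X.copy()
        for col in range(X.shape[1]):
            perm = rng.permutation(n) if permutation is None else np.asarray(permutation)
            Xr[:, col] = Xr[perm, col]
        yr = y
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    if real_result is None:
        real_result = nested_cv(X, y, k=k, reps=reps, grid=grid, spec=spec, seed=cv_seed)
    randomized = nested_cv(Xr, yr, k=k, reps=reps, grid=grid, spec=spec, seed=cv_seed)
    u = stats.mannwhitneyu(
        real_result.fold_maes,
        randomized.fold_maes,
        alternative="two-sided",
        method="asymptotic",
    )
    real_lam, _ = gp.select_noise(X, y, grid, spec, k=min(10, n), seed=cv_seed)
    return RandomizationResult(
        mode=mode,
        real=real_result,
        randomized=randomized,
        p_value=float(u.pvalue),
        real_lambda=real_lam,
        randomized_lambdas=randomized.lambdas.ravel(),
    )
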