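"""Learning on the fly: variance-gated prediction with retraining.

For each incoming conformation the controller computes the GP predictive
variance. If it falls below the kappa-quantile of the *training points'* own
predictive variances, the conformation is inside the model's domain of
applicability and its energy is predicted; otherwise the expensive oracle
(the reference quantum-chemistry calculation, here any callable) is invoked,
the result is appended to the training set, and the model is refit. kappa
trades prediction accuracy against the fraction of oracle calls avoided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import gp
from .chem_io import Conformation, Ensemble, concat_ensembles
from .descriptor import featurize_ensemble, vectorize
from .gp import DEFAULT_LAMBDA_GRID, LINEAR, GPModel, KernelSpec
from .validation import compute_metrics, stratified_sample

Oracle = Callable[[Conformation], float]


@dataclass
class AdaptiveConfig:
    """Controller settings.

    kappa is the quantile of training-point predictive variances used as the
    acceptance threshold (0 rejects everything, 1 accepts anything at or below
    the largest training variance). ``retrain_lambda`` decides whether the
    noise level chosen on the initial training set is held fixed (default) or
    re-optimized by grid CV after every retrain. ``retrain=False`` freezes the
    model entirely (pure gating, no learning) — useful for analysis.
    """

    initial_size: int = 50
    kappa: float = 0.95
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())
    kernel: KernelSpec = LINEAR
    retrain_lambda: str = "fixed_after_init"
    retrain: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")
        if self.initial_size < 2:
            raise ValueError("initial_size must be >= 2")
        if self.retrain_lambda not in ("fixed_after_init", "reoptimize_each"):
            raise ValueError(f"unknown retrain_lambda mode {self.retrain_lambda!r}")


@dataclass
class AdaptiveResult:
    """Outcome of one adaptive pass over a conformation stream."""

    decisions: list[str]  # "predicted" | "computed", in stream order
    conf_ids: list[str]
    predictions: dict[str, float]  # conf_id -> predicted energy (kJ/mol)
    computed: dict[str, float]  # conf_id -> oracle energy (kJ/mol)
    n_predicted: int
    initial_size: int
    final_train_size: int
    lam: float
    predicted_rmse: float | None = None
    predicted_mae: float | None = None
    predicted_r2: float | None = None

    @property
    def savings(self) -> float:
        """Fraction of oracle calls avoided over the stream."""
        return self.n_predicted / max(len(self.decisions), 1)


def variance_threshold(model: GPModel, kappa: float) -> float:
    """Empirical kappa-quantile (linear interpolation) of the training-point
    predictive variances."""
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must be in [0, 1]")
    if model.train_variances is None or model.n_train < 2:
        raise ValueError("model must cache train_variances for >= 2 training points")
    return float(np.quantile(model.train_variances, kappa))


def _select_initial(
    stream: Ensemble, config: AdaptiveConfig, initial_pool: Ensemble | None
) -> tuple[list[Conformation], list[Conformation]]:
    """Initial training conformations + the remaining stream items, in order.

    The initial set is an energy-stratified sample: from ``initial_pool`` when
    given, otherwise from the stream itself (whose sampled members are then
    removed from the pass). Stratification uses stored reference energies;
    without them the first ``initial_size`` items are taken as-is.
    """
    pool = initial_pool if initial_pool is not None else stream
    if len(pool) < config.initial_size:
        raise ValueError(
            f"initial pool has {len(pool)} conformations < initial_size={config.initial_size}"
        )
    e = pool.energies()
    if np.all(np.isfinite(e)):
        idx = stratified_sample(e, config.initial_size, config.seed)
    else:
        idx = np.arange(config.initial_size)
    chosen = [pool[int(i)] for i in idx]
    chosen_ids = {c.conf_id for c in chosen}
    rest = [c for c in stream if c.conf_id not in chosen_ids]
    return chosen, rest


def run_on_the_fly(
    stream: Ensemble,
    oracle: Oracle,
    config: AdaptiveConfig | None = None,
    initial_pool: Ensemble | None = None,
    evaluate: bool = True,
) -> AdaptiveResult:
    """One adaptive pass over ``stream`` in order.

    The oracle is called for every initial-training conformation, and for each
    stream item whose predictive variance is at or above the gate. After every
    oracle call the model is refit on the enlarged training set and the gate
    threshold is recomputed from the new training variances.

    With ``evaluate=True``, predicted items are scored against their stored
    reference energies (falling back to extra oracle calls that are *not*
    counted as computed) and RMSE/MAE/R^2 of the predicted subset are filled in.
    """
    config = config or AdaptiveConfig()
    if len(stream) < 1:
        raise ValueError("stream must contain at least one conformation")

    def call_oracle(conf: Conformation) -> float:
        try:
            return float(oracle(conf))
        except Exception as exc:
            raise RuntimeError(f"oracle failed on conformer {conf.conf_id!r}: {exc}") from exc

    initial, items = _select_initial(stream, config, initial_pool)
    X_train = [vectorize(c).values for c in initial]
    y_train = [call_oracle(c) for c in initial]
    lam, _ = gp.select_noise(
        np.array(X_train), np.array(y_train), config.lambda_grid, config.kernel,
        k=min(10, len(y_train)), seed=config.seed,
    )
    model = gp.fit(np.array(X_train), np.array(y_train), lam, config.kernel)
    threshold = variance_threshold(model, config.kappa)

    decisions: list[str] = []
    predictions: dict[str, float] = {}
    computed: dict[str, float] = {}
    for conf in items:
        x = vectorize(conf).values[None, :]
        var = float(gp.predict_variance(model, x)[0])
        # kappa = 0 means "no confidence region": everything is recomputed,
        # even items whose variance happens to undercut the smallest
        # training-point variance
        if config.kappa > 0 and var < threshold:
            decisions.append("predicted")
            predictions[conf.conf_id] = float(gp.predict_mean(model, x)[0])
        else:
            decisions.append("computed")
            e = call_oracle(conf)
            computed[conf.conf_id] = e
            if config.retrain:
                X_train.append(x[0])
                y_train.append(e)
                if config.retrain_lambda == "reoptimize_each":
                    lam, _ = gp.select_noise(
                        np.array(X_train), np.array(y_train), config.lambda_grid,
                        config.kernel, k=min(10, len(y_train)), seed=config.seed,
                    )
                model = gp.fit(np.array(X_train), np.array(y_train), lam, config.kernel)
                threshold = variance_threshold(model, config.kappa)

    result = AdaptiveResult(
        decisions=decisions,
        conf_ids=[c.conf_id for c in items],
        predictions=predictions,
        computed=computed,
        n_predicted=len(predictions),
        initial_size=config.initial_size,
        final_train_size=len(y_train),
        lam=lam,
    )
    if evaluate and predictions:
        by_id = {c.conf_id: c for c in items}
        truth, pred = [], []
        for cid, p in predictions.items():
            conf = by_id[cid]
            truth.append(conf.energy if conf.energy is not None else call_oracle(conf))
            pred.append(p)
        rng = np.ptp(np.array(y_train))
        rep = compute_metrics(truth, pred, train_range=rng if rng > 0 else 1.0)
        result.predicted_rmse = rep.rmse
        result.predicted_mae = rep.mae
        result.predicted_r2 = rep.r2
    return result


def _stream_from_runs(
    runs: Sequence[Ensemble], order: Sequence[int]
) -> tuple[Ensemble, Ensemble]:
    """(initial pool, stream) for one ordering of the runs: the pool is the
    first run in the ordering, the stream everything in ordering sequence."""
    ordered = [runs[i] for i in order]
    return ordered[0], concat_ensembles(ordered)


def kappa_tradeoff(
    runs: Ensemble | Sequence[Ensemble],
    oracle: Oracle,
    kappa_list: Sequence[float],
    config: AdaptiveConfig | None = None,
    average_orderings: bool = False,
) -> pd.DataFrame:
    """Accuracy-versus-savings table over a grid of gate quantiles.

    One full adaptive run per kappa with a common seed and initialization.
    ``runs`` may be a single ensemble or one ensemble per MD run; with
    ``average_orderings=True`` every permutation of the runs is streamed and
    the table reports mean and std over orderings (all 24 for four runs).
    """
    config = config or AdaptiveConfig()
    kappa_list = list(kappa_list)
    if sorted(kappa_list) != kappa_list:
        raise ValueError("kappa_list must be sorted ascending")
    multi = not isinstance(runs, Ensemble)
    orderings: list[tuple[int, ...]]
    if multi and average_orderings:
        orderings = list(permutations(range(len(runs))))
    elif multi:
        orderings = [tuple(range(len(runs)))]
    else:
        orderings = [(0,)]
    rows = []
    for kappa in kappa_list:
        per_order = []
        for order in orderings:
            cfg = AdaptiveConfig(
                initial_size=config.initial_size,
                kappa=kappa,
                lambda_grid=config.lambda_grid,
                kernel=config.kernel,
                retrain_lambda=config.retrain_lambda,
                retrain=config.retrain,
                seed=config.seed,
            )
            if multi:
                pool, stream = _stream_from_runs(runs, order)
                res = run_on_the_fly(stream, oracle, cfg, initial_pool=pool)
            else:
                res = run_on_the_fly(runs, oracle, cfg)
            per_order.append(
                (res.n_predicted, res.predicted_mae, res.predicted_r2, res.savings)
            )
        arr = np.array(per_order, dtype=float)
        with np.errstate(invalid="ignore"):
            rows.append(
                {
                    "kappa": kappa,
                    "m_predicted": float(np.nanmean(arr[:, 0])),
                    "m_predicted_std": float(np.nanstd(arr[:, 0])),
                    "mae": float(np.nanmean(arr[:, 1])) if np.any(np.isfinite(arr[:, 1])) else np.nan,
                    "mae_std": float(np.nanstd(arr[:, 1])) if np.any(np.isfinite(arr[:, 1])) else np.nan,
                    "r2": float(np.nanmean(arr[:, 2])) if np.any(np.isfinite(arr[:, 2])) else np.nan,
                    "savings": float(np.nanmean(arr[:, 3])),
                }
            )
    return pd.DataFrame(rows)
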