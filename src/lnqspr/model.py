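"""Cross-validated dense-network ensemble for logK regression.

The estimator follows the small-data protocol common in QSPR work on
stability constants: the curated set is split 80/20 with endpoint
stratification, the training 80% is shuffled into 10 folds, one
multilayer perceptron is fitted per fold on its 90% with early
stopping on the held-out 10%, and the ensemble prediction is the mean
of the sub-model outputs mapped back to logK units.  Targets are
MinMax-scaled before fitting; binary fingerprint features are
numerically unchanged by MinMax scaling, so features enter the network
as 0/1.

The module is organised statsmodels-style: build a
:class:`StabilityModel` from data, call :meth:`~StabilityModel.fit`,
and work with the returned :class:`StabilityResults`.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.neural_network import MLPRegressor

from .data import (
    LigandRecord,
    ScalerState,
    SplitSpec,
    fit_scaler,
    make_folds,
    stratified_split,
)
from .exceptions import ParameterError, TrainingError
from .fingerprints import FingerprintMatrix, FingerprintSpec, fingerprint_dataset


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimisation settings for one sub-model.

    The 3-layer, 512-node default is the accuracy/cost compromise for
    datasets of a few hundred ligands; all settings are exposed.
    ``dropout_rate`` is input-layer dropout, realised as per-epoch
    Bernoulli masking of the training features with inverted scaling
    (the scikit-learn backend has no hidden-layer dropout).  On sparse
    binary fingerprints it is the regulariser that stops the network
    from memorising individual bits, which matters when the ensemble
    is later decoded bit by bit.
    """

    n_layers: int = 3
    n_nodes: int = 512
    l2_strength: float = 1e-4
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_layers <= 5:
            raise ValueError("n_layers must lie in [1, 5]")
        if not 16 <= self.n_nodes <= 4096:
            raise ValueError("n_nodes must lie in [16, 4096]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.l2_strength < 0 or self.learning_rate <= 0:
            raise ValueError("l2_strength must be >= 0 and learning_rate > 0")


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Coefficient of determination and RMSE (logK units).

    R2 is 1 - SS_res/SS_tot with SS_tot taken about the evaluated
    set's own mean; a constant ``y_true`` makes R2 undefined.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length vectors (n >= 2)")
    if np.ptp(y_true) == 0:
        raise ValueError("R^2 is undefined for a constant y_true")
    return float(r2_score(y_true, y_pred)), float(
        np.sqrt(mean_squared_error(y_true, y_pred))
    )


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed * 100_003 + 7 * fold + 1) % (2**31 - 1))


def _fit_one(
    X_fit: np.ndarray,
    y_fit: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: NetConfig,
    fold: int,
) -> MLPRegressor:
    """Train one MLP with early stopping on the fold's validation split."""
    net = MLPRegressor(
        hidden_layer_sizes=(config.n_nodes,) * config.n_layers,
        alpha=config.l2_strength,
        batch_size=min(config.batch_size, len(X_fit)),
        learning_rate_init=config.learning_rate,
        random_state=_fold_seed(config.seed, fold),
    )
    best = np.inf
    best_epoch = 0
    best_state: tuple | None = None
    drop_rng = np.random.default_rng(_fold_seed(config.seed, fold))
    p = config.dropout_rate
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for epoch in range(config.max_epochs):
            if p > 0.0:
                # input-unit dropout with inverted scaling; validation
                # is always evaluated on unperturbed features
                mask = drop_rng.random(X_fit.shape) >= p
                net.partial_fit(X_fit * mask / (1.0 - p), y_fit)
            else:
                net.partial_fit(X_fit, y_fit)
            if not np.isfinite(net.loss_):
                raise TrainingError(f"non-finite loss in fold {fold} at epoch {epoch}")
            val = float(np.sqrt(np.mean((net.predict(X_val) - y_val) ** 2)))
            if val < best - 1e-5:
                best, best_epoch = val, epoch
                best_state = (
                    [c.copy() for c in net.coefs_],
                    [b.copy() for b in net.intercepts_],
                )
            if epoch - best_epoch >= config.patience:
                break
    if best_state is not None:
        net.coefs_, net.intercepts_ = best_state
    return net


@dataclass
class ModelEnsemble:
    """The CV sub-models plus the scaler; predicts by averaging."""

    sub_models: list[MLPRegressor]
    scaler: ScalerState
    config: NetConfig
    folds: list[tuple[np.ndarray, np.ndarray]]

    @property
    def n_features(self) -> int:
        return self.sub_models[0].n_features_in_

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean of the sub-model outputs, inverse-scaled to logK."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"X must have {self.n_features} columns, got {X.shape}"
            )
        scaled = np.mean([m.predict(X) for m in self.sub_models], axis=0)
        return self.scaler.inverse_target(scaled)

    def predict_function(self) -> Callable[[np.ndarray], np.ndarray]:
        """The ensemble-average map as a plain vectorised function."""
        return self.predict


def train_ensemble(
    X_train: np.ndarray,
    y_train: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    config: NetConfig | None = None,
) -> ModelEnsemble:
    """Fit one sub-model per CV fold.

    ``folds`` holds (fit, validation) index pairs *into the rows of
    X_train*; each sub-model early-stops on its own validation split.
    Per-fold seeds derive deterministically from ``config.seed``.
    """
    config = config or NetConfig()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    scaler = fit_scaler(X_train, y_train)
    ys = scaler.transform_target(y_train)
    subs = []
    for k, (fit_idx, val_idx) in enumerate(folds):
        subs.append(
            _fit_one(
                X_train[fit_idx], ys[fit_idx],
                X_train[val_idx], ys[val_idx],
                config, k,
            )
        )
    return ModelEnsemble(
        sub_models=subs, scaler=scaler, config=config,
        folds=[(np.asarray(f), np.asarray(v)) for f, v in folds],
    )


@dataclass
class EvalReport:
    """Validation and test metrics of a fitted ensemble."""

    r2_validation: float
    rmse_validation: float
    r2_test: float | None
    rmse_test: float | None
    per_fold: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "r2_validation": self.r2_validation,
            "rmse_validation": self.rmse_validation,
            "r2_test": self.r2_test,
            "rmse_test": self.rmse_test,
            "per_fold": self.per_fold.to_dict(orient="records"),
        }


class StabilityModel:
    """logK regression model over fingerprint features.

    Parameters
    ----------
    endog : array, logK values for all molecules.
    exog : binary fingerprint matrix, one row per molecule.
    split_spec : controls the stratified train/test split and folds.

    Use :meth:`from_records` to start from ligand records and have the
    fingerprints computed here.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        split_spec: SplitSpec | None = None,
        fingerprints: FingerprintMatrix | None = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog disagree on the number of molecules")
        self.split_spec = split_spec or SplitSpec()
        self.fingerprints = fingerprints
        self.train_idx, self.test_idx = stratified_split(self.endog, self.split_spec)
        self.folds = make_folds(self.train_idx, self.split_spec)

    @classmethod
    def from_records(
        cls,
        records: Sequence[LigandRecord],
        fingerprint_spec: FingerprintSpec | None = None,
        split_spec: SplitSpec | None = None,
    ) -> "StabilityModel":
        fp = fingerprint_dataset([r.smiles for r in records], fingerprint_spec)
        y = np.array([r.logk for r in records], dtype=float)
        return cls(y, fp.X.astype(float), split_spec=split_spec, fingerprints=fp)

    def fit(self, config: NetConfig | None = None) -> "StabilityResults":
        config = config or NetConfig()
        # fold indices are positions within the training block
        pos = {g: i for i, g in enumerate(self.train_idx)}
        local_folds = [
            (
                np.array([pos[g] for g in fit_idx]),
                np.array([pos[g] for g in val_idx]),
            )
            for fit_idx, val_idx in self.folds
        ]
        ensemble = train_ensemble(
            self.exog[self.train_idx], self.endog[self.train_idx],
            local_folds, config,
        )
        return StabilityResults(self, ensemble)


class StabilityResults:
    """Fitted ensemble plus its evaluation report."""

    def __init__(self, model: StabilityModel, ensemble: ModelEnsemble) -> None:
        self.model = model
        self.ensemble = ensemble
        self.report = self._evaluate()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.ensemble.predict(X)

    def _evaluate(self) -> EvalReport:
        m = self.model
        Xtr = m.exog[m.train_idx]
        ytr = m.endog[m.train_idx]
        rows = []
        for k, (sub, (fit_idx, val_idx)) in enumerate(
            zip(self.ensemble.sub_models, self.ensemble.folds)
        ):
            pred = self.ensemble.scaler.inverse_target(sub.predict(Xtr[val_idx]))
            try:
                r2, rmse = evaluate(ytr[val_idx], pred)
            except ValueError:
                r2, rmse = np.nan, float(
                    np.sqrt(np.mean((pred - ytr[val_idx]) ** 2))
                )
            rows.append({"fold": k, "r2_validation": r2, "rmse_validation": rmse})
        per_fold = pd.DataFrame(rows)
        r2_test = rmse_test = None
        if len(m.test_idx) >= 2 and np.ptp(m.endog[m.test_idx]) > 0:
            r2_test, rmse_test = evaluate(
                m.endog[m.test_idx], self.predict(m.exog[m.test_idx])
            )
        return EvalReport(
            r2_validation=float(per_fold["r2_validation"].mean()),
            rmse_validation=float(per_fold["rmse_validation"].mean()),
            r2_test=r2_test,
            rmse_test=rmse_test,
            per_fold=per_fold,
        )

    def summary(self) -> str:
        rep = self.report
        cfg = self.ensemble.config
        lines = [
            "logK ensemble regression",
            "=" * 40,
            f"molecules (train/test):  {len(self.model.train_idx)}/{len(self.model.test_idx)}",
            f"architecture:            {cfg.n_layers} x {cfg.n_nodes} nodes",
            f"sub-models:              {len(self.ensemble.sub_models)}",
            f"R2  (validation mean):   {rep.r2_validation:.3f}",
            f"RMSE(validation mean):   {rep.rmse_validation:.3f} logK",
        ]
        if rep.r2_test is not None:
            lines += [
                f"R2  (test):              {rep.r2_test:.3f}",
                f"RMSE(test):              {rep.rmse_test:.3f} logK",
            ]
        return "\n".join(lines)


def architecture_sweep(
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    n_layers_grid: Sequence[int] = (1, 2, 3, 4, 5),
    n_nodes_grid: Sequence[int] = (256, 512, 1024, 2048, 4096),
    base_config: NetConfig | None = None,
) -> pd.DataFrame:
    """Mean validation R2 and train time over an architecture grid.

    Every configuration is trained on identical fold assignments, so
    rows are directly comparable; output is sorted by
    (n_layers, n_nodes).
    """
    base = base_config or NetConfig()
    if not len(n_layers_grid) or not len(n_nodes_grid):
        raise ParameterError("architecture grid must be non-empty")
    rows = []
    for n_layers in sorted(n_layers_grid):
        for n_nodes in sorted(n_nodes_grid):
            cfg = replace(base, n_layers=n_layers, n_nodes=n_nodes)
            t0 = time.perf_counter()
            ens = train_ensemble(X, y, folds, cfg)
            elapsed = time.perf_counter() - t0
            vals = []
            for sub, (fit_idx, val_idx) in zip(ens.sub_models, ens.folds):
                pred = ens.scaler.inverse_target(sub.predict(np.asarray(X, float)[val_idx]))
                vals.append(evaluate(np.asarray(y, float)[val_idx], pred)[0])
            rows.append(
                {
                    "n_layers": n_layers,
                    "n_nodes": n_nodes,
                    "mean_val_r2": float(np.mean(vals)),
                    "train_time_s": elapsed,
                }
            )
    return pd.DataFrame(rows).sort_values(["n_layers", "n_nodes"], ignore_index=True)
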