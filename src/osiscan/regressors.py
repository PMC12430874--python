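"""LNC estimators (ELM, BPNN, RF) and the R2 / RMSE / MRE evaluation metrics.

The extreme learning machine is written out explicitly: random input
weights and biases drawn uniformly from [-1, 1], a sigmoid hidden layer,
and output weights solved by least squares, with multiple random restarts
keeping the restart of lowest training RMSE.  The back-propagation network
(one tanh hidden layer trained by a quasi-Newton scheme) and the
100-tree random forest delegate to scikit-learn.  ELM and BPNN features
are z-scored on the modeling set and the same transform is reused on
validation data; the forest consumes raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .errors import ConfigurationError, DegenerateInputError, TrainingFailureError
from .dataset_prep import FeatureMatrix, SplitResult
from .spectra_io import TraitVector


# ---------------------------------------------------------------------------
# Configs


@dataclass(frozen=True)
class ELMConfig:
    kind: str = "ELM"
    n_hidden: int = 1000
    weight_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    n_restarts: int = 50

    def __post_init__(self):
        if self.n_hidden < 1 or self.n_restarts < 1:
            raise ConfigurationError("n_hidden and n_restarts must be >= 1")
        if self.weight_range[0] >= self.weight_range[1]:
            raise ConfigurationError("weight_range min must be < max")


@dataclass(frozen=True)
class BPNNConfig:
    kind: str = "BPNN"
    n_hidden: int = 15
    max_epochs: int = 2000
    tol: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ConfigurationError("n_hidden must be >= 1")


@dataclass(frozen=True)
class RFConfig:
    kind: str = "RF"
    n_trees: int = 100
    seed: int = 0
    oob: bool = True

    def __post_init__(self):
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")


def default_configs(seed: int = 0) -> dict:
    return {"ELM": ELMConfig(seed=seed), "BPNN": BPNNConfig(seed=seed), "RF": RFConfig(seed=seed)}


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class MetricSet:
    r2: float
    rmse: float  # mg g^-1
    mre: float  # percent

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mre": self.mre}


def metrics(y: np.ndarray, yhat: np.ndarray) -> MetricSet:
    """R2 = 1 - SS_res/SS_tot, RMSE = sqrt(mean squared error),
    MRE = mean(|y - yhat| / y) * 100."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ConfigurationError("metrics expect two equal-length 1-D vectors")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateInputError("R2 undefined for a zero-variance target")
    if np.any(y == 0):
        raise DegenerateInputError("MRE undefined when an observed value is 0")
    resid = y - yhat
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    rmse = float(np.sqrt((resid**2).mean()))
    mre = float(np.mean(np.abs(resid) / np.abs(y)) * 100.0)
    return MetricSet(r2=r2, rmse=rmse, mre=mre)


# ---------------------------------------------------------------------------
# Fit result


@dataclass
class FitResult:
    config: object
    predict: Callable[[np.ndarray], np.ndarray]
    training: MetricSet
    oob_error: float | None = None


def _check_X(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("feature matrix must be 2-D with n >= 2")
    if not np.all(np.isfinite(X)):
        raise ConfigurationError("feature matrix contains non-finite values")
    return X


def _training_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricSet:
    """Training-set metrics tolerant of degenerate targets (R2/MRE -> NaN)."""
    resid = y - yhat
    rmse = float(np.sqrt((resid**2).mean()))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else np.nan
    mre = float(np.mean(np.abs(resid) / np.abs(y)) * 100.0) if np.all(y != 0) else np.nan
    return MetricSet(r2=r2, rmse=rmse, mre=mre)


class _Standardizer:
    """Column z-score fitted on the modeling set, reused on validation data."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


# ---------------------------------------------------------------------------
# ELM


def fit_elm(X: np.ndarray, y: np.ndarray, config: ELMConfig | None = None) -> FitResult:
    """Extreme learning machine with random-restart selection.

    For each restart, hidden weights a ~ U[lo, hi] and biases b ~ U[lo, hi]
    are drawn under a restart-specific child seed, H = sigmoid(Xs a + b) is
    augmented with an intercept column, and output weights solve the least
    squares problem; the restart with lowest training RMSE wins.
    """
    config = config or ELMConfig()
    X = _check_X(X)
    y = np.asarray(y, dtype=float)
    scaler = _Standardizer(X)
    Xs = scaler(X)
    lo, hi = config.weight_range
    best = None
    for restart in range(config.n_restarts):
        rng = np.random.default_rng([config.seed, restart])
        a = rng.uniform(lo, hi, size=(X.shape[1], config.n_hidden))
        b = rng.uniform(lo, hi, size=config.n_hidden)
        H = np.column_stack([expit(Xs @ a + b), np.ones(X.shape[0])])
        beta, *_ = np.linalg.lstsq(H, y, rcond=None)
        rmse = float(np.sqrt(((H @ beta - y) ** 2).mean()))
        if best is None or rmse < best[0]:
            best = (rmse, a, b, beta)
    _, a, b, beta = best
    if not np.all(np.isfinite(beta)):
        raise TrainingFailureError("ELM output weights are non-finite")

    def predict(Xnew: np.ndarray) -> np.ndarray:
        Xn = scaler(_check_X(Xnew))
        H = np.column_stack([expit(Xn @ a + b), np.ones(Xn.shape[0])])
        return H @ beta

    return FitResult(config=config, predict=predict, training=_training_metrics(y, predict(X)))


# ---------------------------------------------------------------------------
# BPNN


def fit_bpnn(X: np.ndarray, y: np.ndarray, config: BPNNConfig | None = None) -> FitResult:
    """Single tanh hidden layer, linear output, quasi-Newton (L-BFGS) training."""
    config = config or BPNNConfig()
    X = _check_X(X)
    y = np.asarray(y, dtype=float)
    scaler = _Standardizer(X)
    net = MLPRegressor(
        hidden_layer_sizes=(config.n_hidden,),
        activation="tanh",
        solver="lbfgs",
        max_iter=config.max_epochs,
        tol=config.tol,
        alpha=1e-6,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net.fit(scaler(X), y)
    pred_train = net.predict(scaler(X))
    if not np.all(np.isfinite(pred_train)):
        raise TrainingFailureError(
            f"BPNN training diverged after {config.max_epochs} epochs"
        )

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return net.predict(scaler(_check_X(Xnew)))

    return FitResult(config=config, predict=predict, training=_training_metrics(y, pred_train))


# ---------------------------------------------------------------------------
# RF


def fit_rf(X: np.ndarray, y: np.ndarray, config: RFConfig | None = None) -> FitResult:
    """100-tree bootstrap ensemble of variance-reduction regression trees."""
    config = config or RFConfig()
    X = _check_X(X)
    y = np.asarray(y, dtype=float)
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        criterion="squared_error",
        oob_score=config.oob,
        random_state=config.seed,
        bootstrap=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(X, y)
    oob_error = None
    if config.oob:
        oob_pred = forest.oob_prediction_
        ok = np.isfinite(oob_pred)
        oob_error = float(np.sqrt(((oob_pred[ok] - y[ok]) ** 2).mean()))

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return forest.predict(_check_X(Xnew))

    result = FitResult(
        config=config, predict=predict, training=_training_metrics(y, forest.predict(X)), oob_error=oob_error
    )
    result.feature_importances_ = forest.feature_importances_
    return result


FITTERS = {"ELM": fit_elm, "BPNN": fit_bpnn, "RF": fit_rf}


def evaluate(fit: FitResult, X: np.ndarray, y: np.ndarray) -> MetricSet:
    """Score a fitted model on a subset."""
    return metrics(np.asarray(y, dtype=float), fit.predict(X))


# ---------------------------------------------------------------------------
# The 7 x 3 grid


def run_grid(
    feature_matrices: dict[int, FeatureMatrix],
    trait: TraitVector,
    split: SplitResult,
    model_configs: dict | None = None,
) -> pd.DataFrame:
    """Fit every (combine, model) cell on the modeling set and score both subsets.

    Returns a tidy frame with columns combine, model, subset, r2, rmse,
    mre (plus oob_error for RF rows), two rows per cell.
    """
    model_configs = model_configs or default_configs()
    rows = []
    y_mod = trait.select_samples(split.modeling_ids).lnc
    y_val = trait.select_samples(split.validation_ids).lnc
    for cid in sorted(feature_matrices):
        fm = feature_matrices[cid]
        X_mod = fm.select_samples(split.modeling_ids).values
        X_val = fm.select_samples(split.validation_ids).values
        for model_name, cfg in model_configs.items():
            fit = FITTERS[model_name](X_mod, y_mod, cfg)
            for subset, X, yv in (("modeling", X_mod, y_mod), ("validation", X_val, y_val)):
                m = evaluate(fit, X, yv)
                rows.append(
                    {
                        "combine": cid,
                        "model": model_name,
                        "subset": subset,
                        "r2": m.r2,
                        "rmse": m.rmse,
                        "mre": m.mre,
                        "oob_error": fit.oob_error,
                    }
                )
    return pd.DataFrame(rows)
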