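"""Stratified splitting, feed-forward NN regression, and evaluation.

The regressor is a fully connected 30 -> 64 -> 32 -> 16 -> 1 network with
leaky-ReLU activations trained by Adam on an imbalance-weighted MSE loss
with elastic-net (L1 + L2) weight penalties.  The learning rate starts at
0.01 and is halved, down to a floor of 1e-4, whenever the validation loss
has not improved for 10 epochs; early stopping restores the best-validation
weights.  Implemented directly on numpy so the loss, weighting and schedule
match the stated training protocol exactly.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import SCHEMA_ID, ScalerParams

__all__ = [
    "SplitSpec",
    "ModelConfig",
    "TrainedModel",
    "EvalReport",
    "split_stratified",
    "kfold_stratified",
    "train",
    "predict",
    "evaluate",
    "delta_delta_e",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Splitting

@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Stratified split parameters.

    Strata are (halogen, halogen-plane-distance bin); the grid's discrete
    distances stratify as-is, continuous distances are binned at
    ``distance_bin_width``.
    """

    test_fraction: float = 0.2
    val_fraction: float = 0.2  # of the training part
    n_folds: int = 5
    distance_bin_width: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1 and 0 < self.val_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")


def _strata(df: pd.DataFrame, spec: SplitSpec) -> np.ndarray:
    if "halogen" not in df:
        raise ValueError("strata column 'halogen' missing")
    dcol = "d" if "d" in df else "y" if "y" in df else "d_X_plane"
    if dcol not in df:
        raise ValueError("no halogen-plane distance column found for stratification")
    bins = np.round(df[dcol].to_numpy() / spec.distance_bin_width).astype(int)
    return np.array([f"{h}|{b}" for h, b in zip(df["halogen"], bins)])


def split_stratified(df: pd.DataFrame, spec: SplitSpec) -> np.ndarray:
    """Assign each row to 'train', 'val' or 'test'.

    Within every stratum the test share is ``test_fraction`` (within one
    element) and the validation share is ``val_fraction`` of the remaining
    training rows, mirroring an 80/20 outer and 80/20 inner split.
    Deterministic under ``spec.seed``.
    """
    labels = np.empty(len(df), dtype=object)
    rng = np.random.default_rng(spec.seed)
    strata = _strata(df, spec)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = idx[rng.permutation(len(idx))]
        n_test = int(round(spec.test_fraction * len(idx)))
        n_val = int(round(spec.val_fraction * (len(idx) - n_test)))
        labels[idx[:n_test]] = "test"
        labels[idx[n_test : n_test + n_val]] = "val"
        labels[idx[n_test + n_val :]] = "train"
    return labels


def kfold_stratified(df: pd.DataFrame, spec: SplitSpec) -> np.ndarray:
    """Fold index (0..n_folds-1) per row; folds tile each stratum evenly."""
    folds = np.empty(len(df), dtype=int)
    rng = np.random.default_rng(spec.seed)
    strata = _strata(df, spec)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = idx[rng.permutation(len(idx))]
        folds[idx] = np.arange(len(idx)) % spec.n_folds
    return folds


# ---------------------------------------------------------------------------
# Network

@dataclasses.dataclass(frozen=True)
class ModelConfig:
    hidden_sizes: tuple[int, ...] = (64, 32, 16)
    leaky_slope: float = 0.01
    learning_rate: float = 0.01
    lr_floor: float = 1e-4
    lr_patience: int = 10
    batch_size: int = 128
    max_epochs: int = 500
    early_stop_patience: int = 30
    min_delta: float = 1e-4
    l1: float = 1e-6
    l2: float = 1e-6
    imbalance_weighting: bool = True
    imbalance_bin_width: float = 1.0  # kJ/mol energy bins for weighting
    max_weight: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.lr_floor > self.learning_rate:
            raise ValueError("lr_floor must not exceed the initial learning rate")


@dataclasses.dataclass
class TrainedModel:
    weights: list[np.ndarray]  # W1, b1, W2, b2, ...
    scaler: ScalerParams | None
    config: ModelConfig
    history: pd.DataFrame  # per-epoch train/val RMSE and learning rate
    schema_id: str = SCHEMA_ID

    @property
    def input_width(self) -> int:
        return self.weights[0].shape[0]


def _init_weights(sizes: Sequence[int], rng: np.random.Generator) -> list[np.ndarray]:
    params: list[np.ndarray] = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)  # He init for (leaky) ReLU
        params.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        params.append(np.zeros(fan_out))
    return params


def _forward(params: Sequence[np.ndarray], X: np.ndarray, slope: float):
    acts = [X]
    h = X
    n_layers = len(params) // 2
    for i in range(n_layers):
        W, b = params[2 * i], params[2 * i + 1]
        z = h @ W + b
        if i < n_layers - 1:
            h = np.where(z > 0, z, slope * z)
        else:
            h = z
        acts.append(h)
    return h[:, 0], acts


def _backward(
    params: Sequence[np.ndarray],
    acts: Sequence[np.ndarray],
    dloss_dy: np.ndarray,
    slope: float,
) -> list[np.ndarray]:
    grads = [np.zeros_like(p) for p in params]
    n_layers = len(params) // 2
    delta = dloss_dy[:, None]  # output layer is linear
    for i in reversed(range(n_layers)):
        W = params[2 * i]
        grads[2 * i] = acts[i].T @ delta
        grads[2 * i + 1] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ W.T
            delta = np.where(acts[i] > 0, delta, slope * delta)
    return grads


def _imbalance_weights(y: np.ndarray, bin_width: float, cap: float) -> np.ndarray:
    """Inverse-frequency weights over fixed-width energy bins, mean 1."""
    bins = np.floor(y / bin_width).astype(int)
    _, inv, counts = np.unique(bins, return_inverse=True, return_counts=True)
    w = 1.0 / counts[inv]
    w = w / w.mean()
    w = np.minimum(w, cap)
    return w / w.mean()


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig = ModelConfig(),
    scaler: ScalerParams | None = None,
) -> TrainedModel:
    """Fit the regressor on scaled features and energies (kJ/mol).

    Per-sample weights address the imbalance of the energy distribution;
    the elastic-net penalty acts on all weight matrices.  Validation loss
    (unweighted MSE) drives both the halving schedule and early stopping.
    """
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, float).reshape(-1)
    X_val = np.asarray(X_val, float)
    y_val = np.asarray(y_val, float).reshape(-1)
    rng = np.random.default_rng(config.seed)
    sizes = [X_train.shape[1], *config.hidden_sizes, 1]
    params = _init_weights(sizes, rng)

    if config.imbalance_weighting:
        sample_w = _imbalance_weights(y_train, config.imbalance_bin_width, config.max_weight)
    else:
        sample_w = np.ones_like(y_train)

    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    lr = config.learning_rate

    best_val = np.inf
    best_params = [p.copy() for p in params]
    epochs_since_best = 0
    epochs_since_lr_best = 0
    lr_best = np.inf
    history: list[dict] = []

    n = len(y_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            Xb, yb, wb = X_train[sel], y_train[sel], sample_w[sel]
            pred, acts = _forward(params, Xb, config.leaky_slope)
            resid = pred - yb
            dloss = 2.0 * wb * resid / len(sel)
            grads = _backward(params, acts, dloss, config.leaky_slope)
            step += 1
            for i, p in enumerate(params):
                g = grads[i]
                if p.ndim == 2:  # elastic-net penalty on weight matrices only
                    g = g + config.l1 * np.sign(p) + 2.0 * config.l2 * p
                m_adam[i] = beta1 * m_adam[i] + (1 - beta1) * g
                v_adam[i] = beta2 * v_adam[i] + (1 - beta2) * g * g
                mhat = m_adam[i] / (1 - beta1**step)
                vhat = v_adam[i] / (1 - beta2**step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
            if not np.isfinite(pred).all():
                raise FloatingPointError(
                    f"non-finite prediction at epoch {epoch}, step {step}; "
                    "check feature scaling and learning rate"
                )

        train_pred, _ = _forward(params, X_train, config.leaky_slope)
        val_pred, _ = _forward(params, X_val, config.leaky_slope)
        train_rmse = float(np.sqrt(np.mean((train_pred - y_train) ** 2)))
        val_rmse = float(np.sqrt(np.mean((val_pred - y_val) ** 2)))
        val_loss = val_rmse**2
        history.append(
            {"epoch": epoch, "train_rmse": train_rmse, "val_rmse": val_rmse, "lr": lr}
        )

        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            epochs_since_best = 0
        else:
            epochs_since_best += 1

        if val_loss < lr_best - config.min_delta:
            lr_best = val_loss
            epochs_since_lr_best = 0
        else:
            epochs_since_lr_best += 1
            if epochs_since_lr_best >= config.lr_patience and lr > config.lr_floor:
                lr = max(lr / 2.0, config.lr_floor)
                epochs_since_lr_best = 0

        if epochs_since_best >= config.early_stop_patience:
            break

    return TrainedModel(
        weights=best_params,
        scaler=scaler,
        config=config,
        history=pd.DataFrame(history),
    )


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Predicted adduct formation energies (kJ/mol) for scaled features."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.input_width:
        raise ValueError(f"expected feature width {model.input_width}, got {X.shape[1]}")
    out, _ = _forward(model.weights, X, model.config.leaky_slope)
    return out


# ---------------------------------------------------------------------------
# Evaluation

@dataclasses.dataclass
class EvalReport:
    r2: float
    rmse: float
    mae: float
    dde: np.ndarray  # calculated minus predicted, per record
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    r2_defined: bool = True


def delta_delta_e(calc, pred):
    """Energy difference, calculated minus predicted (kJ/mol)."""
    return np.asarray(calc, float) - np.asarray(pred, float)


def evaluate(
    calc: np.ndarray,
    pred: np.ndarray,
    hist_range: tuple[float, float] = (-4.0, 4.0),
    hist_bin: float = 0.5,
) -> EvalReport:
    """Standard regression metrics plus the clipped energy-difference histogram.

    Differences beyond the histogram range are clipped into the edge bins so
    the counts always sum to the number of records.
    """
    calc = np.asarray(calc, float).reshape(-1)
    pred = np.asarray(pred, float).reshape(-1)
    if len(calc) != len(pred) or len(calc) < 2:
        raise ValueError("calc and pred must have equal length >= 2")
    dde = delta_delta_e(calc, pred)
    rmse = float(np.sqrt(np.mean(dde**2)))
    mae = float(np.mean(np.abs(dde)))
    ss_tot = float(np.sum((calc - calc.mean()) ** 2))
    if ss_tot == 0:
        r2, r2_defined = float("nan"), False
    else:
        r2, r2_defined = 1.0 - float(np.sum(dde**2)) / ss_tot, True
    lo, hi = hist_range
    edges = np.arange(lo, hi + hist_bin / 2, hist_bin)
    clipped = np.clip(dde, lo, hi)
    counts, _ = np.histogram(clipped, bins=edges)
    # values exactly at the upper edge belong to the last bin via clipping
    return EvalReport(
        r2=r2, rmse=rmse, mae=mae, dde=dde, hist_counts=counts, hist_edges=edges,
        r2_defined=r2_defined,
    )


# ---------------------------------------------------------------------------
# Checkpoint I/O (single JSON file: weights, scaler, config, history)

def save_checkpoint(model: TrainedModel, path, applicability: Mapping | None = None) -> None:
    payload = {
        "format": "halopi-checkpoint-1",
        "schema_id": model.schema_id,
        "config": dataclasses.asdict(model.config),
        "weights": [w.tolist() for w in model.weights],
        "scaler": None
        if model.scaler is None
        else {
            "mins": model.scaler.mins.tolist(),
            "maxs": model.scaler.maxs.tolist(),
            "schema_id": model.scaler.schema_id,
        },
        "history": model.history.to_dict(orient="list"),
        "applicability": dict(applicability) if applicability else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> tuple[TrainedModel, dict | None]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "halopi-checkpoint-1":
        raise ValueError(
            f"unsupported checkpoint format {payload.get('format')!r}; "
            "expected 'halopi-checkpoint-1'"
        )
    cfg = dict(payload["config"])
    cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
    config = ModelConfig(**cfg)
    scaler = None
    if payload["scaler"] is not None:
        scaler = ScalerParams(
            mins=np.array(payload["scaler"]["mins"]),
            maxs=np.array(payload["scaler"]["maxs"]),
            schema_id=payload["scaler"]["schema_id"],
        )
    model = TrainedModel(
        weights=[np.array(w) for w in payload["weights"]],
        scaler=scaler,
        config=config,
        history=pd.DataFrame(payload["history"]),
        schema_id=payload["schema_id"],
    )
    return model, payload.get("applicability")
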