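"""LSTM sequence regressor: engagement-velocity curve -> contact-force curve.

The published architecture is two stacked LSTM layers (128 and 64 cells)
followed by a per-time-step dense unit with ReLU, trained with Adam
(learning rate 0.002) on mean squared error, with early stopping on
validation loss. Both channels are max-abs normalised with constants
computed on the training dataset and persisted with the model; prediction
applies the same constants and returns newtons.

The hyperparameter space the study searched — layers {1,2,3}, cells
{32,64,128}, learning rate {0.001,0.002,0.01} — is reproduced by
:func:`grid_search` with k-fold cross-validation. A grid candidate uses one
cell width for all of its layers (the stated space cannot produce mixed
widths); the mixed-width [128, 64] network is kept as the package default
because it is the published final model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .io_preprocess import N_POINTS, ShapeError, VelocityForcePair

__all__ = [
    "RnnConfig",
    "NormalizationConstants",
    "TrainedPredictor",
    "GridSearchSpace",
    "normalize",
    "denormalize",
    "split_dataset",
    "train_predictor",
    "grid_search",
    "predict_force",
    "PredictorError",
    "DivergenceError",
]


class PredictorError(ValueError):
    pass


class DivergenceError(PredictorError):
    pass


@dataclass
class RnnConfig:
    layer_cells: tuple = (128, 64)
    learning_rate: float = 0.002
    epochs: int = 1000
    batch_size: int = 32
    patience: int = 50
    seed: int = 0

    def __post_init__(self):
        self.layer_cells = tuple(int(c) for c in self.layer_cells)
        if not 1 <= len(self.layer_cells) <= 3:
            raise PredictorError("1 to 3 LSTM layers supported")
        if self.learning_rate <= 0:
            raise PredictorError("learning_rate must be positive")


@dataclass
class NormalizationConstants:
    """Max-abs scaling constants of the training dataset (m/s, newtons)."""

    v_maxabs: float
    f_maxabs: float

    def __post_init__(self):
        if self.v_maxabs <= 0 or self.f_maxabs <= 0:
            raise PredictorError("degenerate scale: an all-zero channel cannot be normalised")


@dataclass
class TrainedPredictor:
    model: _nn.Sequential
    config: RnnConfig
    norms: NormalizationConstants
    history: pd.DataFrame = field(default_factory=pd.DataFrame)  # train/val loss per epoch
    stopped_epoch: int = -1


@dataclass
class GridSearchSpace:
    layers_options: tuple = (1, 2, 3)
    cells_options: tuple = (32, 64, 128)
    lr_options: tuple = (0.001, 0.002, 0.01)
    cv_folds: int = 5


# ---------------------------------------------------------------------------
# normalisation and splitting
# ---------------------------------------------------------------------------


def _stack(pairs: Sequence[VelocityForcePair]) -> tuple[np.ndarray, np.ndarray]:
    return np.array([p.velocity for p in pairs]), np.array([p.force for p in pairs])


def normalize(
    pairs: Sequence[VelocityForcePair], norms: NormalizationConstants | None = None
) -> tuple[np.ndarray, np.ndarray, NormalizationConstants]:
    """Scale both channels into [-1, 1] by the dataset's max absolute values.

    Returns ``(V_scaled, F_scaled, constants)`` with arrays of shape
    (n, 101). When ``norms`` is given the stored constants are reused (the
    prediction-time contract); otherwise they are computed from ``pairs``
    and at least one scaled sample per channel has absolute value 1.
    """
    if len(pairs) == 0:
        raise PredictorError("cannot normalize an empty dataset")
    V, F = _stack(pairs)
    if norms is None:
        norms = NormalizationConstants(v_maxabs=float(np.abs(V).max()), f_maxabs=float(np.abs(F).max()))
    return V / norms.v_maxabs, F / norms.f_maxabs, norms


def denormalize(F_scaled: np.ndarray, norms: NormalizationConstants) -> np.ndarray:
    return F_scaled * norms.f_maxabs


def split_dataset(
    pairs: Sequence[VelocityForcePair], fraction_train: float = 0.8, seed: int = 0
) -> tuple[list[VelocityForcePair], list[VelocityForcePair]]:
    """Seeded shuffled split into disjoint, exhaustive train/validation lists."""
    n = len(pairs)
    if n < 5:
        raise PredictorError(f"need >= 5 pairs to split, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    n_train = round(fraction_train * n)
    return [pairs[i] for i in order[:n_train]], [pairs[i] for i in order[n_train:]]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _build_rnn(cfg: RnnConfig, rng: np.random.Generator) -> _nn.Sequential:
    layers: list = []
    n_in = 1
    for cells in cfg.layer_cells:
        layers.append(_nn.LSTM(n_in, cells, rng))
        n_in = cells
    head = _nn.Dense(n_in, 1, rng)
    # start the width-1 ReLU head in its active region; an all-negative
    # initial pre-activation would zero every gradient (dead ReLU)
    head.b[...] = 0.1
    layers.append(head)
    layers.append(_nn.Activation("relu"))
    return _nn.Sequential(layers)


def train_predictor(
    train: Sequence[VelocityForcePair],
    val: Sequence[VelocityForcePair],
    cfg: RnnConfig | None = None,
) -> TrainedPredictor:
    """Fit the LSTM on scaled force curves with early stopping.

    Normalisation constants are computed from ``train`` and applied to
    ``val``; training minimises MSE on the scaled force and halts once the
    validation loss has not improved for ``cfg.patience`` epochs, restoring
    the best epoch's weights.
    """
    cfg = cfg or RnnConfig()
    if len(train) == 0 or len(val) == 0:
        raise PredictorError("train and validation sets must be non-empty")
    Xtr, Ytr, norms = normalize(train)
    Xva, Yva, _ = normalize(val, norms)
    rng = np.random.default_rng(cfg.seed)
    model = _build_rnn(cfg, rng)

    Xtr3 = Xtr[:, :, None].astype(_nn.DTYPE)
    Ytr3 = Ytr[:, :, None].astype(_nn.DTYPE)
    Xva3 = Xva[:, :, None].astype(_nn.DTYPE)
    Yva3 = Yva[:, :, None].astype(_nn.DTYPE)
    opt = _nn.Adam(model.params(), cfg.learning_rate)
    n = len(train)
    bs = min(cfg.batch_size, n)

    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = -1
    wait = 0
    rows = []
    stopped = cfg.epochs - 1
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, bs):
            idx = order[i : i + bs]
            pred = model.forward(Xtr3[idx], training=True)
            loss, grad = _nn.mse_loss(pred, Ytr3[idx])
            model.backward(grad)
            opt.step(model.grads())
            losses.append(loss)
        train_loss = float(np.mean(losses))
        val_pred = model.forward(Xva3, training=False)
        val_loss = float(np.mean((val_pred - Yva3) ** 2))
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait > cfg.patience:
                stopped = epoch
                break
    else:
        stopped = cfg.epochs - 1
    model.set_weights(best_weights)
    return TrainedPredictor(
        model=model,
        config=cfg,
        norms=norms,
        history=pd.DataFrame(rows),
        stopped_epoch=stopped,
    )


def predict_force(predictor: TrainedPredictor, velocity: np.ndarray) -> np.ndarray:
    """Predict the 101-point contact-force curve (newtons) from a velocity curve.

    Accepts one curve (101,) or a batch (n, 101); scaling with the stored
    constants happens internally, so inputs are always physical units.
    Outputs are non-negative by the ReLU head.
    """
    velocity = np.asarray(velocity, dtype=float)
    single = velocity.ndim == 1
    V = velocity[None, :] if single else velocity
    if V.shape[1] != N_POINTS:
        raise ShapeError(f"velocity must have {N_POINTS} samples, got {V.shape[1]}")
    if not np.isfinite(V).all():
        raise PredictorError("velocity contains non-finite samples")
    X = (V / predictor.norms.v_maxabs)[:, :, None].astype(_nn.DTYPE)
    out = predictor.model.forward(X, training=False)[:, :, 0]
    F = denormalize(out.astype(float), predictor.norms)
    return F[0] if single else F


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def grid_search(
    pairs: Sequence[VelocityForcePair],
    space: GridSearchSpace | None = None,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 32,
    patience: int = 10,
) -> tuple[RnnConfig, pd.DataFrame]:
    """Exhaustive architecture/learning-rate search with k-fold cross-validation.

    Every (layers, cells, lr) combination is scored by its mean validation
    MSE over ``space.cv_folds`` folds (same folds and init seed for every
    combination, so identical combinations score identically). Returns the
    argmin combination as an :class:`RnnConfig` plus the full score table.
    ``epochs``/``patience`` bound the per-fold training budget.
    """
    space = space or GridSearchSpace()
    n = len(pairs)
    if space.cv_folds < 2 or space.cv_folds > n:
        raise PredictorError(f"cv_folds={space.cv_folds} invalid for a dataset of {n} pairs")
    folds = np.array_split(np.random.default_rng(seed).permutation(n), space.cv_folds)
    rows = []
    for layers, cells, lr in product(space.layers_options, space.cells_options, space.lr_options):
        cfg = RnnConfig(
            layer_cells=(cells,) * layers,
            learning_rate=lr,
            epochs=epochs,
            batch_size=batch_size,
            patience=patience,
            seed=seed,
        )
        fold_scores = []
        for k in range(space.cv_folds):
            val_idx = set(folds[k].tolist())
            tr = [pairs[i] for i in range(n) if i not in val_idx]
            va = [pairs[i] for i in sorted(val_idx)]
            fitted = train_predictor(tr, va, cfg)
            fold_scores.append(float(fitted.history["val_loss"].min()))
        rows.append(
            {
                "layers": layers,
                "cells": cells,
                "learning_rate": lr,
                "mean_val_loss": float(np.mean(fold_scores)),
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_val_loss"].idxmin()]
    best_cfg = RnnConfig(
        layer_cells=(int(best["cells"]),) * int(best["layers"]),
        learning_rate=float(best["learning_rate"]),
        epochs=epochs,
        batch_size=batch_size,
        patience=patience,
        seed=seed,
    )
    return best_cfg, table
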