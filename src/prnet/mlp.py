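"""Train the initial fully connected classifier — the black box to decompose.

The base model is a single-hidden-layer tanh network whose output logit is
``logit(P(class | x))``.  Width is chosen on a small grid by held-out
log-loss; weight decay keeps the fitted surface smooth so that its cuts
(the partial responses) are stable.  The trained network is exposed through
``predict_logit`` and serializes to structured text for bit-exact reload.
"""

from __future__ import annotations

import json

import numpy as np

from ._nn import ModularNet, TrainingRecord, init_mlp, log_loss, sigmoid, train
from .data import StandardizedTable

DEFAULT_WIDTH_GRID = (4, 8, 16)


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, StandardizedTable):
        if table.missing_mask.any():
            raise ValueError("table still contains missing values; impute first")
        return table.values
    return np.asarray(table, float)


def train_mlp(table, outcome: np.ndarray, hidden_units=None,
              l2_penalty: float = 1e-3, seed: int = 0,
              validation_fraction: float = 0.2, learning_rate: float = 0.01,
              max_epochs: int = 300, patience: int = 20,
              batch_size: int = 512) -> ModularNet:
    """Fit the base MLP; deterministic per seed.

    ``hidden_units`` may be an int (fixed width) or an iterable of widths to
    compare by validation log-loss (default grid ``(4, 8, 16)``; ties go to
    the narrower network).
    """
    X = _as_matrix(table)
    y = np.asarray(outcome).ravel()
    classes = set(np.unique(y))
    if classes - {0, 1} or len(classes) < 2:
        raise ValueError("outcome must contain both classes coded 0/1")

    if hidden_units is None:
        widths = DEFAULT_WIDTH_GRID
    elif np.isscalar(hidden_units):
        widths = (int(hidden_units),)
    else:
        widths = tuple(int(h) for h in hidden_units)

    base_rate = float(np.mean(y))
    b0 = float(np.log(base_rate / (1 - base_rate)))
    best = None
    for width in widths:
        net0 = init_mlp(X.shape[1], width, seed=seed, intercept=b0)
        net, record = train(
            net0, X, y, seed=seed, learning_rate=learning_rate,
            max_epochs=max_epochs, patience=patience,
            validation_fraction=validation_fraction, l2=l2_penalty,
            batch_size=batch_size,
        )
        val = min(record.val_loss)
        if best is None or val < best[0] - 1e-9:
            best = (val, width, net, record)

    _, width, net, record = best
    net.metadata = {
        "architecture": f"1 hidden layer, {width} tanh units",
        "hidden_units": width,
        "width_grid": list(widths),
        "l2_penalty": l2_penalty,
        "seed": seed,
        "epochs_run": record.epochs_run,
        "best_epoch": record.best_epoch,
        "final_val_logloss": float(min(record.val_loss)),
    }
    return net


def predict_logit(model: ModularNet, table) -> np.ndarray:
    """Logit of the fitted class probability for each row."""
    return model.predict_logit(_as_matrix(table))


def predict_proba(model: ModularNet, table) -> np.ndarray:
    return sigmoid(predict_logit(model, table))


def save_model(model: ModularNet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path) -> ModularNet:
    with open(path, "r", encoding="utf-8") as fh:
        return ModularNet.from_dict(json.load(fh))
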