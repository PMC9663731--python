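"""Minimal modular one-hidden-layer network and its trainer.

The network's logit is an intercept plus a sum of module outputs; each
module is a tanh hidden layer that sees only its own subset of input
columns.  A plain MLP is the single-module special case (one module over
all columns); the self-explaining network uses one module per retained
partial response.  Modularity is structural: a module's weight matrix has
no rows for non-member inputs, so its gradient with respect to them is
identically zero.

Training is minibatch Adam on the binomial log-loss with an L2 penalty on
weights, early stopping on held-out log-loss with best-weights restore,
fully deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def log_loss(y: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class Module:
    """One subnetwork: tanh(x_S @ W + b) @ v, offset by a constant so the
    displayed output is zero at the anchor."""

    var_idx: np.ndarray  # column indices this module may see
    W: np.ndarray        # (len(var_idx), H)
    b: np.ndarray        # (H,)
    v: np.ndarray        # (H,)
    offset: float = 0.0  # raw output at the anchor; subtracted on display

    def __post_init__(self) -> None:
        self.var_idx = np.asarray(self.var_idx, dtype=int)
        self.W = np.asarray(self.W, float)
        self.b = np.asarray(self.b, float)
        self.v = np.asarray(self.v, float)
        if self.W.shape != (self.var_idx.size, self.b.size):
            raise ValueError("module weight shapes are inconsistent")
        if self.v.shape != self.b.shape:
            raise ValueError("module output weights mismatch hidden size")

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X[:, self.var_idx] @ self.W + self.b)

    def raw(self, X: np.ndarray) -> np.ndarray:
        return self.hidden(X) @ self.v

    def output(self, X: np.ndarray) -> np.ndarray:
        """Anchored output: exactly zero when the member inputs sit at the
        anchor used to set ``offset``."""
        return self.raw(X) - self.offset

    def copy(self) -> "Module":
        return Module(self.var_idx.copy(), self.W.copy(), self.b.copy(),
                      self.v.copy(), self.offset)


@dataclass
class ModularNet:
    modules: list[Module]
    intercept: float
    n_features: int
    metadata: dict = field(default_factory=dict)

    def predict_logit(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} columns, got {X.shape[1]}"
            )
        out = np.full(X.shape[0], self.intercept)
        for m in self.modules:
            out += m.output(X)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(self.predict_logit(X))

    def copy(self) -> "ModularNet":
        return ModularNet([m.copy() for m in self.modules], self.intercept,
                          self.n_features, dict(self.metadata))

    def recenter(self, anchor: np.ndarray) -> None:
        """Re-enforce module-zero at the anchor, absorbing the shifts into
        the intercept (total logit unchanged)."""
        a = np.atleast_2d(np.asarray(anchor, float))
        for m in self.modules:
            old = m.offset
            m.offset = float(m.raw(a)[0])
            self.intercept += old - m.offset  # net logit = raw - offset + intercept

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "n_features": self.n_features,
            "metadata": self.metadata,
            "modules": [
                {
                    "var_idx": m.var_idx.tolist(),
                    "W": m.W.tolist(),
                    "b": m.b.tolist(),
                    "v": m.v.tolist(),
                    "offset": m.offset,
                }
                for m in self.modules
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModularNet":
        modules = [
            Module(np.asarray(m["var_idx"], int), np.asarray(m["W"]),
                   np.asarray(m["b"]), np.asarray(m["v"]), m["offset"])
            for m in doc["modules"]
        ]
        return cls(modules, doc["intercept"], doc["n_features"],
                   dict(doc.get("metadata", {})))


@dataclass
class TrainingRecord:
    epochs_run: int
    best_epoch: int
    train_loss: list[float]
    val_loss: list[float]


def init_mlp(n_features: int, hidden_units: int, seed: int,
             intercept: float = 0.0) -> ModularNet:
    """Fresh single-module network over all inputs (the plain MLP)."""
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 1.0 / np.sqrt(max(n_features, 1)), (n_features, hidden_units))
    b = rng.normal(0.0, 0.1, hidden_units)
    v = rng.normal(0.0, 1.0 / np.sqrt(hidden_units), hidden_units)
    module = Module(np.arange(n_features), W, b, v, offset=0.0)
    return ModularNet([module], float(intercept), n_features)


def train(net: ModularNet, X: np.ndarray, y: np.ndarray, seed: int,
          learning_rate: float = 0.01, max_epochs: int = 500, patience: int = 20,
          validation_fraction: float = 0.2, l2: float = 1e-3,
          batch_size: int = 512, min_delta: float = 1e-7) -> tuple[ModularNet, TrainingRecord]:
    """Train (a copy of) the net; returns the best-validation-loss weights.

    The validation split, minibatch shuffling and Adam state are all driven
    by ``seed``, so identical calls produce bit-identical networks.
    ``max_epochs=0`` returns the initialization unchanged.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    rng = np.random.default_rng(seed)
    net = net.copy()
    if max_epochs == 0:
        return net, TrainingRecord(0, 0, [], [])

    perm = rng.permutation(n)
    n_val = max(1, int(round(validation_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training rows")
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    ntr = Xtr.shape[0]
    bs = min(batch_size, ntr)

    # flat parameter vector view: per-module (W, b, v) then intercept
    params = []
    for m in net.modules:
        params.extend([m.W, m.b, m.v])
    adam_m = [np.zeros_like(p) for p in params] + [0.0]
    adam_v = [np.zeros_like(p) for p in params] + [0.0]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    best_loss = np.inf
    best_state = None
    best_epoch = 0
    wait = 0
    tr_hist: list[float] = []
    val_hist: list[float] = []

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(ntr)
        for start in range(0, ntr, bs):
            idx = order[start:start + bs]
            Xb, yb = Xtr[idx], ytr[idx]
            nb = Xb.shape[0]
            # forward
            hiddens = []
            logit = np.full(nb, net.intercept)
            for m in net.modules:
                h = m.hidden(Xb)
                hiddens.append(h)
                logit += h @ m.v - m.offset
            p = sigmoid(logit)
            g = (p - yb) / nb
            # backward + Adam
            t += 1
            corr1 = 1 - beta1**t
            corr2 = 1 - beta2**t
            k = 0
            for m, h in zip(net.modules, hiddens):
                gv = h.T @ g + l2 * m.v
                gh = np.outer(g, m.v) * (1 - h * h)
                gW = Xb[:, m.var_idx].T @ gh + l2 * m.W
                gb = gh.sum(axis=0)
                for arr, grad in ((m.W, gW), (m.b, gb), (m.v, gv)):
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grad
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grad * grad
                    arr -= learning_rate * (adam_m[k] / corr1) / (
                        np.sqrt(adam_v[k] / corr2) + eps)
                    k += 1
            g0 = g.sum()
            adam_m[-1] = beta1 * adam_m[-1] + (1 - beta1) * g0
            adam_v[-1] = beta2 * adam_v[-1] + (1 - beta2) * g0 * g0
            net.intercept -= learning_rate * (adam_m[-1] / corr1) / (
                np.sqrt(adam_v[-1] / corr2) + eps)

        tr_loss = log_loss(ytr, net.predict_proba(Xtr))
        val_loss = log_loss(yval, net.predict_proba(Xval))
        if not np.isfinite(tr_loss) or not np.isfinite(val_loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); try a smaller learning rate"
            )
        tr_hist.append(tr_loss)
        val_hist.append(val_loss)
        if val_loss < best_loss - min_delta:
            best_loss = val_loss
            best_state = net.copy()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait > patience:
                break

    final = best_state if best_state is not None else net
    return final, TrainingRecord(len(tr_hist), best_epoch, tr_hist, val_hist)
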