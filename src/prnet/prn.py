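"""The partial response network: a self-explaining modular rebuild.

The responses retained by the Lasso are turned into a generalized additive
neural network: one subnetwork per response, each a replica of the base
MLP's hidden layer restricted to that response's variable(s) (all other
inputs clamped at the anchor), output-scaled by the Lasso coefficient and
offset so the module is exactly zero at the anchor.  At initialization the
network's logit therefore equals the Lasso-GAM's logit to machine
precision; retraining by backpropagation then sharpens the responses free
of the noise contributed by the variables that were dropped.  Decomposing
and re-selecting on the retrained network yields the final model
("PRN-Lasso"), whose per-patient prediction is an exactly additive sum of
readable contributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import ModularNet, Module, TrainingRecord, sigmoid, train
from .anova import (
    AnovaDecomposition,
    PartialResponse,
    cut_component_values,
    decompose,
)
from .data import BINARY, AnchorVector, StandardizedTable
from .gam import (
    GamLassoModel,
    ResponseFeatureMatrix,
    build_feature_matrix,
    fit_lasso_path,
    select_model,
)


@dataclass
class PRNModel:
    """Modular network whose logit is intercept + sum of module outputs."""

    net: ModularNet
    module_sets: list[tuple[int, ...]]
    module_labels: list[str]
    anchor_point: np.ndarray
    column_names: tuple[str, ...] = ()
    column_kinds: tuple[str, ...] = ()
    training: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.anchor_point = np.asarray(self.anchor_point, float)

    @property
    def n_features(self) -> int:
        return self.net.n_features

    @property
    def intercept(self) -> float:
        return float(self.net.intercept)

    def predict_logit(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_logit(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(self.predict_logit(X))

    def module_contributions(self, X: np.ndarray) -> np.ndarray:
        """(n_rows, n_modules) matrix of anchored module outputs."""
        X = np.atleast_2d(np.asarray(X, float))
        return np.column_stack([m.output(X) for m in self.net.modules]) \
            if self.net.modules else np.zeros((X.shape[0], 0))

    def to_json(self, path) -> None:
        doc = {
            "net": self.net.to_dict(),
            "module_sets": [list(s) for s in self.module_sets],
            "module_labels": self.module_labels,
            "anchor_point": self.anchor_point.tolist(),
            "column_names": list(self.column_names),
            "column_kinds": list(self.column_kinds),
            "training": self.training,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "PRNModel":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            net=ModularNet.from_dict(doc["net"]),
            module_sets=[tuple(s) for s in doc["module_sets"]],
            module_labels=doc["module_labels"],
            anchor_point=np.asarray(doc["anchor_point"]),
            column_names=tuple(doc["column_names"]),
            column_kinds=tuple(doc["column_kinds"]),
            training=dict(doc.get("training", {})),
        )


def _base_weights(base: ModularNet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(base.modules) != 1 or base.modules[0].var_idx.size != base.n_features:
        raise ValueError("base model must be a fully connected single-module MLP")
    m = base.modules[0]
    return m.W, m.b, m.v


def build_prn(base: ModularNet, gam: GamLassoModel, anchor_point: np.ndarray,
              column_names=(), column_kinds=()) -> PRNModel:
    """Assemble the modular network reproducing the Lasso-GAM exactly.

    Univariate module for response i: the base hidden layer with every
    input but i clamped at the anchor, output weights scaled by the Lasso
    coefficient.  Bivariate module for (i, j): three replicas encoding the
    inclusion-exclusion cut ``m_ij - m_i - m_j``, so the module equals the
    coefficient times the pure pairwise component.  Offsets enforce
    module-zero at the anchor; the global intercept is the Lasso's.
    """
    W, b, v = _base_weights(base)
    a = np.asarray(anchor_point, float)
    p = base.n_features
    if a.shape[0] != p:
        raise ValueError("anchor dimension does not match the base model")
    base_shift = a @ W  # clamped contribution of the full anchor

    modules: list[Module] = []
    sets: list[tuple[int, ...]] = []
    labels: list[str] = []
    for k in gam.selected_set:
        beta = gam.coefficients[k]
        idx_set = gam.index_sets[k]
        for i in idx_set:
            if i >= p:
                raise ValueError(
                    f"response {gam.labels[k]!r} refers to column {i}, "
                    f"absent from the base model"
                )
        if len(idx_set) == 1:
            (i,) = idx_set
            Wm = W[[i], :].copy()
            bm = b + base_shift - a[i] * W[i]
            vm = beta * v
            mod = Module(np.array([i]), Wm, bm.copy(), vm.copy())
        else:
            i, j = idx_set
            H = b.size
            Wm = np.zeros((2, 3 * H))
            Wm[0, :H], Wm[1, :H] = W[i], W[j]          # joint cut
            Wm[0, H:2 * H] = W[i]                       # i-only cut
            Wm[1, 2 * H:] = W[j]                        # j-only cut
            bm = np.concatenate([
                b + base_shift - a[i] * W[i] - a[j] * W[j],
                b + base_shift - a[i] * W[i],
                b + base_shift - a[j] * W[j],
            ])
            vm = np.concatenate([beta * v, -beta * v, -beta * v])
            mod = Module(np.array([i, j]), Wm, bm, vm)
        mod.offset = float(mod.raw(a[None, :])[0])
        modules.append(mod)
        sets.append(tuple(idx_set))
        labels.append(gam.labels[k])

    net = ModularNet(modules, gam.intercept, p,
                     metadata={"source": "build_prn",
                               "base": dict(base.metadata)})
    return PRNModel(net, sets, labels, a, tuple(column_names),
                    tuple(column_kinds))


def retrain_prn(model: PRNModel, table, outcome: np.ndarray, seed: int = 0,
                epochs: int = 500, learning_rate: float = 0.005,
                validation_fraction: float = 0.2, patience: int = 20,
                l2: float = 1e-4, batch_size: int = 512) -> PRNModel:
    """Backpropagation over module weights and the intercept.

    The module structure is untouched (no cross-module connections can
    appear), and after training each module is re-centred at the anchor
    with the shifts absorbed into the intercept, so the anchored-zero
    property survives exactly.  ``epochs=0`` returns the initialization.
    """
    X = table.values if isinstance(table, StandardizedTable) else np.asarray(table, float)
    try:
        net, record = train(
            model.net, X, np.asarray(outcome).ravel(), seed=seed,
            learning_rate=learning_rate, max_epochs=epochs, patience=patience,
            validation_fraction=validation_fraction, l2=l2,
            batch_size=batch_size,
        )
    except FloatingPointError as err:
        raise FloatingPointError(
            f"PRN retraining diverged: {err}; reduce learning_rate"
        ) from None
    net.recenter(model.anchor_point)
    return PRNModel(
        net, list(model.module_sets), list(model.module_labels),
        model.anchor_point, model.column_names, model.column_kinds,
        training={"seed": seed, "epochs_run": record.epochs_run,
                  "best_epoch": record.best_epoch,
                  "val_loss": record.val_loss[-1] if record.val_loss else None},
    )


def prn_to_lasso(model: PRNModel, table, outcome: np.ndarray,
                 grids: list[np.ndarray] | None = None, folds: int = 10,
                 seed: int = 0, n_lambdas: int = 100,
                 lambda_ratio: float = 1e-4,
                 allow_new_pairs: bool = False) -> tuple[GamLassoModel, AnovaDecomposition]:
    """Second pass: decompose the PRN's own logit and re-select.

    Candidates are restricted to the PRN's variables — all singletons that
    appear in any module plus exactly the pairs that exist as bivariate
    modules (``allow_new_pairs=True`` admits every pair of PRN variables).
    """
    from .anova import quantile_grids

    if isinstance(table, StandardizedTable):
        if table.missing_mask.any():
            raise ValueError("table still contains missing values; impute first")
        X = table.values
        if grids is None:
            grids_full = quantile_grids(table)
        else:
            grids_full = grids
        kinds = table.anchor.kinds
        names = table.column_names
    else:
        X = np.asarray(table, float)
        if grids is None:
            raise ValueError("grids are required when passing a bare matrix")
        grids_full = grids
        kinds = tuple(model.column_kinds) or None
        names = tuple(model.column_names) or None

    singles = sorted({i for s in model.module_sets for i in s})
    if allow_new_pairs:
        from itertools import combinations
        pairs = list(combinations(singles, 2))
    else:
        pairs = [s for s in model.module_sets if len(s) == 2]

    decomp = decompose(model, model.anchor_point, grids_full, max_order=2,
                       pairs=pairs, singles=singles, kinds=kinds, names=names)
    features = build_feature_matrix(decomp, X)
    path = fit_lasso_path(features, outcome, folds=folds, seed=seed,
                          n_lambdas=n_lambdas, lambda_ratio=lambda_ratio,
                          decomposition=decomp)
    return select_model(path, "min_cv"), decomp


@dataclass
class ExplanationRecord:
    """Additive per-patient explanation: contribution of each response (in
    logit units), the intercept, and their sum pushed through the sigmoid."""

    terms: list[tuple[str, float]]
    intercept: float

    @property
    def logit(self) -> float:
        return self.intercept + sum(c for _, c in self.terms)

    @property
    def probability(self) -> float:
        return float(sigmoid(np.array([self.logit]))[0])

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": t, "logit_contribution": c, "odds_ratio": float(np.exp(c))}
                for t, c in self.terms]
        rows.append({"term": "(intercept)", "logit_contribution": self.intercept,
                     "odds_ratio": float(np.exp(self.intercept))})
        df = pd.DataFrame(rows)
        return df


def explain(model, row: np.ndarray) -> ExplanationRecord:
    """Decompose one (standardized, complete) row's prediction.

    ``model`` is a :class:`PRNModel` (module outputs are the terms) or a
    :class:`GamLassoModel` carrying its decomposition (terms are
    coefficient times model-direct component value).  The contributions
    plus the intercept reproduce the model logit exactly.
    """
    row = np.asarray(row, float).ravel()
    if isinstance(row, np.ndarray) and np.any(~np.isfinite(row)):
        raise ValueError("row contains missing values; impute first")
    if isinstance(model, PRNModel):
        contribs = model.module_contributions(row[None, :])[0]
        terms = list(zip(model.module_labels, contribs.astype(float)))
        return ExplanationRecord(terms, model.intercept)
    if isinstance(model, GamLassoModel):
        if model.decomposition is None or model.decomposition.model is None:
            raise ValueError(
                "this GamLassoModel carries no decomposition/model reference"
            )
        sel = model.selected_set
        sets = [model.index_sets[k] for k in sel]
        vals = cut_component_values(
            model.decomposition.model, model.decomposition.anchor_point,
            row[None, :], sets)[0]
        terms = [(model.labels[k], float(model.coefficients[k] * vals[m]))
                 for m, k in enumerate(sel)]
        return ExplanationRecord(terms, model.intercept)
    raise TypeError(f"cannot explain model of type {type(model).__name__}")


def export_nomogram(responses: list[PartialResponse],
                    coefficients: np.ndarray, intercept: float,
                    anchor: AnchorVector) -> pd.DataFrame:
    """Value -> odds-ratio contribution tables, in raw units.

    One block per term; a bivariate response with a binary partner is
    exported as one curve per indicator level.  Summing the log odds-ratio
    contributions for a patient's values and adding the intercept gives the
    prediction's logit.
    """
    rows = []
    for resp, beta in zip(responses, coefficients):
        if beta == 0:
            continue
        if resp.order == 1:
            j = resp.var_indices[0]
            raw_grid = resp.grids[0] * anchor.scale[j] + anchor.anchor[j]
            logits = beta * resp.values
            for val, lo in zip(raw_grid, logits):
                rows.append({
                    "term": resp.label, "variable": resp.var_names[0],
                    "value": float(val), "level": "",
                    "logit_contribution": float(lo),
                    "odds_ratio": float(np.exp(lo)),
                })
        else:
            i, j = resp.var_indices
            kinds = resp.kinds
            if BINARY in kinds:
                # orient so axis 0 is the continuous variable
                bin_axis = 1 if kinds[1] == BINARY else 0
                cont_axis = 1 - bin_axis
                cont_idx = resp.var_indices[cont_axis]
                raw_cont = (resp.grids[cont_axis] * anchor.scale[cont_idx]
                            + anchor.anchor[cont_idx])
                bin_idx = resp.var_indices[bin_axis]
                raw_bin = (resp.grids[bin_axis] * anchor.scale[bin_idx]
                           + anchor.anchor[bin_idx])
                for bi, bval in enumerate(raw_bin):
                    sl = resp.values[:, bi] if bin_axis == 1 else resp.values[bi, :]
                    level = f"{resp.var_names[bin_axis]}={bval:g}"
                    for val, v in zip(raw_cont, beta * sl):
                        rows.append({
                            "term": resp.label,
                            "variable": resp.var_names[cont_axis],
                            "value": float(val), "level": level,
                            "logit_contribution": float(v),
                            "odds_ratio": float(np.exp(v)),
                        })
            else:
                raw_i = resp.grids[0] * anchor.scale[i] + anchor.anchor[i]
                raw_j = resp.grids[1] * anchor.scale[j] + anchor.anchor[j]
                for ai, vi in enumerate(raw_i):
                    for aj, vj in enumerate(raw_j):
                        lo = float(beta * resp.values[ai, aj])
                        rows.append({
                            "term": resp.label, "variable": resp.var_names[0],
                            "value": float(vi),
                            "level": f"{resp.var_names[1]}={vj:g}",
                            "logit_contribution": lo,
                            "odds_ratio": float(np.exp(lo)),
                        })
    rows.append({"term": "(intercept)", "variable": "", "value": np.nan,
                 "level": "", "logit_contribution": float(intercept),
                 "odds_ratio": float(np.exp(intercept))})
    return pd.DataFrame(rows)


def nomogram_from_gam(model: GamLassoModel, anchor: AnchorVector) -> pd.DataFrame:
    if not model.responses:
        raise ValueError("model carries no response grids; refit with a "
                         "decomposition attached")
    sel = model.selected_set
    responses = [model.responses[k] for k in sel]
    coefs = model.coefficients[sel]
    return export_nomogram(responses, coefs, model.intercept, anchor)
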