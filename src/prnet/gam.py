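"""Sparse additive model selection over partial responses.

Each partial response, evaluated row-wise on the training table (by direct
cuts of the source model, not by grid interpolation), becomes one feature
of an L1-penalized logistic regression.  Because the features already live
on the logit scale of the source model, they are not re-standardized before
penalization: a coefficient of 1 means "keep this component as the black
box estimated it", and the penalty treats all components comparably.
Responses whose coefficients survive the penalty form the selected set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import _lasso
from ._nn import sigmoid
from .anova import AnovaDecomposition, PartialResponse, cut_component_values
from .data import StandardizedTable

RULES = ("min_cv", "one_se")


@dataclass
class ResponseFeatureMatrix:
    """n_rows x n_responses matrix; column k is response k evaluated on the
    data (model-direct).  A row at the anchor is a zero row."""

    values: np.ndarray
    labels: list[str]
    index_sets: list[tuple[int, ...]]

    @property
    def n_responses(self) -> int:
        return self.values.shape[1]


def build_feature_matrix(decomposition: AnovaDecomposition,
                         table: StandardizedTable | np.ndarray) -> ResponseFeatureMatrix:
    """One column per retained response, in decomposition order."""
    if isinstance(table, StandardizedTable):
        if table.missing_mask.any():
            raise ValueError("table still contains missing values; impute first")
        X = table.values
    else:
        X = np.asarray(table, float)
    if decomposition.model is None:
        raise ValueError("decomposition carries no model reference")
    sets = [tuple(r.var_indices) for r in decomposition.responses]
    vals = cut_component_values(decomposition.model, decomposition.anchor_point,
                                X, sets)
    return ResponseFeatureMatrix(vals, list(decomposition.labels), sets)


@dataclass
class GamLassoModel:
    """L1 path over response features plus a selected single-lambda model."""

    labels: list[str]
    index_sets: list[tuple[int, ...]]
    lambdas: np.ndarray
    coef_path: np.ndarray       # (L, p)
    intercept_path: np.ndarray  # (L,)
    cv_deviance: np.ndarray     # (L,) mean over folds
    cv_se: np.ndarray           # (L,) standard error over folds
    train_deviance: np.ndarray  # (L,)
    rule: str = "min_cv"
    selected_index: int = 0
    folds: int = 10
    seed: int = 0
    responses: list[PartialResponse] = field(default_factory=list)
    decomposition: AnovaDecomposition | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return self.coef_path[self.selected_index]

    @property
    def intercept(self) -> float:
        return float(self.intercept_path[self.selected_index])

    @property
    def penalty(self) -> float:
        return float(self.lambdas[self.selected_index])

    @property
    def selected_set(self) -> list[int]:
        return list(np.flatnonzero(self.coefficients))

    @property
    def selected_labels(self) -> list[str]:
        return [self.labels[k] for k in self.selected_set]

    def entry_order(self) -> list[int]:
        """Responses ordered by the lambda at which they first enter the
        path — the survivors of the highest penalties come first."""
        first = np.full(len(self.labels), np.inf)
        for li in range(self.lambdas.size):
            nz = self.coef_path[li] != 0
            newly = nz & ~np.isfinite(first)
            first[newly] = li
        order = np.argsort(first, kind="stable")
        return [int(k) for k in order if np.isfinite(first[k])]

    def support_sizes(self) -> np.ndarray:
        return (self.coef_path != 0).sum(axis=1)

    def path_report(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "lambda": self.lambdas,
            "train_deviance": self.train_deviance,
            "cv_deviance": self.cv_deviance,
            "cv_se": self.cv_se,
            "n_selected": self.support_sizes(),
        })
        for k, lab in enumerate(self.labels):
            df[f"beta[{lab}]"] = self.coef_path[:, k]
        return df

    # -- persistence -----------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "labels": self.labels,
            "index_sets": [list(s) for s in self.index_sets],
            "lambdas": self.lambdas.tolist(),
            "coef_path": self.coef_path.tolist(),
            "intercept_path": self.intercept_path.tolist(),
            "cv_deviance": self.cv_deviance.tolist(),
            "cv_se": self.cv_se.tolist(),
            "train_deviance": self.train_deviance.tolist(),
            "rule": self.rule,
            "selected_index": self.selected_index,
            "folds": self.folds,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "GamLassoModel":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            labels=doc["labels"],
            index_sets=[tuple(s) for s in doc["index_sets"]],
            lambdas=np.asarray(doc["lambdas"]),
            coef_path=np.asarray(doc["coef_path"]),
            intercept_path=np.asarray(doc["intercept_path"]),
            cv_deviance=np.asarray(doc["cv_deviance"]),
            cv_se=np.asarray(doc["cv_se"]),
            train_deviance=np.asarray(doc["train_deviance"]),
            rule=doc["rule"],
            selected_index=doc["selected_index"],
            folds=doc["folds"],
            seed=doc["seed"],
        )


def fit_lasso_path(features: ResponseFeatureMatrix, outcome: np.ndarray,
                   lambda_grid: np.ndarray | None = None, folds: int = 10,
                   seed: int = 0, n_lambdas: int = 100,
                   lambda_ratio: float = 1e-4, tol: float = 1e-5,
                   cv_tol: float = 1e-3, standardize: bool = False,
                   decomposition: AnovaDecomposition | None = None) -> GamLassoModel:
    """Penalized path plus k-fold cross-validated deviance, seeded.

    The default grid runs from lambda_max (all coefficients zero) down four
    decades.  ``standardize=True`` scales the feature columns to unit SD
    before penalization (sensitivity analysis only) and reports the
    coefficients back on the original scale.
    """
    F = np.asarray(features.values, float)
    y = np.asarray(outcome, float).ravel()
    if folds < 2:
        raise ValueError("cross-validation needs k >= 2 folds")
    if len(set(np.unique(y)) - {0.0, 1.0}) or np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes coded 0/1")

    scales = np.ones(F.shape[1])
    if standardize:
        scales = F.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
    Fs = F / scales

    if lambda_grid is None:
        lambda_grid = _lasso.default_lambda_grid(Fs, y, n_lambdas, lambda_ratio)
    lambda_grid = np.asarray(lambda_grid, float)

    b0s, betas = _lasso.logistic_lasso_path(Fs, y, lambda_grid, tol=tol)
    train_dev = np.array([
        _lasso.binomial_deviance(y, sigmoid(b0s[li] + Fs @ betas[li]))
        for li in range(lambda_grid.size)
    ])

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_dev = np.empty((folds, lambda_grid.size))
    for f, (tr, va) in enumerate(splitter.split(Fs, y)):
        fb0, fbeta = _lasso.logistic_lasso_path(Fs[tr], y[tr], lambda_grid,
                                                tol=max(tol, cv_tol))
        pv = sigmoid(fb0[:, None] + fbeta @ Fs[va].T)
        eps = 1e-12
        pv = np.clip(pv, eps, 1 - eps)
        fold_dev[f] = -2.0 * np.mean(
            y[va] * np.log(pv) + (1 - y[va]) * np.log(1 - pv), axis=1)
    cv_mean = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(folds)

    model = GamLassoModel(
        labels=list(features.labels),
        index_sets=list(features.index_sets),
        lambdas=lambda_grid,
        coef_path=betas / scales,
        intercept_path=b0s,
        cv_deviance=cv_mean,
        cv_se=cv_se,
        train_deviance=train_dev,
        folds=folds,
        seed=seed,
        responses=list(decomposition.responses) if decomposition else [],
        decomposition=decomposition,
    )
    return select_model(model, "min_cv")


def select_model(path: GamLassoModel, rule: str = "min_cv") -> GamLassoModel:
    """Pick the working lambda: minimum CV deviance, or the sparsest model
    within one standard error of it."""
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    i_min = int(np.argmin(path.cv_deviance))
    if rule == "min_cv":
        idx = i_min
    else:
        threshold = path.cv_deviance[i_min] + path.cv_se[i_min]
        ok = np.flatnonzero(path.cv_deviance[: i_min + 1] <= threshold)
        idx = int(ok[0]) if ok.size else i_min  # largest qualifying lambda
    return replace(path, rule=rule, selected_index=idx)


def predict_gam(model: GamLassoModel, features: ResponseFeatureMatrix | np.ndarray) -> np.ndarray:
    """Sigmoid of the additive linear predictor over response features."""
    F = features.values if isinstance(features, ResponseFeatureMatrix) else np.asarray(features, float)
    if F.shape[1] != len(model.labels):
        raise ValueError(
            f"feature matrix has {F.shape[1]} columns; model needs "
            f"{len(model.labels)}"
        )
    return sigmoid(predict_gam_logit(model, F))


def predict_gam_logit(model: GamLassoModel, features) -> np.ndarray:
    F = features.values if isinstance(features, ResponseFeatureMatrix) else np.asarray(features, float)
    return model.intercept + F @ model.coefficients
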