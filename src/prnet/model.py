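"""Model/Results front end for the full interpretable-risk workflow.

``PartialResponseNetwork`` is constructed from a data table (or dataframe
plus schema); ``fit`` runs the whole procedure — base MLP, anchored
decomposition, Lasso selection, modular network build and retraining, and
the second decompose-and-select pass — and returns a
:class:`PRNResults` carrying the fitted objects, held-out performance,
per-patient explanations, and the nomogram export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import anova, gam as gam_mod, mlp as mlp_mod, prn as prn_mod
from ._nn import ModularNet, sigmoid
from .config import PipelineConfig
from .data import (
    AnchorVector,
    DataTable,
    Schema,
    StandardizedTable,
    compute_anchor,
    encode_dataframe,
    impute_zero,
    multiple_impute,
    standardize,
)
from .evaluation import EvaluationReport, auroc, evaluate_scores


class PartialResponseNetwork:
    """Self-explaining additive risk model for a binary outcome.

    Parameters
    ----------
    table
        Encoded :class:`DataTable` with a binary outcome.
    config
        Optional :class:`PipelineConfig`; defaults are used otherwise.
    """

    def __init__(self, table: DataTable, config: PipelineConfig | None = None):
        if table.outcome is None:
            raise ValueError("fitting requires a table with an outcome column")
        self.table = table
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: Schema,
                       config: PipelineConfig | None = None) -> "PartialResponseNetwork":
        return cls(encode_dataframe(df, schema), config)

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None) -> "PRNResults":
        cfg = self.config
        if seed is not None:
            cfg.seed = int(seed)

        table = self.table
        anchor = compute_anchor(table)
        if table.missing_mask.any() and cfg.impute.method == "multiple":
            table = multiple_impute(table, cfg.impute.strata, cfg.impute.m,
                                    seed=cfg.stage_seed("impute"))
        std = standardize(table, anchor)
        std = impute_zero(std)  # no-op when nothing is missing

        X, y = std.values, table.outcome
        n = X.shape[0]

        # held-out split for honest discrimination estimates
        test_fraction = cfg.evaluation.test_fraction
        rng = np.random.default_rng(cfg.stage_seed("split"))
        perm = rng.permutation(n)
        n_test = int(round(test_fraction * n))
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        Xtr, ytr = X[train_idx], y[train_idx]

        train_std = StandardizedTable(Xtr, np.zeros_like(Xtr, bool), anchor,
                                      outcome=ytr)

        base = mlp_mod.train_mlp(
            train_std, ytr, hidden_units=cfg.mlp.width_grid,
            l2_penalty=cfg.mlp.l2_penalty, seed=cfg.stage_seed("mlp"),
            validation_fraction=cfg.mlp.validation_fraction,
            learning_rate=cfg.mlp.learning_rate, max_epochs=cfg.mlp.max_epochs,
            patience=cfg.mlp.patience, batch_size=cfg.mlp.batch_size,
        )

        grids = anova.quantile_grids(train_std, cfg.anova.n_grid)
        pairs = None
        if cfg.anova.max_pairs is not None:
            pairs = _top_variance_pairs(base, np.zeros(X.shape[1]), grids,
                                        cfg.anova.max_pairs)
        decomp = anova.decompose(
            base, np.zeros(X.shape[1]), grids, max_order=cfg.anova.max_order,
            pairs=pairs, kinds=list(anchor.kinds), names=list(anchor.column_names),
        )

        features = gam_mod.build_feature_matrix(decomp, Xtr)
        path = gam_mod.fit_lasso_path(
            features, ytr, folds=cfg.lasso.folds, seed=cfg.stage_seed("lasso"),
            n_lambdas=cfg.lasso.n_lambdas, lambda_ratio=cfg.lasso.lambda_ratio,
            standardize=cfg.lasso.standardize, decomposition=decomp,
        )
        first_gam = gam_mod.select_model(path, cfg.lasso.rule)

        prn0 = prn_mod.build_prn(base, first_gam, np.zeros(X.shape[1]),
                                 anchor.column_names, anchor.kinds)
        prn = prn_mod.retrain_prn(
            prn0, Xtr, ytr, seed=cfg.stage_seed("prn"), epochs=cfg.prn.epochs,
            learning_rate=cfg.prn.learning_rate, patience=cfg.prn.patience,
            l2=cfg.prn.l2, batch_size=cfg.prn.batch_size,
        )
        if prn.module_sets:
            final_gam, final_decomp = prn_mod.prn_to_lasso(
                prn, train_std, ytr, folds=cfg.lasso.folds,
                seed=cfg.stage_seed("prn_lasso"), n_lambdas=cfg.lasso.n_lambdas,
                lambda_ratio=cfg.lasso.lambda_ratio,
                allow_new_pairs=cfg.prn.allow_new_pairs,
            )
            final_gam = gam_mod.select_model(final_gam, cfg.lasso.rule)
        else:
            final_gam, final_decomp = first_gam, decomp

        return PRNResults(
            model=self, anchor=anchor, std_values=X, outcome=y,
            train_idx=train_idx, test_idx=test_idx, base_mlp=base,
            decomposition=decomp, first_gam=first_gam, prn=prn,
            final_gam=final_gam, final_decomposition=final_decomp,
        )


def _top_variance_pairs(model, anchor_point, grids, max_pairs):
    """Rank candidate pairs by the grid variance of their component."""
    d = anchor_point.shape[0]
    scores = []
    for i, j in combinations(range(d), 2):
        r = anova.component_bivariate(model, anchor_point, i, j,
                                      (grids[i], grids[j]))
        scores.append(((i, j), float(np.var(r.values))))
    scores.sort(key=lambda t: -t[1])
    return [p for p, _ in scores[:max_pairs]]


@dataclass
class PRNResults:
    """Everything the fit produced, with statsmodels-flavoured accessors."""

    model: PartialResponseNetwork
    anchor: AnchorVector
    std_values: np.ndarray
    outcome: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    base_mlp: ModularNet
    decomposition: anova.AnovaDecomposition
    first_gam: gam_mod.GamLassoModel
    prn: prn_mod.PRNModel
    final_gam: gam_mod.GamLassoModel
    final_decomposition: anova.AnovaDecomposition

    # -- predictions ----------------------------------------------------
    def predict_logit(self, X: np.ndarray | None = None) -> np.ndarray:
        """Final-model logit (PRN-Lasso) for standardized rows."""
        X = self.std_values if X is None else np.atleast_2d(np.asarray(X, float))
        sel = self.final_gam.selected_set
        if not sel:
            return np.full(X.shape[0], self.final_gam.intercept)
        sets = [self.final_gam.index_sets[k] for k in sel]
        src = self.final_decomposition
        vals = anova.cut_component_values(src.model, src.anchor_point, X, sets)
        return self.final_gam.intercept + vals @ self.final_gam.coefficients[sel]

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        return sigmoid(self.predict_logit(X))

    # -- headline numbers ----------------------------------------------
    @property
    def params(self) -> pd.Series:
        sel = self.final_gam.selected_set
        return pd.Series(
            [self.final_gam.intercept, *self.final_gam.coefficients[sel]],
            index=["(intercept)", *[self.final_gam.labels[k] for k in sel]],
        )

    def holdout_auroc(self) -> dict[str, float]:
        """Held-out AUROC of the base MLP and the final model."""
        Xte, yte = self.std_values[self.test_idx], self.outcome[self.test_idx]
        return {
            "mlp": auroc(self.base_mlp.predict_logit(Xte), yte),
            "prn_lasso": auroc(self.predict_logit(Xte), yte),
        }

    def evaluate(self, X: np.ndarray | None = None,
                 y: np.ndarray | None = None) -> EvaluationReport:
        """Discrimination + calibration report (held-out rows by default)."""
        if X is None:
            X, y = self.std_values[self.test_idx], self.outcome[self.test_idx]
        probs = self.predict(X)
        baseline = sigmoid(self.base_mlp.predict_logit(np.atleast_2d(X)))
        return evaluate_scores(probs, y, self.model.config.evaluation.groups,
                               self.model.config.evaluation.level,
                               baseline=baseline)

    # -- interpretation -------------------------------------------------
    def explain(self, row: int | np.ndarray) -> prn_mod.ExplanationRecord:
        """Additive explanation of one prediction (row index or
        standardized vector)."""
        vec = self.std_values[row] if np.isscalar(row) else np.asarray(row, float)
        return prn_mod.explain(self.final_gam, vec)

    def nomogram(self) -> pd.DataFrame:
        return prn_mod.nomogram_from_gam(self.final_gam, self.anchor)

    def summary(self) -> str:
        sel = self.final_gam.selected_set
        hold = self.holdout_auroc()
        lines = [
            "Partial Response Network (Lasso-refined)",
            "=" * 58,
            f"rows (train/test): {self.train_idx.size}/{self.test_idx.size}"
            f"   prevalence: {self.outcome.mean():.3f}",
            f"base MLP: {self.base_mlp.metadata.get('architecture', '?')}",
            f"penalty lambda: {self.final_gam.penalty:.5g}  "
            f"(rule: {self.final_gam.rule})",
            f"held-out AUROC  base MLP: {hold['mlp']:.3f}   "
            f"final model: {hold['prn_lasso']:.3f}",
            "-" * 58,
            f"{'term':<34}{'coef':>10}",
        ]
        lines.append(f"{'(intercept)':<34}{self.final_gam.intercept:>10.4f}")
        for k in sel:
            lines.append(
                f"{self.final_gam.labels[k]:<34}"
                f"{self.final_gam.coefficients[k]:>10.4f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)
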