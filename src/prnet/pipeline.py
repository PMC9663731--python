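"""Staged, resumable pipeline with plain-file artifacts and a manifest.

Every stage writes ordinary inspectable files (delimited tables, JSON,
YAML) into the output directory; a manifest records the config hash and a
content hash per artifact.  With ``resume=True`` a stage whose artifacts
exist, match their recorded hashes and belong to the same config is
skipped and its outputs are loaded from disk instead.  Per-stage seeds are
derived from the global seed, so two runs with the same config produce
byte-identical model files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import anova, gam as gam_mod, mlp as mlp_mod, prn as prn_mod
from .config import PipelineConfig
from .data import (
    DataTable,
    Schema,
    StandardizedTable,
    compute_anchor,
    impute_zero,
    multiple_impute,
    read_table,
    standardize,
    write_table,
)
from .evaluation import evaluate_scores
from ._nn import sigmoid
from .synthetic import generate, registry_preset

log = logging.getLogger("prnet")

STAGES = ("simulate", "impute", "fit", "decompose", "select", "refine",
          "evaluate", "nomogram")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()


class Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.doc = {"config_hash": None, "stages": {}}
        if path.exists():
            self.doc = json.loads(path.read_text())

    def stage_done(self, stage: str, config_hash: str) -> bool:
        rec = self.doc["stages"].get(stage)
        if rec is None or self.doc.get("config_hash") != config_hash:
            return False
        return all(Path(f).exists() and _hash_file(Path(f)) == h
                   for f, h in rec["artifacts"].items())

    def record(self, stage: str, config_hash: str, files: list[Path]) -> None:
        if self.doc.get("config_hash") != config_hash:
            self.doc = {"config_hash": config_hash, "stages": {}}
        self.doc["stages"][stage] = {
            "artifacts": {str(f): _hash_file(Path(f)) for f in files},
        }
        self.path.write_text(json.dumps(self.doc, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig, out_dir, table: DataTable | None = None,
                 input_table=None, schema_file=None, simulate_n: int | None = None,
                 resume: bool = False) -> Path:
    """Run every stage end to end; returns the artifact directory.

    Data come from (in order of precedence) ``table``, ``input_table`` +
    ``schema_file``, or the synthetic registry preset (``simulate_n``
    rows).  Any stage error is logged with its stage name and re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    manifest = Manifest(out / "manifest.json")
    config.to_yaml(out / "config.yaml")

    def done(stage: str) -> bool:
        skip = resume and manifest.stage_done(stage, chash)
        if skip:
            log.info("stage %s: up to date, skipping", stage)
        else:
            log.info("stage %s: running", stage)
        return skip

    stage = "simulate"
    try:
        # ------------------------------------------------ data ingestion
        if table is None:
            if input_table is not None:
                schema = Schema.from_yaml(schema_file)
                table = read_table(input_table, schema)
            elif done(stage):
                schema = Schema.from_yaml(out / "schema.yaml")
                table = read_table(out / "table.csv", schema)
            else:
                spec = registry_preset(n=simulate_n or 20000,
                                       seed=config.stage_seed("simulate"))
                table, _ = generate(spec)
                write_table(table, out / "table.csv")
                spec.schema().to_yaml(out / "schema.yaml")
                (out / "ground_truth.json").write_text(json.dumps({
                    "intercept": spec.intercept,
                    "active_terms": [list(t) for t in spec.active_terms()],
                    "seed": spec.seed, "n": spec.n,
                }, indent=2))
                manifest.record(stage, chash, [out / "table.csv",
                                               out / "schema.yaml",
                                               out / "ground_truth.json"])

        # ------------------------------------------- impute + standardize
        stage = "impute"
        anchor = compute_anchor(table)
        if table.missing_mask.any() and config.impute.method == "multiple":
            if done(stage):
                table = read_table(out / "imputed.csv", table.schema)
            else:
                table = multiple_impute(table, config.impute.strata,
                                        config.impute.m,
                                        seed=config.stage_seed("impute"))
                write_table(table, out / "imputed.csv")
                manifest.record(stage, chash, [out / "imputed.csv"])
        std = impute_zero(standardize(table, anchor))
        X, y = std.values, table.outcome
        n, d = X.shape
        zeros = np.zeros(d)

        rng = np.random.default_rng(config.stage_seed("split"))
        perm = rng.permutation(n)
        n_test = int(round(config.evaluation.test_fraction * n))
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        Xtr, ytr = X[train_idx], y[train_idx]
        train_std = StandardizedTable(Xtr, np.zeros_like(Xtr, bool), anchor,
                                      outcome=ytr)

        # ----------------------------------------------------- base MLP
        stage = "fit"
        if done(stage):
            base = mlp_mod.load_model(out / "mlp.json")
        else:
            base = mlp_mod.train_mlp(
                train_std, ytr, hidden_units=config.mlp.width_grid,
                l2_penalty=config.mlp.l2_penalty,
                seed=config.stage_seed("mlp"),
                validation_fraction=config.mlp.validation_fraction,
                learning_rate=config.mlp.learning_rate,
                max_epochs=config.mlp.max_epochs,
                patience=config.mlp.patience,
                batch_size=config.mlp.batch_size,
            )
            mlp_mod.save_model(base, out / "mlp.json")
            manifest.record(stage, chash, [out / "mlp.json"])

        # ------------------------------------------------- decomposition
        stage = "decompose"
        grids = anova.quantile_grids(train_std, config.anova.n_grid)
        if done(stage):
            decomp = anova.AnovaDecomposition.from_json(out / "decomposition.json")
            decomp.model = base
        else:
            decomp = anova.decompose(base, zeros, grids,
                                     max_order=config.anova.max_order,
                                     kinds=list(anchor.kinds),
                                     names=list(anchor.column_names))
            decomp.to_json(out / "decomposition.json")
            manifest.record(stage, chash, [out / "decomposition.json"])

        # ----------------------------------------------------- selection
        stage = "select"
        if done(stage):
            first_gam = gam_mod.GamLassoModel.from_json(out / "gam.json")
            first_gam.responses = list(decomp.responses)
            first_gam.decomposition = decomp
        else:
            features = gam_mod.build_feature_matrix(decomp, Xtr)
            path = gam_mod.fit_lasso_path(
                features, ytr, folds=config.lasso.folds,
                seed=config.stage_seed("lasso"),
                n_lambdas=config.lasso.n_lambdas,
                lambda_ratio=config.lasso.lambda_ratio,
                standardize=config.lasso.standardize, decomposition=decomp,
            )
            first_gam = gam_mod.select_model(path, config.lasso.rule)
            first_gam.to_json(out / "gam.json")
            first_gam.path_report().to_csv(out / "lasso_path.csv", index=False)
            manifest.record(stage, chash,
                            [out / "gam.json", out / "lasso_path.csv"])

        # --------------------------------- PRN build/retrain, second pass
        stage = "refine"
        if done(stage):
            prn = prn_mod.PRNModel.from_json(out / "prn.json")
            final_decomp = anova.AnovaDecomposition.from_json(
                out / "final_decomposition.json")
            final_decomp.model = prn
            final_gam = gam_mod.GamLassoModel.from_json(out / "final_gam.json")
            final_gam.responses = list(final_decomp.responses)
            final_gam.decomposition = final_decomp
        else:
            prn0 = prn_mod.build_prn(base, first_gam, zeros,
                                     anchor.column_names, anchor.kinds)
            prn = prn_mod.retrain_prn(
                prn0, Xtr, ytr, seed=config.stage_seed("prn"),
                epochs=config.prn.epochs,
                learning_rate=config.prn.learning_rate,
                patience=config.prn.patience, l2=config.prn.l2,
                batch_size=config.prn.batch_size,
            )
            if prn.module_sets:
                final_gam, final_decomp = prn_mod.prn_to_lasso(
                    prn, train_std, ytr, folds=config.lasso.folds,
                    seed=config.stage_seed("prn_lasso"),
                    n_lambdas=config.lasso.n_lambdas,
                    lambda_ratio=config.lasso.lambda_ratio,
                    allow_new_pairs=config.prn.allow_new_pairs,
                )
                final_gam = gam_mod.select_model(final_gam, config.lasso.rule)
            else:
                final_gam, final_decomp = first_gam, decomp
            prn.to_json(out / "prn.json")
            final_gam.to_json(out / "final_gam.json")
            final_decomp.to_json(out / "final_decomposition.json")
            manifest.record(stage, chash,
                            [out / "prn.json", out / "final_gam.json",
                             out / "final_decomposition.json"])

        # ---------------------------------------------------- evaluation
        def final_logit(rows: np.ndarray) -> np.ndarray:
            sel = final_gam.selected_set
            if not sel:
                return np.full(rows.shape[0], final_gam.intercept)
            sets = [final_gam.index_sets[k] for k in sel]
            vals = anova.cut_component_values(
                final_decomp.model, final_decomp.anchor_point, rows, sets)
            return final_gam.intercept + vals @ final_gam.coefficients[sel]

        stage = "evaluate"
        if not done(stage):
            Xte, yte = X[test_idx], y[test_idx]
            report = evaluate_scores(
                sigmoid(final_logit(Xte)), yte,
                groups=config.evaluation.groups,
                level=config.evaluation.level,
                baseline=sigmoid(base.predict_logit(Xte)),
            )
            report.to_frame().to_csv(out / "evaluation.csv", index=False)
            report.group_table.to_csv(out / "calibration_groups.csv",
                                      index=False)
            manifest.record(stage, chash, [out / "evaluation.csv",
                                           out / "calibration_groups.csv"])

        stage = "nomogram"
        if not done(stage):
            nomo = prn_mod.nomogram_from_gam(final_gam, anchor)
            nomo.to_csv(out / "nomogram.csv", index=False)
            manifest.record(stage, chash, [out / "nomogram.csv"])
    except Exception:
        log.exception("pipeline stage %r failed", stage)
        raise

    return out
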