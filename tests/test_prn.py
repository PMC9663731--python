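"""Modular network: initialization exactness, modularity, explanations."""

import numpy as np
import pytest

from prnet import generate, registry_preset, compute_anchor, standardize, impute_zero
from prnet._nn import sigmoid
from prnet.anova import decompose, quantile_grids
from prnet.gam import build_feature_matrix, fit_lasso_path, predict_gam_logit, select_model
from prnet.mlp import train_mlp
from prnet.prn import (
    ExplanationRecord,
    PRNModel,
    build_prn,
    explain,
    export_nomogram,
    nomogram_from_gam,
    prn_to_lasso,
    retrain_prn,
)


@pytest.fixture(scope="module")
def setup():
    """Small trained base model + first-pass selection on preset data."""
    spec = registry_preset(n=4000, seed=55)
    table, _ = generate(spec)
    anchor = compute_anchor(table)
    std = impute_zero(standardize(table, anchor))
    X, y = std.values, table.outcome
    base = train_mlp(std, y, hidden_units=8, seed=1, max_epochs=150)
    grids = quantile_grids(std)
    dec = decompose(base, np.zeros(X.shape[1]), grids,
                    kinds=list(anchor.kinds), names=list(anchor.column_names))
    feats = build_feature_matrix(dec, X)
    gam = fit_lasso_path(feats, y, seed=2, folds=5, decomposition=dec)
    gam = select_model(gam, "min_cv")
    return spec, table, anchor, std, X, y, base, dec, gam


class TestBuild:
    def test_initialization_reproduces_lasso_gam_exactly(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]),
                        anchor.column_names, anchor.kinds)
        rng = np.random.default_rng(0)
        R = rng.normal(0, 1.5, (1000, X.shape[1]))
        feats = build_feature_matrix(dec, R)
        want = predict_gam_logit(gam, feats)
        got = prn.predict_logit(R)
        assert np.max(np.abs(got - want)) < 1e-8

    def test_empty_selection_collapses_to_intercept(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        from dataclasses import replace
        null = replace(gam, selected_index=0)  # lambda_max: all zeros
        assert not null.selected_set
        prn = build_prn(base, null, np.zeros(X.shape[1]))
        out = prn.predict_logit(np.random.default_rng(1).normal(0, 1, (20, X.shape[1])))
        np.testing.assert_allclose(out, null.intercept, atol=1e-12)

    def test_module_ignores_non_member_inputs_exactly(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]))
        rng = np.random.default_rng(3)
        row = rng.normal(0, 1, (1, X.shape[1]))
        base_out = prn.module_contributions(row)
        for k, members in enumerate(prn.module_sets):
            perturbed = row.copy()
            for j in range(X.shape[1]):
                if j not in members:
                    perturbed[0, j] += rng.normal(0, 2)
            out = prn.module_contributions(perturbed)
            assert out[0, k] == base_out[0, k]  # exactly unchanged

    def test_modules_are_zero_at_anchor(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]))
        contrib = prn.module_contributions(np.zeros((1, X.shape[1])))
        np.testing.assert_allclose(contrib, 0.0, atol=1e-12)

    def test_unknown_variable_rejected(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        from dataclasses import replace
        bad = replace(gam, index_sets=[(99,)] * len(gam.index_sets))
        with pytest.raises(ValueError, match="absent|column"):
            build_prn(base, bad, np.zeros(X.shape[1]))

    def test_serialization_round_trip(self, setup, tmp_path):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]),
                        anchor.column_names, anchor.kinds)
        prn.to_json(tmp_path / "prn.json")
        back = PRNModel.from_json(tmp_path / "prn.json")
        R = np.random.default_rng(5).normal(0, 1, (50, X.shape[1]))
        np.testing.assert_array_equal(prn.predict_logit(R), back.predict_logit(R))


class TestRetrain:
    def test_zero_epochs_is_identity(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]))
        same = retrain_prn(prn, X, y, seed=0, epochs=0)
        R = np.random.default_rng(7).normal(0, 1, (100, X.shape[1]))
        np.testing.assert_allclose(same.predict_logit(R), prn.predict_logit(R),
                                   atol=1e-12)

    def test_anchored_zero_survives_retraining(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]))
        trained = retrain_prn(prn, X, y, seed=4, epochs=60)
        contrib = trained.module_contributions(np.zeros((1, X.shape[1])))
        np.testing.assert_allclose(contrib, 0.0, atol=1e-12)

    def test_modularity_preserved_after_retraining(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = retrain_prn(build_prn(base, gam, np.zeros(X.shape[1])),
                          X, y, seed=4, epochs=40)
        for mod, members in zip(prn.net.modules, prn.module_sets):
            assert tuple(mod.var_idx) == tuple(members)

    def test_corrupted_initialization_is_recovered(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        n = X.shape[0]
        tr, te = slice(0, 3 * n // 4), slice(3 * n // 4, None)
        prn_good = build_prn(base, gam, np.zeros(X.shape[1]))
        prn_bad = build_prn(base, gam, np.zeros(X.shape[1]))
        prn_bad.net.modules[0].v *= 0.5  # corrupt one module's scale

        good = retrain_prn(prn_good, X[tr], y[tr], seed=8, epochs=300)
        bad = retrain_prn(prn_bad, X[tr], y[tr], seed=8, epochs=300)
        from prnet._nn import log_loss
        ll_good = log_loss(y[te], sigmoid(good.predict_logit(X[te])))
        ll_bad = log_loss(y[te], sigmoid(bad.predict_logit(X[te])))
        assert ll_bad <= ll_good * 1.01  # within 1% of the clean start


class TestSecondPass:
    def test_single_module_gives_single_candidate(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]),
                        anchor.column_names, anchor.kinds)
        # keep only the first univariate module
        keep = next(k for k, s in enumerate(prn.module_sets) if len(s) == 1)
        prn.net.modules = [prn.net.modules[keep]]
        prn.module_sets = [prn.module_sets[keep]]
        prn.module_labels = [prn.module_labels[keep]]
        gam2, dec2 = prn_to_lasso(prn, std, y, seed=3, folds=3)
        assert len(dec2.responses) == 1
        assert dec2.responses[0].var_indices == prn.module_sets[0]

    def test_decomposing_prn_recovers_module_functions_exactly(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]),
                        anchor.column_names, anchor.kinds)
        grids = quantile_grids(std)
        singles = sorted({i for s in prn.module_sets for i in s})
        pairs = [s for s in prn.module_sets if len(s) == 2]
        dec2 = decompose(prn, np.zeros(X.shape[1]), grids, pairs=pairs,
                         singles=singles, kinds=list(anchor.kinds),
                         names=list(anchor.column_names))
        # the PRN is additive over modules, so truncation at order 2 is exact
        from prnet.anova import reconstruction_residual
        res = reconstruction_residual(dec2, X[:200])
        assert np.max(np.abs(res)) < 1e-8


class TestExplain:
    def test_anchor_row_explanation_is_all_zero(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]),
                        anchor.column_names, anchor.kinds)
        rec = explain(prn, np.zeros(X.shape[1]))
        assert all(c == 0 for _, c in rec.terms)
        assert rec.probability == pytest.approx(
            sigmoid(np.array([prn.intercept]))[0])

    def test_contributions_plus_intercept_reproduce_logit(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        prn = build_prn(base, gam, np.zeros(X.shape[1]),
                        anchor.column_names, anchor.kinds)
        row = X[17]
        rec = explain(prn, row)
        assert abs(rec.logit - prn.predict_logit(row[None])[0]) < 1e-10

    def test_gam_explanation_matches_gam_logit(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        row = X[3]
        rec = explain(gam, row)
        feats = build_feature_matrix(dec, row[None])
        want = predict_gam_logit(gam, feats)[0]
        assert abs(rec.logit - want) < 1e-10

    def test_missing_value_rejected(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        row = X[0].copy()
        row[2] = np.nan
        prn = build_prn(base, gam, np.zeros(X.shape[1]))
        with pytest.raises(ValueError, match="missing"):
            explain(prn, row)

    def test_worked_example_record(self):
        # synthetic stand-in contribution set with the published intercept;
        # the record's aggregation reproduces the published total and risk
        contributions = [
            ("donor_age", 0.15), ("ischemic_time", -0.12),
            ("recipient_age x diagnosis", -0.30), ("creatinine", -0.10),
            ("tx_year", -0.1276),
        ]
        rec = ExplanationRecord(contributions, intercept=-2.3354)
        assert rec.logit == pytest.approx(-2.833, abs=1e-3)
        assert round(rec.probability, 3) == 0.056


class TestNomogram:
    def test_anchor_value_has_unit_odds_ratio(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        nomo = nomogram_from_gam(gam, anchor)
        for term, block in nomo[nomo["term"] != "(intercept)"].groupby("term"):
            assert np.min(np.abs(block["logit_contribution"])) < 1e-8
            near = block.iloc[np.argmin(np.abs(block["logit_contribution"]))]
            assert near["odds_ratio"] == pytest.approx(1.0, abs=1e-8)

    def test_odds_ratio_is_exp_of_logit_column(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        nomo = nomogram_from_gam(gam, anchor)
        np.testing.assert_allclose(nomo["odds_ratio"],
                                   np.exp(nomo["logit_contribution"]))

    def test_interaction_exported_per_indicator_level(self, setup):
        _, _, anchor, std, X, y, base, dec, gam = setup
        pair_terms = [gam.labels[k] for k in gam.selected_set
                      if len(gam.index_sets[k]) == 2]
        if not pair_terms:
            pytest.skip("no pair survived selection in this fixture")
        nomo = nomogram_from_gam(gam, anchor)
        for term in pair_terms:
            block = nomo[nomo["term"] == term]
            resp = gam.responses[gam.labels.index(term)]
            if "binary" in resp.kinds:
                assert block["level"].nunique() == 2
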