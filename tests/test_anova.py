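"""Anchored decomposition: cut identities, exactness, interpolation."""

from itertools import chain, combinations

import numpy as np
import pytest

from prnet._nn import init_mlp
from prnet.anova import (
    AnovaDecomposition,
    FunctionModel,
    PartialResponse,
    component_bivariate,
    component_univariate,
    decompose,
    evaluate_response,
    reconstruction_residual,
    rms,
)


def _grids(d, lo=-2.0, hi=2.0, k=21):
    return [np.linspace(lo, hi, k) for _ in range(d)]


def brute_force_components(g, anchor, X):
    """Oracle: every subset component by inclusion-exclusion over cuts.

    Returns {subset: values on X}; summing all of them (plus g(anchor))
    reconstructs g exactly — the defining property of the decomposition.
    """
    d = anchor.size
    subsets = list(chain.from_iterable(
        combinations(range(d), r) for r in range(d + 1)))
    cut_cache = {}

    def cut(u):
        if u not in cut_cache:
            A = np.tile(anchor, (X.shape[0], 1))
            for c in u:
                A[:, c] = X[:, c]
            cut_cache[u] = g(A)
        return cut_cache[u]

    comp = {}
    for u in subsets:
        total = np.zeros(X.shape[0])
        for r in range(len(u) + 1):
            for v in combinations(u, r):
                total += (-1) ** (len(u) - len(v)) * cut(v)
        comp[u] = total
    return comp


class TestComponents:
    def test_constant_function_gives_zero_response(self):
        model = FunctionModel(lambda X: np.full(X.shape[0], 3.7), 3)
        r = component_univariate(model, np.zeros(3), 0, np.linspace(-1, 1, 11))
        np.testing.assert_allclose(r.values, 0.0, atol=1e-12)

    def test_identity_coordinate_recovers_shifted_line(self):
        model = FunctionModel(lambda X: X[:, 1], 3)
        anchor = np.array([0.5, -0.25, 0.0])
        grid = np.linspace(-1, 1, 9)
        r = component_univariate(model, anchor, 1, grid)
        np.testing.assert_allclose(r.values, grid - (-0.25), atol=1e-12)

    def test_additive_components_are_the_addends_under_zero_anchor(self):
        model = FunctionModel(lambda X: X[:, 0] ** 2 + X[:, 1], 2)
        grid = np.linspace(-2, 2, 15)
        f1 = component_univariate(model, np.zeros(2), 0, grid)
        f2 = component_univariate(model, np.zeros(2), 1, grid)
        np.testing.assert_allclose(f1.values, grid ** 2, atol=1e-12)
        np.testing.assert_allclose(f2.values, grid, atol=1e-12)

    def test_additive_function_has_zero_pairwise_component(self):
        model = FunctionModel(lambda X: np.sin(X[:, 0]) + X[:, 1] ** 3, 2)
        r = component_bivariate(model, np.zeros(2), 0, 1,
                                (np.linspace(-2, 2, 13), np.linspace(-2, 2, 13)))
        assert np.max(np.abs(r.values)) < 1e-8

    def test_pure_product_interaction(self):
        model = FunctionModel(lambda X: X[:, 0] * X[:, 1], 2)
        g1, g2 = np.linspace(-2, 2, 11), np.linspace(-1, 3, 9)
        f12 = component_bivariate(model, np.zeros(2), 0, 1, (g1, g2))
        np.testing.assert_allclose(f12.values, np.outer(g1, g2), atol=1e-12)
        f1 = component_univariate(model, np.zeros(2), 0, g1)
        np.testing.assert_allclose(f1.values, 0.0, atol=1e-12)

    def test_anchor_slice_of_bivariate_is_zero(self):
        net = init_mlp(3, 7, seed=42)
        anchor = np.array([0.3, -1.2, 0.8])
        gi = np.sort(np.append(np.linspace(-2, 2, 10), anchor[0]))
        gj = np.sort(np.append(np.linspace(-2, 2, 10), anchor[1]))
        r = component_bivariate(net, anchor, 0, 1, (gi, gj))
        ia = int(np.where(gi == anchor[0])[0][0])
        ja = int(np.where(gj == anchor[1])[0][0])
        np.testing.assert_allclose(r.values[ia, :], 0.0, atol=1e-12)
        np.testing.assert_allclose(r.values[:, ja], 0.0, atol=1e-12)

    def test_same_index_pair_rejected(self):
        net = init_mlp(3, 4, seed=0)
        with pytest.raises(ValueError, match="distinct"):
            component_bivariate(net, np.zeros(3), 1, 1, (_grids(1)[0],) * 2)


class TestDecompose:
    def test_counting_all_orders(self):
        net = init_mlp(5, 6, seed=1)
        dec = decompose(net, np.zeros(5), _grids(5), max_order=2)
        assert len(dec.responses) == 5 + 5 * 4 // 2
        dec1 = decompose(net, np.zeros(5), _grids(5), max_order=1)
        assert len(dec1.responses) == 5

    def test_intercept_is_g_at_anchor(self):
        net = init_mlp(4, 5, seed=2)
        anchor = np.array([0.1, 0.2, -0.3, 0.0])
        dec = decompose(net, anchor, _grids(4))
        assert dec.intercept == pytest.approx(
            float(net.predict_logit(anchor[None])[0]), abs=1e-14)

    def test_purely_additive_truncation_is_exact(self):
        model = FunctionModel(
            lambda X: 1.0 + np.tanh(X[:, 0]) + X[:, 1] ** 2 - 0.5 * X[:, 2], 3)
        dec = decompose(model, np.zeros(3), _grids(3), max_order=2)
        rng = np.random.default_rng(0)
        X = rng.uniform(-2, 2, (100, 3))
        res = reconstruction_residual(dec, X)
        assert np.max(np.abs(res)) < 1e-8

    @pytest.mark.parametrize("d", [3, 4])
    def test_full_subset_expansion_reconstructs_random_mlp(self, d):
        net = init_mlp(d, 8, seed=100 + d)
        anchor = np.zeros(d)
        rng = np.random.default_rng(d)
        X = rng.normal(0, 1.5, (100, d))
        comp = brute_force_components(net.predict_logit, anchor, X)
        total = sum(comp.values()) + 0.0
        # comp[()] equals g(anchor); the sum of ALL components equals g
        np.testing.assert_allclose(total, net.predict_logit(X), atol=1e-8)

    def test_truncation_residual_equals_missing_higher_orders(self):
        d = 3
        net = init_mlp(d, 8, seed=33)
        anchor = np.zeros(d)
        dec = decompose(net, anchor, _grids(d), max_order=2)
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (50, d))
        res = reconstruction_residual(dec, X)
        oracle = brute_force_components(net.predict_logit, anchor, X)
        np.testing.assert_allclose(res, oracle[(0, 1, 2)], atol=1e-8)

    def test_interaction_only_function_truncates_exactly(self):
        model = FunctionModel(lambda X: X[:, 0] * X[:, 2] - 1.0, 3)
        dec = decompose(model, np.zeros(3), _grids(3), max_order=2)
        rng = np.random.default_rng(1)
        X = rng.uniform(-2, 2, (80, 3))
        assert rms(reconstruction_residual(dec, X)) < 1e-8

    def test_recovery_of_wrapped_generating_function(self):
        # decomposing the truth itself must reproduce the symbolic anchored
        # components on the grid
        from dataclasses import replace
        from prnet import (compute_anchor, generate, registry_preset,
                           standardize, true_partial_responses, unstandardize)

        spec = registry_preset(n=2000, seed=14)
        table, _ = generate(spec)
        anchor = compute_anchor(table)
        std = standardize(table, anchor)

        def g(Z):
            return spec.logit(unstandardize(Z, anchor))

        model = FunctionModel(g, len(anchor.anchor))
        from prnet.anova import quantile_grids
        grids = quantile_grids(std)
        names = list(anchor.column_names)
        dec = decompose(model, np.zeros(len(names)), grids,
                        kinds=list(anchor.kinds), names=names)
        truth = true_partial_responses(
            spec, anchor, {nm: grids[j] for j, nm in enumerate(names)})
        for t in truth:
            got = dec.response_for(*t.var_indices)
            tv = t.values
            if t.order == 2 and got.var_indices != t.var_indices:
                tv = tv.T
            np.testing.assert_allclose(got.values, tv, atol=1e-8)

    def test_serialization_round_trips_exactly(self, tmp_path):
        net = init_mlp(3, 5, seed=9)
        dec = decompose(net, np.zeros(3), _grids(3),
                        names=["a", "b", "c"])
        path = tmp_path / "dec.json"
        dec.to_json(path)
        back = AnovaDecomposition.from_json(path)
        assert back.intercept == dec.intercept
        for r1, r2 in zip(dec.responses, back.responses):
            np.testing.assert_array_equal(r1.values, r2.values)
            assert r1.var_names == r2.var_names


class TestEvaluateResponse:
    @pytest.fixture
    def resp(self):
        grid = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        return PartialResponse((0,), ("x",), ("continuous",), (grid,),
                               np.array([4.0, 1.0, 0.0, 1.0, 4.0]))

    def test_anchor_maps_to_zero(self, resp):
        assert evaluate_response(resp, np.array([0.0]))[0] == 0.0

    def test_grid_point_is_exact(self, resp):
        assert evaluate_response(resp, np.array([-1.0]))[0] == 1.0

    def test_midpoint_is_arithmetic_mean(self, resp):
        assert evaluate_response(resp, np.array([0.5]))[0] == pytest.approx(0.5)

    def test_extrapolation_is_linear_from_terminal_segment(self, resp):
        # slope of last segment is 3 -> value at 3.0 is 4 + 3
        assert evaluate_response(resp, np.array([3.0]))[0] == pytest.approx(7.0)
        assert evaluate_response(resp, np.array([-3.0]))[0] == pytest.approx(7.0)

    def test_binary_lookup_is_exact_and_strict(self):
        resp = PartialResponse((1,), ("flag",), ("binary",),
                               (np.array([0.0, 2.1]),), np.array([0.0, 0.8]))
        assert evaluate_response(resp, np.array([2.1]))[0] == 0.8
        with pytest.raises(ValueError, match="flag"):
            evaluate_response(resp, np.array([1.0]))

    def test_bilinear_on_grid_product(self):
        g = np.array([0.0, 1.0])
        vals = np.array([[0.0, 0.0], [0.0, 1.0]])  # s*t on {0,1}^2
        resp = PartialResponse((0, 1), ("a", "b"),
                               ("continuous", "continuous"), (g, g), vals)
        out = evaluate_response(resp, np.array([0.5]), np.array([0.5]))
        assert out[0] == pytest.approx(0.25)
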