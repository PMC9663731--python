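"""Anchored (cut-type) functional ANOVA decomposition of a black-box logit.

Any multivariate function g can be written as an intercept plus components
of increasing order defined by cutting g at an anchor point c:

    f_0       = g(c)
    f_i(t)    = g(c with coordinate i set to t) - f_0
    f_ij(s,t) = g(c with i -> s, j -> t) - f_i(s) - f_j(t) - f_0

and so on by inclusion-exclusion over subsets; the sum over all subset
components reconstructs g exactly.  With the anchor at the data median
(the zero vector after median-anchored standardization), each component is
the additive contribution of its variable(s) to the log-odds, and it
vanishes when those variables sit at their median — the property that makes
the decomposition directly readable as a clinical risk profile.

Truncating at order two keeps main effects and pairwise interactions; the
residual is exactly the sum of the discarded higher-order components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .data import BINARY, CONTINUOUS, StandardizedTable

_BINARY_TOL = 1e-8


class FunctionModel:
    """Wrap a plain callable ``X -> logit`` as a black-box model."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], n_features: int,
                 metadata: dict | None = None):
        self._fn = fn
        self.n_features = int(n_features)
        self.metadata = metadata or {}

    def predict_logit(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} columns, got {X.shape[1]}"
            )
        out = np.asarray(self._fn(X), float)
        if not np.all(np.isfinite(out)):
            raise ValueError("model produced non-finite logits")
        return out


@dataclass
class PartialResponse:
    """A univariate or bivariate component on an evaluation grid.

    Grids are in standardized units and strictly increasing; binary
    variables carry their two standardized levels.  ``values`` has one axis
    per variable.  The component is exactly 0 at the anchor (order 1) and 0
    along both anchor slices (order 2).
    """

    var_indices: tuple[int, ...]
    var_names: tuple[str, ...]
    kinds: tuple[str, ...]
    grids: tuple[np.ndarray, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grids = tuple(np.asarray(g, float) for g in self.grids)
        self.values = np.asarray(self.values, float)
        if len(self.var_indices) not in (1, 2):
            raise ValueError("only order-1 and order-2 responses are supported")
        for g in self.grids:
            if g.ndim != 1 or g.size < 2 or np.any(np.diff(g) <= 0):
                raise ValueError("grids must be strictly increasing with >= 2 points")
        expect = tuple(g.size for g in self.grids)
        if self.values.shape != expect:
            raise ValueError(f"values shape {self.values.shape} != grid shape {expect}")

    @property
    def order(self) -> int:
        return len(self.var_indices)

    @property
    def label(self) -> str:
        return " x ".join(self.var_names)

    def __call__(self, *coords) -> np.ndarray:
        return evaluate_response(self, *coords)


def _interp_weights(grid: np.ndarray, x: np.ndarray, kind: str,
                    name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices (i0, i1) and weight w on i1 for 1-D linear interpolation with
    linear extrapolation from the terminal segments; exact lookup for
    binary variables."""
    x = np.asarray(x, float)
    if kind == BINARY:
        d = np.abs(x[:, None] - grid[None, :])
        j = np.argmin(d, axis=1)
        if np.any(d[np.arange(x.size), j] > _BINARY_TOL):
            bad = x[d[np.arange(x.size), j] > _BINARY_TOL][0]
            raise ValueError(
                f"binary variable {name!r} evaluated at non-level value {bad!r}"
            )
        return j, j, np.zeros_like(x)
    i1 = np.clip(np.searchsorted(grid, x), 1, grid.size - 1)
    i0 = i1 - 1
    w = (x - grid[i0]) / (grid[i1] - grid[i0])  # may lie outside [0,1]: extrapolation
    return i0, i1, w


def evaluate_response(response: PartialResponse, *coords) -> np.ndarray:
    """Evaluate on per-variable coordinate vectors (standardized units).

    Continuous axes use piecewise-linear interpolation with linear
    extrapolation beyond the grid; binary axes use exact lookup; order-2
    responses combine the axes bilinearly.
    """
    if len(coords) != response.order:
        raise ValueError(
            f"response of order {response.order} needs {response.order} "
            f"coordinate arrays"
        )
    coords = [np.atleast_1d(np.asarray(c, float)) for c in coords]
    if response.order == 1:
        (grid,) = response.grids
        i0, i1, w = _interp_weights(grid, coords[0], response.kinds[0],
                                    response.var_names[0])
        v = response.values
        return (1 - w) * v[i0] + w * v[i1]
    g1, g2 = response.grids
    a0, a1, wa = _interp_weights(g1, coords[0], response.kinds[0],
                                 response.var_names[0])
    b0, b1, wb = _interp_weights(g2, coords[1], response.kinds[1],
                                 response.var_names[1])
    v = response.values
    return ((1 - wa) * (1 - wb) * v[a0, b0] + (1 - wa) * wb * v[a0, b1]
            + wa * (1 - wb) * v[a1, b0] + wa * wb * v[a1, b1])


@dataclass
class AnovaDecomposition:
    """Intercept plus a set of partial responses cut from one model."""

    intercept: float
    responses: list[PartialResponse]
    anchor_point: np.ndarray
    model: object | None = None
    column_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.anchor_point = np.asarray(self.anchor_point, float)
        seen = set()
        for r in self.responses:
            key = tuple(sorted(r.var_indices))
            if key in seen:
                raise ValueError(f"duplicate response for variables {key}")
            seen.add(key)

    def response_for(self, *indices: int) -> PartialResponse:
        key = tuple(sorted(indices))
        for r in self.responses:
            if tuple(sorted(r.var_indices)) == key:
                return r
        raise KeyError(key)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.responses]

    # -- structured-text round trip -------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "intercept": self.intercept,
            "anchor_point": self.anchor_point.tolist(),
            "column_names": list(self.column_names),
            "responses": [
                {
                    "var_indices": list(r.var_indices),
                    "var_names": list(r.var_names),
                    "kinds": list(r.kinds),
                    "grids": [g.tolist() for g in r.grids],
                    "values": r.values.tolist(),
                }
                for r in self.responses
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "AnovaDecomposition":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        responses = [
            PartialResponse(
                tuple(r["var_indices"]), tuple(r["var_names"]), tuple(r["kinds"]),
                tuple(np.asarray(g) for g in r["grids"]), np.asarray(r["values"]),
            )
            for r in doc["responses"]
        ]
        return cls(doc["intercept"], responses, np.asarray(doc["anchor_point"]),
                   column_names=tuple(doc["column_names"]))


def quantile_grids(table: StandardizedTable, n_points: int = 101) -> list[np.ndarray]:
    """Default evaluation grids: equally spaced quantiles of the observed
    standardized values (deduplicated) for continuous columns; the two
    observed levels for binary columns."""
    grids = []
    for j in range(table.n_columns):
        obs = table.values[~table.missing_mask[:, j], j]
        if table.anchor.kinds[j] == BINARY:
            levels = np.unique(obs)
            if levels.size != 2:
                raise ValueError(
                    f"binary column {table.column_names[j]!r} does not show "
                    "two levels in the data"
                )
            grids.append(levels)
        else:
            q = np.quantile(obs, np.linspace(0, 1, n_points))
            grids.append(np.unique(q))
    return grids


def _cut_matrix(anchor: np.ndarray, cols: Sequence[int],
                coords: Sequence[np.ndarray]) -> np.ndarray:
    X = np.tile(anchor, (coords[0].shape[0], 1))
    for c, vals in zip(cols, coords):
        X[:, c] = vals
    return X


def component_univariate(model, anchor: np.ndarray, i: int, grid: np.ndarray,
                         kind: str = CONTINUOUS, name: str | None = None,
                         g0: float | None = None) -> PartialResponse:
    """f_i on the grid: cut g along coordinate i, minus the intercept."""
    anchor = np.asarray(anchor, float)
    grid = np.asarray(grid, float)
    if g0 is None:
        g0 = float(model.predict_logit(anchor[None, :])[0])
    vals = model.predict_logit(_cut_matrix(anchor, [i], [grid])) - g0
    return PartialResponse((i,), (name or f"x{i}",), (kind,), (grid,), vals)


def component_bivariate(model, anchor: np.ndarray, i: int, j: int,
                        grids: tuple[np.ndarray, np.ndarray],
                        kinds: tuple[str, str] = (CONTINUOUS, CONTINUOUS),
                        names: tuple[str, str] | None = None,
                        g0: float | None = None,
                        f_i: PartialResponse | None = None,
                        f_j: PartialResponse | None = None) -> PartialResponse:
    """f_ij on the grid product, with both univariate cuts removed."""
    if i == j:
        raise ValueError("bivariate component needs two distinct variables")
    anchor = np.asarray(anchor, float)
    gi, gj = (np.asarray(g, float) for g in grids)
    if g0 is None:
        g0 = float(model.predict_logit(anchor[None, :])[0])
    names = names or (f"x{i}", f"x{j}")
    if f_i is None:
        f_i = component_univariate(model, anchor, i, gi, kinds[0], names[0], g0)
    if f_j is None:
        f_j = component_univariate(model, anchor, j, gj, kinds[1], names[1], g0)
    S, T = np.meshgrid(gi, gj, indexing="ij")
    cut = model.predict_logit(
        _cut_matrix(anchor, [i, j], [S.ravel(), T.ravel()])
    ).reshape(S.shape)
    vals = cut - f_i.values[:, None] - f_j.values[None, :] - g0
    # the anchor slices are identically zero; enforce it exactly rather
    # than leave machine-rounding residue from the cancellation
    vals[gi == anchor[i], :] = 0.0
    vals[:, gj == anchor[j]] = 0.0
    return PartialResponse((i, j), names, kinds, (gi, gj), vals)


def decompose(model, anchor: np.ndarray, grids: Sequence[np.ndarray],
              max_order: int = 2,
              pairs: Sequence[tuple[int, int]] | None = None,
              singles: Sequence[int] | None = None,
              kinds: Sequence[str] | None = None,
              names: Sequence[str] | None = None) -> AnovaDecomposition:
    """All order-1 components plus (for ``max_order=2``) pairwise ones.

    ``pairs`` restricts which interactions are cut (default: all pairs of
    the retained singles); ``singles`` restricts the univariate set.
    """
    if max_order not in (1, 2):
        raise ValueError("max_order must be 1 or 2")
    anchor = np.asarray(anchor, float)
    d = anchor.shape[0]
    singles = list(range(d)) if singles is None else list(singles)
    kinds = list(kinds) if kinds is not None else [CONTINUOUS] * d
    names = list(names) if names is not None else [f"x{j}" for j in range(d)]
    g0 = float(model.predict_logit(anchor[None, :])[0])

    uni: dict[int, PartialResponse] = {}
    for i in singles:
        uni[i] = component_univariate(model, anchor, i, grids[i], kinds[i],
                                      names[i], g0)
    responses: list[PartialResponse] = [uni[i] for i in singles]
    if max_order == 2:
        if pairs is None:
            pairs = list(combinations(singles, 2))
        for i, j in pairs:
            if i not in uni:
                uni[i] = component_univariate(model, anchor, i, grids[i],
                                              kinds[i], names[i], g0)
            if j not in uni:
                uni[j] = component_univariate(model, anchor, j, grids[j],
                                              kinds[j], names[j], g0)
            responses.append(
                component_bivariate(model, anchor, i, j, (grids[i], grids[j]),
                                    (kinds[i], kinds[j]), (names[i], names[j]),
                                    g0, uni[i], uni[j])
            )
    return AnovaDecomposition(g0, responses, anchor, model=model,
                              column_names=tuple(names))


def cut_component_values(model, anchor: np.ndarray, X: np.ndarray,
                         index_sets: Sequence[tuple[int, ...]]) -> np.ndarray:
    """Model-direct component values per row (no interpolation).

    Column k holds ``f_{u_k}(x_{u_k})`` for each requested index set,
    computed by cutting the model at the anchor for every row.  This is the
    evaluation convention used for residuals, selection features and
    explanations, so the exactness identities hold to machine precision.
    """
    anchor = np.asarray(anchor, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[0]
    g0 = float(model.predict_logit(anchor[None, :])[0])

    needed_singles = sorted({i for u in index_sets for i in u})
    uni: dict[int, np.ndarray] = {}
    for i in needed_singles:
        A = np.tile(anchor, (n, 1))
        A[:, i] = X[:, i]
        uni[i] = model.predict_logit(A) - g0

    out = np.empty((n, len(index_sets)))
    for k, u in enumerate(index_sets):
        if len(u) == 1:
            out[:, k] = uni[u[0]]
        elif len(u) == 2:
            i, j = u
            A = np.tile(anchor, (n, 1))
            A[:, i] = X[:, i]
            A[:, j] = X[:, j]
            out[:, k] = model.predict_logit(A) - uni[i] - uni[j] - g0
        else:
            raise ValueError("only order-1/2 index sets are supported")
    return out


def reconstruction_residual(decomposition: AnovaDecomposition,
                            table: StandardizedTable | np.ndarray) -> np.ndarray:
    """Per-row ``g(x) - [f0 + sum of retained components]``, model-direct.

    For an additive model the residual is numerically zero; in general it
    equals the sum of the components of order three and above.
    """
    if decomposition.model is None:
        raise ValueError("decomposition carries no model reference")
    X = table.values if isinstance(table, StandardizedTable) else np.asarray(table, float)
    sets = [tuple(r.var_indices) for r in decomposition.responses]
    comp = cut_component_values(decomposition.model, decomposition.anchor_point,
                                X, sets)
    total = decomposition.intercept + comp.sum(axis=1)
    return decomposition.model.predict_logit(X) - total


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))
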