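"""Schema-aware tables, median-anchored standardization, and imputation.

Registry extracts arrive as flat delimited text with a mix of continuous
measurements (ages, creatinine, ischemic time), binary flags (ventilator
use, infection) and categorical codes (diagnosis).  Everything downstream
works on a numeric encoding of that table: categoricals are expanded to 0/1
indicator columns, missing cells are tracked in an explicit mask, and all
columns are centred at the sample median (continuous) or modal value
(binary) so that the anchor point of the functional decomposition maps to
the zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"
_KINDS = (CONTINUOUS, BINARY, CATEGORICAL)

#: strings treated as missing on input, in addition to empty cells
NA_VALUES = ("", "NA", "NaN", "nan")


@dataclass(frozen=True)
class VariableSpec:
    """One source column: its name, kind and (for categoricals) level set."""

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == CATEGORICAL and len(self.categories) < 2:
            raise ValueError(f"categorical {self.name!r} needs >= 2 categories")
        object.__setattr__(self, "categories", tuple(self.categories))


@dataclass(frozen=True)
class EncodedColumn:
    """One column of the numeric matrix: a continuous variable, a binary
    flag, or a single 0/1 indicator of a categorical level."""

    name: str
    kind: str  # continuous | binary
    source: str
    level: str | None = None


@dataclass
class Schema:
    """Declares the predictor set, the outcome column and an optional
    stratification column (used by :func:`multiple_impute`)."""

    variables: list[VariableSpec]
    outcome: str | None = None
    strata: str | None = None

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def encoded_columns(self) -> list[EncodedColumn]:
        cols: list[EncodedColumn] = []
        for v in self.variables:
            if v.kind == CATEGORICAL:
                for level in v.categories:
                    cols.append(
                        EncodedColumn(f"{v.name}={level}", BINARY, v.name, level)
                    )
            else:
                cols.append(EncodedColumn(v.name, v.kind, v.name))
        return cols

    @classmethod
    def from_yaml(cls, path) -> "Schema":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        variables = [
            VariableSpec(
                name=entry["name"],
                kind=entry["kind"],
                categories=tuple(entry.get("categories", ())),
                units=entry.get("units", ""),
            )
            for entry in doc["variables"]
        ]
        return cls(variables, outcome=doc.get("outcome"), strata=doc.get("strata"))

    def to_yaml(self, path) -> None:
        doc = {
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    **({"categories": list(v.categories)} if v.categories else {}),
                    **({"units": v.units} if v.units else {}),
                }
                for v in self.variables
            ],
        }
        if self.outcome:
            doc["outcome"] = self.outcome
        if self.strata:
            doc["strata"] = self.strata
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class DataTable:
    """Encoded numeric table with an explicit missingness mask.

    ``values[i, j]`` is undefined wherever ``missing_mask[i, j]`` is True.
    The outcome, when present, must be fully observed and binary.
    """

    schema: Schema
    values: np.ndarray
    missing_mask: np.ndarray
    outcome: np.ndarray | None = None
    strata: np.ndarray | None = None
    columns: list[EncodedColumn] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if not self.columns:
            self.columns = self.schema.encoded_columns()
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count does not match schema encoding")
        if self.outcome is not None:
            self.outcome = np.asarray(self.outcome)
            if self.outcome.shape[0] != self.values.shape[0]:
                raise ValueError("outcome length does not match table")
            if np.any(pd.isna(self.outcome)):
                raise ValueError("outcome contains missing values; records with "
                                 "an unknown endpoint must be excluded upstream")
            self.outcome = self.outcome.astype(int)
            bad = set(np.unique(self.outcome)) - {0, 1}
            if bad:
                raise ValueError(f"outcome takes non-binary values {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def to_dataframe(self) -> pd.DataFrame:
        """Decode back to source columns (categorical indicator blocks
        become their level labels)."""
        data: dict[str, object] = {}
        for spec in self.schema.variables:
            cols = [j for j, c in enumerate(self.columns) if c.source == spec.name]
            if spec.kind == CATEGORICAL:
                block = self.values[:, cols]
                miss = self.missing_mask[:, cols[0]]
                levels = np.array([self.columns[j].level for j in cols])
                decoded = pd.Series(levels[np.argmax(np.nan_to_num(block), axis=1)],
                                    dtype=object)
                decoded[miss] = np.nan
                data[spec.name] = decoded
            else:
                (j,) = cols
                data[spec.name] = np.where(self.missing_mask[:, j], np.nan,
                                           self.values[:, j])
        df = pd.DataFrame(data)
        if self.outcome is not None and self.schema.outcome:
            df[self.schema.outcome] = self.outcome
        if self.strata is not None and self.schema.strata:
            df[self.schema.strata] = self.strata
        return df


def _parse_column(raw: pd.Series, spec: VariableSpec, col_label: str) -> np.ndarray:
    vals = np.full(len(raw), np.nan)
    for idx, cell in enumerate(raw):
        if pd.isna(cell) or (isinstance(cell, str) and cell.strip() in NA_VALUES):
            continue
        try:
            vals[idx] = float(cell)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric value {cell!r} in {spec.kind} column "
                f"{col_label!r} at row {idx}"
            ) from None
    return vals


def encode_dataframe(df: pd.DataFrame, schema: Schema) -> DataTable:
    """Encode a raw dataframe (source columns) into a :class:`DataTable`."""
    missing_cols = [n for n in schema.names if n not in df.columns]
    if missing_cols:
        raise ValueError(f"schema columns absent from table: {missing_cols}")

    blocks: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for spec in schema.variables:
        raw = df[spec.name]
        if spec.kind == CATEGORICAL:
            levels = set(spec.categories)
            obs = raw[~raw.apply(
                lambda c: pd.isna(c) or (isinstance(c, str) and c.strip() in NA_VALUES)
            )]
            unknown = set(obs.astype(str).str.strip()) - levels
            if unknown:
                raise ValueError(
                    f"unknown level(s) {sorted(unknown)} in categorical "
                    f"column {spec.name!r}"
                )
            miss = raw.apply(
                lambda c: pd.isna(c) or (isinstance(c, str) and c.strip() in NA_VALUES)
            ).to_numpy()
            for level in spec.categories:
                ind = (raw.astype(str).str.strip() == level).to_numpy(dtype=float)
                ind[miss] = np.nan
                blocks.append(ind)
                masks.append(miss.copy())
        else:
            vals = _parse_column(raw, spec, spec.name)
            miss = np.isnan(vals)
            if spec.kind == BINARY:
                obs = vals[~miss]
                bad = set(np.unique(obs)) - {0.0, 1.0}
                if bad:
                    raise ValueError(
                        f"binary column {spec.name!r} takes values outside "
                        f"{{0,1}}: {sorted(bad)}"
                    )
            blocks.append(vals)
            masks.append(miss)

    values = np.column_stack(blocks) if blocks else np.empty((len(df), 0))
    mask = np.column_stack(masks) if masks else np.zeros((len(df), 0), bool)
    values = np.where(mask, np.nan, values)

    outcome = None
    if schema.outcome is not None and schema.outcome in df.columns:
        outcome = df[schema.outcome].to_numpy()
    strata = None
    if schema.strata is not None and schema.strata in df.columns:
        strata = df[schema.strata].to_numpy()
        if pd.isna(strata).any():
            raise ValueError("strata column must be fully observed")
    return DataTable(schema, values, mask, outcome=outcome, strata=strata)


def read_table(path, schema: Schema, sep: str = ",") -> DataTable:
    """Read a delimited text file (header row, UTF-8) into a DataTable."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=list(NA_VALUES), encoding="utf-8")
    if schema.outcome and schema.outcome in df.columns:
        df[schema.outcome] = pd.to_numeric(df[schema.outcome])
    return encode_dataframe(df, schema)


def write_table(table: DataTable, path, sep: str = ",") -> None:
    table.to_dataframe().to_csv(path, sep=sep, index=False, na_rep="")


@dataclass(frozen=True)
class AnchorVector:
    """Per encoded column: the anchor (continuous: median; binary: mode)
    and a positive spread statistic (sample SD) used for standardization.

    A row equal to the anchor standardizes to the zero vector, which is the
    cut point of the functional decomposition.
    """

    anchor: np.ndarray
    scale: np.ndarray
    column_names: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", np.asarray(self.anchor, float))
        object.__setattr__(self, "scale", np.asarray(self.scale, float))
        if np.any(self.scale <= 0) or not np.all(np.isfinite(self.scale)):
            raise ValueError("anchor scales must be finite and > 0")

    @property
    def n_columns(self) -> int:
        return self.anchor.shape[0]


def compute_anchor(table: DataTable) -> AnchorVector:
    """Anchor every encoded column at its median (continuous) or modal
    value (binary), computed over observed entries only.

    Scale is the sample standard deviation of the observed entries.
    Constant columns are rejected: they carry no information and make the
    standardization degenerate.
    """
    anchors = np.empty(len(table.columns))
    scales = np.empty(len(table.columns))
    for j, col in enumerate(table.columns):
        obs = table.values[~table.missing_mask[:, j], j]
        if obs.size == 0:
            raise ValueError(f"column {col.name!r} has no observed values")
        sd = float(np.std(obs, ddof=1)) if obs.size > 1 else 0.0
        if sd <= 0:
            raise ValueError(
                f"column {col.name!r} is constant over observed entries; "
                "remove it before modelling"
            )
        if col.kind == CONTINUOUS:
            anchors[j] = float(np.median(obs))
        else:
            # modal value; an exact 50/50 split anchors at 0 by convention
            anchors[j] = 1.0 if np.mean(obs) > 0.5 else 0.0
        scales[j] = sd
    return AnchorVector(
        anchors, scales, tuple(table.column_names), tuple(c.kind for c in table.columns)
    )


@dataclass
class StandardizedTable:
    """Values on the ``(raw - anchor) / scale`` scale; the anchor row is the
    zero vector.  Missing slots remain masked until imputation."""

    values: np.ndarray
    missing_mask: np.ndarray
    anchor: AnchorVector
    outcome: np.ndarray | None = None
    column_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.missing_mask = np.asarray(self.missing_mask, bool)
        if not self.column_names:
            self.column_names = self.anchor.column_names

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def standardize(table: DataTable, anchor: AnchorVector) -> StandardizedTable:
    if tuple(table.column_names) != anchor.column_names:
        raise ValueError("anchor was computed on a different schema encoding")
    std = (table.values - anchor.anchor) / anchor.scale
    std = np.where(table.missing_mask, np.nan, std)
    return StandardizedTable(std, table.missing_mask.copy(), anchor,
                             outcome=None if table.outcome is None
                             else table.outcome.copy())


def unstandardize(values: np.ndarray, anchor: AnchorVector) -> np.ndarray:
    """Invert the column-wise standardization (observed entries only)."""
    return np.asarray(values, float) * anchor.scale + anchor.anchor


def impute_zero(table: StandardizedTable) -> StandardizedTable:
    """Set masked slots to 0 — the anchor — and clear the mask.

    Because every partial response vanishes at the anchor, a zero-imputed
    slot contributes exactly nothing to the model prediction.
    """
    values = np.where(table.missing_mask, 0.0, table.values)
    return StandardizedTable(
        values,
        np.zeros_like(table.missing_mask),
        table.anchor,
        outcome=None if table.outcome is None else table.outcome.copy(),
        column_names=table.column_names,
    )


def multiple_impute(table: DataTable, strata: str | np.ndarray | None = None,
                    m: int = 10, seed: int = 0) -> DataTable:
    """Hot-deck multiple imputation, stratified, stacked.

    Each missing value is replaced ``m`` times by a value sampled uniformly
    (with replacement) from the observed donors of the same column within
    the same stratum, and the ``m`` completed copies are stacked row-wise
    into one table of ``m * n_rows`` rows.  Categorical variables are
    imputed at the source-variable level (a donor row's whole indicator
    block is copied) so the one-hot invariant is preserved.
    """
    if m < 1:
        raise ValueError("m must be a positive integer")
    if isinstance(strata, str) or strata is None:
        if strata is None:
            strata_vals = table.strata
        else:
            if table.strata is None or table.schema.strata != strata:
                raise ValueError(f"table carries no strata column {strata!r}")
            strata_vals = table.strata
    else:
        strata_vals = np.asarray(strata)
    if strata_vals is None:
        strata_vals = np.zeros(table.n_rows, dtype=int)
    if pd.isna(strata_vals).any():
        raise ValueError("strata column must be fully observed")

    rng = np.random.default_rng(seed)
    # group encoded columns by source variable so categorical blocks move together
    groups: dict[str, list[int]] = {}
    for j, col in enumerate(table.columns):
        groups.setdefault(col.source, []).append(j)

    levels = pd.unique(strata_vals)
    copies = []
    for _ in range(m):
        vals = table.values.copy()
        for source, cols in groups.items():
            block_missing = table.missing_mask[:, cols[0]]
            if not block_missing.any():
                continue
            for lev in levels:
                in_stratum = strata_vals == lev
                need = block_missing & in_stratum
                if not need.any():
                    continue
                donors = np.flatnonzero(in_stratum & ~block_missing)
                if donors.size == 0:
                    raise ValueError(
                        f"stratum {lev!r} has no observed donor for "
                        f"variable {source!r}"
                    )
                picks = donors[rng.integers(0, donors.size, need.sum())]
                for c in cols:
                    vals[need, c] = table.values[picks, c]
        copies.append(vals)

    stacked = np.vstack(copies)
    mask = np.zeros_like(stacked, dtype=bool)
    outcome = None if table.outcome is None else np.tile(table.outcome, m)
    new_strata = np.tile(strata_vals, m) if table.strata is not None else None
    return DataTable(table.schema, stacked, mask, outcome=outcome,
                     strata=new_strata, columns=list(table.columns))
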