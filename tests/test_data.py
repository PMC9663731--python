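"""Table encoding, anchoring, standardization and imputation."""

import numpy as np
import pandas as pd
import pytest

from prnet.data import (
    AnchorVector,
    DataTable,
    Schema,
    VariableSpec,
    compute_anchor,
    encode_dataframe,
    impute_zero,
    multiple_impute,
    read_table,
    standardize,
    unstandardize,
    write_table,
)


class TestEncoding:
    def test_complete_file_has_all_false_mask(self, tmp_path, mixed_schema, mixed_df):
        df = mixed_df.fillna({"creatinine": 110.0})
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        table = read_table(path, mixed_schema)
        assert not table.missing_mask.any()
        assert table.n_rows == 6

    def test_blank_cell_masks_exactly_that_slot(self, tmp_path, mixed_schema, mixed_df):
        path = tmp_path / "t.csv"
        mixed_df.to_csv(path, index=False)
        table = read_table(path, mixed_schema)
        j = table.column_names.index("creatinine")
        expected = np.zeros_like(table.missing_mask)
        expected[2, j] = True
        np.testing.assert_array_equal(table.missing_mask, expected)

    def test_categorical_expands_to_indicators_summing_to_one(self, mixed_table):
        cols = [i for i, c in enumerate(mixed_table.columns)
                if c.source == "diagnosis"]
        assert len(cols) == 3
        sums = mixed_table.values[:, cols].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)

    def test_unknown_level_error_names_column_and_level(self, mixed_schema, mixed_df):
        df = mixed_df.copy()
        df.loc[0, "diagnosis"] = "Valve"
        with pytest.raises(ValueError, match="Valve.*diagnosis|diagnosis.*Valve"):
            encode_dataframe(df, mixed_schema)

    def test_non_numeric_continuous_reports_row(self, tmp_path, mixed_schema, mixed_df):
        df = mixed_df.copy()
        df["age"] = df["age"].astype(object)
        df.loc[3, "age"] = "old"
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 3"):
            read_table(path, mixed_schema)

    def test_missing_outcome_rejected(self, mixed_schema, mixed_df):
        df = mixed_df.copy()
        df.loc[1, "death"] = np.nan
        with pytest.raises(ValueError, match="outcome"):
            encode_dataframe(df, mixed_schema)

    def test_round_trip_write_read(self, tmp_path, mixed_schema, mixed_table):
        path = tmp_path / "out.csv"
        write_table(mixed_table, path)
        back = read_table(path, mixed_schema)
        np.testing.assert_array_equal(back.missing_mask, mixed_table.missing_mask)
        obs = ~mixed_table.missing_mask
        np.testing.assert_allclose(back.values[obs], mixed_table.values[obs])


class TestAnchor:
    def _table(self, col, kind="continuous"):
        schema = Schema([VariableSpec("x", kind)])
        vals = np.asarray(col, float)[:, None]
        return DataTable(schema, vals, np.isnan(vals))

    def test_odd_median(self):
        a = compute_anchor(self._table([1, 2, 3, 4, 5]))
        assert a.anchor[0] == 3

    def test_even_median_is_mean_of_central_pair(self):
        a = compute_anchor(self._table([1, 2, 3, 4]))
        assert a.anchor[0] == 2.5

    def test_binary_anchor_is_mode(self):
        a = compute_anchor(self._table([0, 0, 0, 0, 0, 0, 0, 1, 1, 1], "binary"))
        assert a.anchor[0] == 0.0

    def test_binary_tie_anchors_at_zero(self):
        a = compute_anchor(self._table([0, 0, 1, 1], "binary"))
        assert a.anchor[0] == 0.0

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_anchor(self._table([2.0, 2.0, 2.0]))

    def test_anchor_ignores_missing(self):
        a = compute_anchor(self._table([1, 2, 3, np.nan, np.nan]))
        assert a.anchor[0] == 2

    def test_scale_is_sample_sd(self):
        vals = [1.0, 2.0, 4.0, 9.0]
        a = compute_anchor(self._table(vals))
        assert a.scale[0] == pytest.approx(np.std(vals, ddof=1))


class TestStandardize:
    def test_anchor_row_maps_to_zero(self, mixed_table):
        anchor = compute_anchor(mixed_table)
        std = standardize(mixed_table, anchor)
        row = DataTable(mixed_table.schema, anchor.anchor[None, :],
                        np.zeros((1, anchor.n_columns), bool))
        std_row = standardize(row, anchor)
        np.testing.assert_allclose(std_row.values, 0.0, atol=1e-14)

    def test_explicit_value(self):
        anchor = AnchorVector(np.array([3.0]), np.array([2.0]), ("x",),
                              ("continuous",))
        schema = Schema([VariableSpec("x", "continuous")])
        t = DataTable(schema, np.array([[5.0]]), np.zeros((1, 1), bool))
        assert standardize(t, anchor).values[0, 0] == 1.0

    def test_round_trip_identity(self, mixed_table):
        anchor = compute_anchor(mixed_table)
        std = standardize(mixed_table, anchor)
        back = unstandardize(std.values, anchor)
        obs = ~mixed_table.missing_mask
        assert np.max(np.abs(back[obs] - mixed_table.values[obs])) < 1e-10

    def test_schema_mismatch_rejected(self, mixed_table):
        anchor = compute_anchor(mixed_table)
        bad = AnchorVector(anchor.anchor[:-1], anchor.scale[:-1],
                           anchor.column_names[:-1], anchor.kinds[:-1])
        with pytest.raises(ValueError, match="schema"):
            standardize(mixed_table, bad)


class TestImputeZero:
    def test_no_missing_is_identity(self, mixed_table):
        anchor = compute_anchor(mixed_table)
        std = standardize(mixed_table, anchor)
        std.missing_mask[:] = False
        std.values = np.nan_to_num(std.values)
        out = impute_zero(std)
        np.testing.assert_array_equal(out.values, std.values)

    def test_masked_slot_becomes_exactly_zero_and_observed_unchanged(self, mixed_table):
        anchor = compute_anchor(mixed_table)
        std = standardize(mixed_table, anchor)
        out = impute_zero(std)
        assert not out.missing_mask.any()
        masked = std.missing_mask
        assert np.all(out.values[masked] == 0.0)
        np.testing.assert_array_equal(out.values[~masked], std.values[~masked])

    def test_imputed_slot_contributes_nothing_to_any_response(self, mixed_table):
        # zero-imputed slots sit at the anchor, where every anchored
        # response vanishes, so the imputed variable adds nothing
        from prnet.anova import PartialResponse, evaluate_response

        grid = np.linspace(-2, 2, 9)
        resp = PartialResponse((1,), ("creatinine",), ("continuous",),
                               (grid,), grid ** 2)  # zero at anchor (0)
        anchor = compute_anchor(mixed_table)
        out = impute_zero(standardize(mixed_table, anchor))
        j = mixed_table.column_names.index("creatinine")
        imputed_value = out.values[2, j]  # row 2 creatinine was missing
        assert evaluate_response(resp, np.array([imputed_value]))[0] == 0.0


class TestMultipleImpute:
    def test_no_missing_gives_m_identical_copies(self, mixed_schema, mixed_df):
        df = mixed_df.fillna({"creatinine": 110.0})
        table = encode_dataframe(df, mixed_schema)
        out = multiple_impute(table, "era", m=10, seed=1)
        assert out.n_rows == 10 * table.n_rows
        for c in range(10):
            block = out.values[c * 6:(c + 1) * 6]
            np.testing.assert_array_equal(block, table.values)

    def test_stacked_row_count(self, mixed_table):
        out = multiple_impute(mixed_table, "era", m=10, seed=0)
        assert out.n_rows == 10 * mixed_table.n_rows
        assert not out.missing_mask.any()

    def test_imputed_values_are_observed_donors_from_same_stratum(self, mixed_table):
        out = multiple_impute(mixed_table, "era", m=25, seed=3)
        j = mixed_table.column_names.index("creatinine")
        donors = mixed_table.values[
            (~mixed_table.missing_mask[:, j]) & (mixed_table.strata == 0), j]
        n = mixed_table.n_rows
        for c in range(25):
            filled = out.values[c * n + 2, j]  # row 2 was missing, stratum 0
            assert filled in donors

    def test_deterministic_per_seed(self, mixed_table):
        a = multiple_impute(mixed_table, "era", m=5, seed=9)
        b = multiple_impute(mixed_table, "era", m=5, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seeds_differ(self, mixed_schema):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "age": rng.normal(50, 10, 60),
            "creatinine": np.where(rng.random(60) < 0.4, np.nan,
                                   rng.normal(110, 20, 60)),
            "ventilator": rng.integers(0, 2, 60),
            "diagnosis": rng.choice(["ICM", "NICM", "Other"], 60),
            "death": rng.integers(0, 2, 60),
            "era": np.zeros(60, int),
        })
        table = encode_dataframe(df, mixed_schema)
        a = multiple_impute(table, "era", m=3, seed=1)
        b = multiple_impute(table, "era", m=3, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_empty_stratum_donor_pool_is_an_error(self, mixed_schema, mixed_df):
        df = mixed_df.copy()
        df.loc[df["era"] == 0, "creatinine"] = np.nan
        table = encode_dataframe(df, mixed_schema)
        with pytest.raises(ValueError, match="stratum.*creatinine|creatinine.*stratum"):
            multiple_impute(table, "era", m=2, seed=0)

    def test_categorical_block_imputed_jointly(self, mixed_schema, mixed_df):
        df = mixed_df.copy()
        df.loc[2, "diagnosis"] = np.nan
        table = encode_dataframe(df, mixed_schema)
        out = multiple_impute(table, "era", m=8, seed=4)
        cols = [i for i, c in enumerate(out.columns) if c.source == "diagnosis"]
        sums = out.values[:, cols].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)
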