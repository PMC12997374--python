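"""Imputation, filtering, validation, SMOTE and the leakage contract."""

import numpy as np
import pandas as pd
import pytest

from spiralselect.dataset import NOMINAL, NUMERIC, ColumnMeta, TabularDataset
from spiralselect.preprocess import (PreprocessConfig, SmoteConfig,
                                     filter_high_missing_rows,
                                     fit_preprocessor, preprocess_fold,
                                     remove_numeric_outliers,
                                     smote_oversample, transform,
                                     validate_categories)


def make_ds(columns, col_meta, y):
    return TabularDataset(X=pd.DataFrame(columns), col_meta=col_meta,
                          y=np.asarray(y))


@pytest.fixture
def mixed_ds():
    return make_ds(
        {
            "htn": ["yes", "yes", "no", np.nan],
            "bu": [1.0, 2.0, 3.0, 4.0],
        },
        [ColumnMeta("htn", NOMINAL, ("yes", "no")), ColumnMeta("bu", NUMERIC)],
        [1, 1, 0, 0],
    )


class TestFitPreprocessor:
    def test_mode_is_majority_category(self, mixed_ds):
        st = fit_preprocessor(mixed_ds)
        assert st.modes["htn"] == "yes"

    def test_mode_tie_breaks_lexicographically(self):
        ds = make_ds({"htn": ["yes", "no"]},
                     [ColumnMeta("htn", NOMINAL, ("yes", "no"))], [0, 1])
        assert fit_preprocessor(ds).modes["htn"] == "no"

    def test_median_even_count(self, mixed_ds):
        assert fit_preprocessor(mixed_ds).medians["bu"] == 2.5

    def test_median_odd_count(self):
        ds = make_ds({"bu": [1.0, 2.0, 3.0]}, [ColumnMeta("bu", NUMERIC)],
                     [0, 1, 0])
        assert fit_preprocessor(ds).medians["bu"] == 2.0

    def test_all_missing_column_names_the_culprit(self):
        ds = make_ds({"bu": [np.nan, np.nan]}, [ColumnMeta("bu", NUMERIC)],
                     [0, 1])
        with pytest.raises(ValueError, match="bu"):
            fit_preprocessor(ds)


class TestRowFilter:
    def _row_ds(self, n_missing):
        """24 numeric attributes; first row has n_missing missing cells."""
        cols = {}
        meta = []
        for j in range(24):
            vals = [np.nan if j < n_missing else 1.0, 2.0]
            cols[f"f{j}"] = vals
            meta.append(ColumnMeta(f"f{j}", NUMERIC))
        return make_ds(cols, meta, [1, 0])

    def test_half_missing_is_removed(self):
        out, removed = filter_high_missing_rows(self._row_ds(12), 0.5)
        assert removed == 1 and out.n_samples == 1

    def test_just_below_half_is_retained(self):
        out, removed = filter_high_missing_rows(self._row_ds(11), 0.5)
        assert removed == 0 and out.n_samples == 2


class TestValidateCategories:
    def test_unknown_becomes_missing(self):
        ds = make_ds({"htn": ["unknown", "yes"]},
                     [ColumnMeta("htn", NOMINAL, ("yes", "no"))], [0, 1])
        out = validate_categories(ds, fit_preprocessor(ds))
        assert pd.isna(out.X["htn"].iloc[0])
        assert out.X["htn"].iloc[1] == "yes"

    def test_case_and_whitespace_normalized(self):
        ds = make_ds({"rbc": ["Normal ", "abnormal"]},
                     [ColumnMeta("rbc", NOMINAL, ("normal", "abnormal"))],
                     [0, 1])
        out = validate_categories(ds, fit_preprocessor(ds))
        assert out.X["rbc"].iloc[0] == "normal"


class TestOutlierRemoval:
    def test_cell_at_mean_is_retained(self):
        ds = make_ds({"bu": [5.0, 5.0, 5.0]}, [ColumnMeta("bu", NUMERIC)],
                     [0, 1, 0])
        out = remove_numeric_outliers(ds, fit_preprocessor(ds), 3.0)
        assert out.n_samples == 3

    def test_extreme_cell_drops_the_row(self):
        # training stats fitted elsewhere: mu=0, sigma=1
        vals = np.array([-1.0, 0.0, 1.0, 3.5])
        ds = make_ds({"bu": vals / vals.std()},
                     [ColumnMeta("bu", NUMERIC)], [0, 1, 0, 1])
        st = fit_preprocessor(ds)
        # rescale so the last cell sits beyond 3 sigma
        z = np.abs(ds.X["bu"] - st.means["bu"]) / st.sds["bu"]
        out = remove_numeric_outliers(ds, st, z_cut=float(z.iloc[-1]) - 0.1)
        assert out.n_samples == 3

    def test_clean_data_unchanged(self, small_ds):
        st = fit_preprocessor(small_ds)
        out = remove_numeric_outliers(small_ds, st, z_cut=10.0)
        assert out.n_samples == small_ds.n_samples


class TestSmote:
    def test_synthetic_rows_are_minority_and_flagged(self, small_ds):
        out = smote_oversample(small_ds, SmoteConfig(seed=1))
        counts = np.bincount(out.y)
        assert counts[0] == counts[1]
        minority = np.argmin(np.bincount(small_ds.y))
        assert (out.y[out.synthetic] == minority).all()
        assert not out.synthetic[:small_ds.n_samples].any()

    def test_interpolation_stays_in_minority_convex_hull(self, small_ds):
        out = smote_oversample(small_ds, SmoteConfig(seed=2))
        minority = np.argmin(np.bincount(small_ds.y))
        st = fit_preprocessor(small_ds)
        for c in small_ds.numeric_columns():
            parents = small_ds.X[c][small_ds.y == minority].to_numpy(float)
            parents = np.where(np.isnan(parents), st.medians[c], parents)
            new = out.X[c][out.synthetic].to_numpy(float)
            assert new.min() >= parents.min() - 1e-12
            assert new.max() <= parents.max() + 1e-12

    def test_nominal_cells_copied_from_allowed_set(self, small_ds):
        out = smote_oversample(small_ds, SmoteConfig(seed=3))
        for c in out.col_meta:
            if c.kind == NOMINAL:
                vals = out.X[c.name][out.synthetic]
                assert vals.isin(c.categories).all()

    def test_minority_too_small_suggests_smaller_k(self):
        ds = make_ds({"bu": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
                     [ColumnMeta("bu", NUMERIC)], [1, 1, 1, 1, 0, 0])
        with pytest.raises(ValueError, match="smaller k"):
            smote_oversample(ds, SmoteConfig(k_neighbors=5))


class TestTransform:
    def test_training_fold_standardized_exactly(self, small_ds):
        st = fit_preprocessor(small_ds)
        enc = transform(small_ds, st)
        for c in small_ds.numeric_columns():
            vals = enc.X[c].to_numpy(float)
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.std(ddof=0) - 1.0) < 1e-10

    def test_heldout_uses_training_statistics(self):
        train = make_ds({"bu": [0.0, 2.0]}, [ColumnMeta("bu", NUMERIC)],
                        [0, 1])
        test = make_ds({"bu": [5.0, 5.0]}, [ColumnMeta("bu", NUMERIC)],
                       [0, 1])
        st = fit_preprocessor(train)
        enc = transform(test, st)
        np.testing.assert_allclose(enc.X["bu"], (5.0 - 1.0) / 1.0)

    def test_missing_numeric_maps_to_training_median(self):
        train = make_ds({"bu": [1.0, 2.0, 3.0]}, [ColumnMeta("bu", NUMERIC)],
                        [0, 1, 0])
        test = make_ds({"bu": [np.nan]}, [ColumnMeta("bu", NUMERIC)], [1])
        st = fit_preprocessor(train)
        enc = transform(test, st)
        expected = (st.medians["bu"] - st.means["bu"]) / st.sds["bu"]
        np.testing.assert_allclose(enc.X["bu"].iloc[0], expected)

    def test_one_hot_groups_carry_origin(self, small_ds):
        st = fit_preprocessor(small_ds)
        enc = transform(small_ds, st)
        origin = np.asarray(enc.origin)
        assert origin.max() == small_ds.n_features - 1
        for j, c in enumerate(small_ds.col_meta):
            width = 1 if c.kind == NUMERIC else len(c.categories)
            assert (origin == j).sum() == width


def test_leakage_guard_heldout_cannot_touch_fitted_state(small_ds):
    """Replacing every held-out cell with extreme values must change no
    fitted statistic and no transformed training value."""
    train = small_ds.subset(np.arange(0, 100))
    test = small_ds.subset(np.arange(100, 150))
    tr_a, te_a, st_a = preprocess_fold(train, test)

    corrupted = test.copy()
    for c in corrupted.col_meta:
        if c.kind == NUMERIC:
            corrupted.X[c.name] = 1e9
        else:
            corrupted.X[c.name] = c.categories[0]
    tr_b, te_b, st_b = preprocess_fold(train, corrupted)

    assert st_a.to_dict() == st_b.to_dict()
    pd.testing.assert_frame_equal(tr_a.X, tr_b.X)


def test_state_round_trips_through_dict(small_ds):
    st = fit_preprocessor(small_ds)
    from spiralselect.preprocess import PreprocessorState
    back = PreprocessorState.from_dict(st.to_dict())
    assert back.to_dict() == st.to_dict()


def test_fold_pipeline_keeps_test_free_of_synthetic_rows(small_ds):
    train = small_ds.subset(np.arange(0, 100))
    test = small_ds.subset(np.arange(100, 150))
    tr_enc, te_enc, _ = preprocess_fold(train, test, PreprocessConfig())
    assert tr_enc.synthetic.any()
    assert not te_enc.synthetic.any()
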