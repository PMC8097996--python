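"""Feature engineering: variability summaries, clinical flags, padding."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwsurf import (
    LabSeries,
    build_feature_matrix,
    compute_nlr,
    count_hypoglycemia,
    flag_anemia,
    flag_iron_deficiency,
    pad_missing,
    summarize_variability,
)
from rwsurf.features import feature_columns

WINDOW = (pd.Timestamp("2004-01-01"), pd.Timestamp("2008-12-31"))


def series(values, analyte="hba1c", start="2004-06-01"):
    dates = pd.date_range(start, periods=len(values), freq="90D")
    return LabSeries("p1", analyte, dates.to_numpy(), np.asarray(values, float))


class TestVariability:
    def test_constant_series(self):
        s = summarize_variability(series([8.0, 8.0, 8.0]), WINDOW)
        assert s.eligible
        assert s.sd == 0.0 and s.cv == 0.0

    def test_hand_computed_sd_and_cv(self):
        # sample SD of (7, 8, 9) is 1; CV = 100 * 1 / 8 = 12.5
        s = summarize_variability(series([7.0, 8.0, 9.0]), WINDOW)
        assert s.mean == pytest.approx(8.0)
        assert s.sd == pytest.approx(1.0)
        assert s.cv == pytest.approx(12.5)
        assert s.baseline == 7.0

    def test_two_measurements_not_eligible(self):
        s = summarize_variability(series([7.0, 9.0]), WINDOW)
        assert not s.eligible
        assert math.isnan(s.cv) and math.isnan(s.sd) and math.isnan(s.mean)
        assert s.baseline == 7.0  # earliest value survives

    def test_empty_window(self):
        s = summarize_variability(series([7.0, 8.0, 9.0], start="2010-01-01"), WINDOW)
        assert s.n_measurements == 0 and not s.eligible
        assert math.isnan(s.baseline)

    def test_out_of_window_values_excluded(self):
        dates = ["2003-01-01", "2004-02-01", "2005-02-01", "2006-02-01"]
        s = LabSeries("p", "hba1c", np.array(dates, dtype="datetime64[D]"), np.array([99.0, 7.0, 8.0, 9.0]))
        summ = summarize_variability(s, WINDOW)
        assert summ.n_measurements == 3
        assert summ.mean == pytest.approx(8.0)

    @given(st.lists(st.floats(1.0, 50.0), min_size=3, max_size=12),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_cv_scale_invariant(self, values, c):
        base = summarize_variability(series(values), WINDOW)
        scaled = summarize_variability(series([c * v for v in values]), WINDOW)
        assert scaled.sd == pytest.approx(c * base.sd, rel=1e-9, abs=1e-9)
        assert scaled.cv == pytest.approx(base.cv, rel=1e-9, abs=1e-9)

    @given(st.lists(st.floats(1.0, 50.0), min_size=3, max_size=10), st.randoms())
    @settings(max_examples=30, deadline=None)
    def test_order_free_statistics(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        a = summarize_variability(series(values), WINDOW)
        # same dates, permuted values: mean/sd/cv unchanged
        b = summarize_variability(series(shuffled), WINDOW)
        assert b.mean == pytest.approx(a.mean, rel=1e-12)
        assert b.sd == pytest.approx(a.sd, rel=1e-9, abs=1e-12)


class TestClinicalFlags:
    def test_hypoglycemia_strict_threshold(self):
        s = series([5.1, 3.8, 3.9, 2.9], analyte="glucose")
        assert count_hypoglycemia(s) == 2  # 3.9 itself does not count

    def test_hypoglycemia_empty_and_none_below(self):
        assert count_hypoglycemia(series([], analyte="glucose")) == 0
        assert count_hypoglycemia(series([4.0, 5.0, 3.9], analyte="glucose")) == 0

    def test_nlr_division(self):
        assert compute_nlr(5.47, 1.87) == pytest.approx(2.925, abs=1e-3)
        assert compute_nlr(0.0, 1.0) == 0.0
        assert math.isnan(compute_nlr(4.0, 0.0))
        with pytest.raises(ValueError):
            compute_nlr(-1.0, 2.0)

    @pytest.mark.parametrize("hb,sex,expected", [
        (12.5, "male", True),    # below the male threshold of 13
        (13.0, "male", False),   # boundary, strict
        (12.0, "female", False),  # boundary, strict
        (11.9, "female", True),
    ])
    def test_anemia_thresholds(self, hb, sex, expected):
        assert flag_anemia(hb, sex) is expected

    def test_anemia_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            flag_anemia(12.0, "other")

    @pytest.mark.parametrize("ferritin,expected", [(67.4, False), (10.0, True), (200.0, False)])
    def test_iron_deficiency_strict(self, ferritin, expected):
        assert flag_iron_deficiency(ferritin) is expected


def toy_cohort():
    rows = []
    # patient a: 3 HbA1c values, full bloods
    for d, v in [("2004-05-01", 7.0), ("2005-05-01", 8.0), ("2006-05-01", 9.0)]:
        rows.append(("a", "hba1c", d, v))
    rows += [
        ("a", "glucose", "2005-01-01", 3.5),
        ("a", "glucose", "2005-06-01", 4.5),
        ("a", "neutrophil", "2004-02-01", 6.0),
        ("a", "lymphocyte", "2004-02-01", 2.0),
        ("a", "hemoglobin", "2004-03-01", 12.5),
        ("a", "ferritin", "2004-03-01", 30.0),
    ]
    # patient b: only 2 HbA1c values, no ferritin
    rows += [
        ("b", "hba1c", "2004-05-01", 6.5),
        ("b", "hba1c", "2005-05-01", 7.5),
        ("b", "hemoglobin", "2004-03-01", 14.0),
    ]
    # patient c: nothing but lipids
    rows += [(f"c", "hdl_c", d, v) for d, v in
             [("2004-01-05", 1.0), ("2005-01-05", 1.2), ("2006-01-05", 1.4), ("2007-01-05", 1.1)]]
    labs = pd.DataFrame(rows, columns=["patient_id", "analyte", "date", "value"])
    baseline = pd.DataFrame({
        "patient_id": ["a", "b", "c"],
        "age": [60.0, 70.0, 55.0],
        "sex": ["male", "female", "male"],
        "biguanide": [1, 0, 1],
    })
    return labs, baseline


class TestBuildMatrix:
    def test_documented_columns_and_shape(self):
        labs, baseline = toy_cohort()
        fm = build_feature_matrix(labs, baseline, WINDOW)
        assert list(fm.frame.columns) == feature_columns(["biguanide"])
        assert len(fm.frame) == 3

    def test_eligibility_applies_per_parameter(self):
        labs, baseline = toy_cohort()
        fm = build_feature_matrix(labs, baseline, WINDOW)
        b = fm.frame.loc["b"]
        assert math.isnan(b["hba1c_sd"]) and math.isnan(b["hba1c_cv"])
        assert b["hba1c_baseline"] == 6.5

    def test_missing_input_gives_missing_flag_not_false(self):
        labs, baseline = toy_cohort()
        fm = build_feature_matrix(labs, baseline, WINDOW)
        assert math.isnan(fm.frame.loc["b", "iron_deficiency"])
        assert fm.frame.loc["a", "iron_deficiency"] == 1.0  # ferritin 30 < 67.4
        assert fm.frame.loc["a", "anemia"] == 1.0  # male, hb 12.5 < 13

    def test_nlr_and_hypoglycemia(self):
        labs, baseline = toy_cohort()
        fm = build_feature_matrix(labs, baseline, WINDOW)
        assert fm.frame.loc["a", "nlr"] == pytest.approx(3.0)
        assert fm.frame.loc["a", "hypoglycemia_count"] == 1

    def test_duplicate_patient_ids_rejected(self):
        labs, baseline = toy_cohort()
        dup = pd.concat([baseline, baseline.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate patient id"):
            build_feature_matrix(labs, dup, WINDOW)

    def test_unknown_analyte_rejected_naming_row(self):
        labs, baseline = toy_cohort()
        labs.loc[len(labs)] = ("a", "mystery", "2004-01-01", 1.0)
        with pytest.raises(ValueError, match="mystery"):
            build_feature_matrix(labs, baseline, WINDOW)


class TestPadding:
    def test_missing_becomes_minus_one_with_mask(self):
        labs, baseline = toy_cohort()
        fm = build_feature_matrix(labs, baseline, WINDOW)
        padded = pad_missing(fm)
        assert padded.frame.loc["b", "hba1c_sd"] == -1.0
        assert padded.mask.loc["b", "hba1c_sd"]
        assert np.isfinite(padded.frame.to_numpy()).all()

    def test_no_missingness_unchanged(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        from rwsurf.features import FeatureMatrix
        fm = FeatureMatrix(frame=frame, mask=frame.isna())
        padded = pad_missing(fm)
        pd.testing.assert_frame_equal(padded.frame, frame)

    def test_fully_missing_row_is_all_minus_one(self):
        frame = pd.DataFrame({"a": [np.nan], "b": [np.nan]})
        from rwsurf.features import FeatureMatrix
        fm = FeatureMatrix(frame=frame, mask=frame.isna())
        assert (pad_missing(fm).frame.iloc[0] == -1.0).all()
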