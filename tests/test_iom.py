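"""WHO categorisation, IOM window projection, gain classification, transitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gwgtraj import iom
from gwgtraj.iom import (
    BMICategory,
    ExclusionError,
    classify_cohort,
    classify_gain,
    gdm_from_glucose,
    projected_window,
    transition_table,
    who_category,
)


class TestWHOCategory:
    @pytest.mark.parametrize(
        "ppbmi, expected",
        [
            (17.0, BMICategory.UNDERWEIGHT),
            (18.499, BMICategory.UNDERWEIGHT),
            (18.5, BMICategory.NORMAL),
            (24.9, BMICategory.NORMAL),
            (25.0, BMICategory.OVERWEIGHT),
            (29.99, BMICategory.OVERWEIGHT),
            (30.0, BMICategory.OBESE),
            (45.0, BMICategory.OBESE),
        ],
    )
    def test_boundaries(self, ppbmi, expected):
        assert who_category(ppbmi) is expected

    @pytest.mark.parametrize("bad", [0.0, -3.0, float("nan"), float("inf")])
    def test_rejects_nonpositive_or_nonfinite(self, bad):
        with pytest.raises(ValueError):
            who_category(bad)

    @given(st.floats(min_value=10, max_value=60))
    def test_vector_agrees_with_scalar(self, ppbmi):
        assert iom.who_category_vector(np.array([ppbmi]))[0] is who_category(ppbmi)


class TestProjectedWindow:
    def test_term_recovers_total_window(self):
        # at 40 weeks the projection is exactly the recommended total range
        assert projected_window(BMICategory.NORMAL, 40) == (11.5, 16.0)
        assert projected_window(BMICategory.UNDERWEIGHT, 40) == (12.5, 18.0)
        assert projected_window(BMICategory.OVERWEIGHT, 40) == (7.0, 11.5)
        assert projected_window(BMICategory.OBESE, 40) == (5.0, 9.0)

    def test_hand_interpolation_midpregnancy(self):
        lo, hi = projected_window(BMICategory.NORMAL, 26.5)
        assert lo == pytest.approx(0.5 + 11 * 13.5 / 27)
        assert hi == pytest.approx(2.0 + 14 * 13.5 / 27)
        assert (lo, hi) == pytest.approx((6.0, 9.0))

    def test_anchor_at_end_of_first_trimester(self):
        assert projected_window(BMICategory.OBESE, 13) == (0.5, 2.0)

    def test_rate_mode_linear_in_ga(self):
        lo, hi = projected_window(BMICategory.NORMAL, 23, mode="rate")
        assert lo == pytest.approx(0.5 + 0.35 * 10)
        assert hi == pytest.approx(2.0 + 0.50 * 10)

    @pytest.mark.parametrize("ga", [12.9, 42.1, -1])
    def test_out_of_range_ga(self, ga):
        with pytest.raises(ValueError):
            projected_window(BMICategory.NORMAL, ga)

    @given(
        st.sampled_from(list(BMICategory)),
        st.floats(min_value=13, max_value=41),
        st.floats(min_value=0.2, max_value=1.0),
        st.sampled_from(["interpolation", "rate"]),
    )
    def test_window_widens_with_ga(self, cat, ga, dt, mode):
        lo1, hi1 = projected_window(cat, ga, mode=mode)
        lo2, hi2 = projected_window(cat, min(ga + dt, 42), mode=mode)
        assert hi2 - lo2 >= hi1 - lo1 - 1e-12

    @given(st.floats(min_value=14, max_value=42))
    def test_heavier_categories_have_lower_windows(self, ga):
        windows = [projected_window(c, ga) for c in iom.CATEGORY_ORDER]
        los, his = zip(*windows)
        assert all(a > b for a, b in zip(los, los[1:]))
        assert all(a > b for a, b in zip(his, his[1:]))


def _record(prepreg, ppbmi, visits):
    return {"pre_pregnancy_weight": prepreg, "ppbmi": ppbmi, "visits": visits}


class TestClassifyGain:
    def test_high_gain_third_trimester(self):
        rec = _record(60.0, 22.0, [(28, 72.0)])
        c = classify_gain(rec, "T3")
        assert c.window_at_ga == pytest.approx((6.611, 9.778), abs=1e-3)
        assert c.label == "H" and c.observed_gain == pytest.approx(12.0)

    def test_gain_on_bounds_is_within(self):
        # term bounds 11.5 and 16.0 kg are exactly representable
        assert classify_gain(_record(60.0, 22.0, [(40, 76.0)]), "T3").label == "N"
        assert classify_gain(_record(60.0, 22.0, [(40, 71.5)]), "T3").label == "N"

    def test_low_gain_underweight_late_t2(self):
        rec = _record(45.0, 17.5, [(27, 48.0)])
        c = classify_gain(rec, "T2")
        assert c.window_at_ga == pytest.approx(
            (0.5 + 12 * 14 / 27, 2 + 16 * 14 / 27), abs=1e-3
        )
        assert c.label == "L"

    def test_latest_visit_in_trimester_used(self):
        rec = _record(60.0, 22.0, [(15, 61.0), (26, 66.0)])
        assert classify_gain(rec, "T2").ga_weeks == 26

    def test_missing_data_raises_exclusion(self):
        with pytest.raises(ExclusionError):
            classify_gain(_record(float("nan"), 22.0, [(30, 70)]), "T3")
        with pytest.raises(ExclusionError):
            classify_gain(_record(60.0, 22.0, [(15, 61.0)]), "T3")

    def test_at_term_equals_total_window_rule(self):
        # classification of total gain at 40 weeks is the pure total-window rule
        for gain, expect in [(11.0, "L"), (13.0, "N"), (16.0, "N"), (16.5, "H")]:
            rec = _record(60.0, 22.0, [(40, 60.0 + gain)])
            assert classify_gain(rec, "T3").label == expect

    @given(
        st.floats(min_value=-5, max_value=25),
        st.floats(min_value=0.1, max_value=5),
        st.one_of(st.floats(min_value=16, max_value=27),
                  st.floats(min_value=28, max_value=40)),
        st.floats(min_value=15, max_value=40),
    )
    def test_monotone_in_gain(self, gain, extra, ga, ppbmi):
        order = {"L": 0, "N": 1, "H": 2}
        tri = "T2" if ga <= 27 else "T3"
        a = classify_gain(_record(60.0, ppbmi, [(ga, 60 + gain)]), tri)
        b = classify_gain(_record(60.0, ppbmi, [(ga, 60 + gain + extra)]), tri)
        assert order[b.label] >= order[a.label]


class TestClassifyCohort:
    def test_matches_scalar_classifier(self):
        df = pd.DataFrame({
            "id": ["a", "b"],
            "pre_pregnancy_weight": [60.0, 80.0],
            "ppbmi": [22.0, 31.0],
            "ga_t1": [10, 11], "wt_t1": [62.0, 82.0],
            "ga_t2": [22, 24], "wt_t2": [68.0, 85.0],
            "ga_t3": [34, 33], "wt_t3": [74.0, 88.0],
        })
        out = classify_cohort(df)
        for i, row in df.iterrows():
            rec = _record(row.pre_pregnancy_weight, row.ppbmi,
                          [(row.ga_t2, row.wt_t2), (row.ga_t3, row.wt_t3)])
            assert out.loc[i, "t2_label"] == classify_gain(rec, "T2").label
            assert out.loc[i, "t3_label"] == classify_gain(rec, "T3").label

    def test_missing_ppbmi_flagged_excluded(self):
        df = pd.DataFrame({
            "id": ["a"], "pre_pregnancy_weight": [60.0], "ppbmi": [np.nan],
            "ga_t1": [10], "wt_t1": [61.0], "ga_t2": [22], "wt_t2": [66.0],
            "ga_t3": [34], "wt_t3": [72.0],
        })
        out = classify_cohort(df)
        assert out.loc[0, "t3_label"] is None
        assert "missing" in out.loc[0, "exclusion"]


class TestTransitionTable:
    def test_printed_count_arithmetic(self):
        # 2270 stayed above, 616 normalised, of 5109 women with both labels
        t2 = ["H"] * 2886 + ["N"] * 1488 + ["L"] * 735
        t3 = (["H"] * 2270 + ["N"] * 569 + ["L"] * 47
              + ["H"] * 357 + ["N"] * 1131
              + ["L"] * 735)
        tt = transition_table(t2, t3)
        assert tt.n == 5109
        h = tt.strata["T2H"]
        assert h["stayed"]["n"] == 2270
        assert h["stayed"]["pct_of_total"] == pytest.approx(44.4, abs=0.05)
        assert h["changed"]["n"] == 616
        assert h["changed"]["pct_of_total"] == pytest.approx(12.06, abs=0.01)
        assert h["changed"]["pct_of_row"] == pytest.approx(21.3, abs=0.05)
        n = tt.strata["T2N"]
        assert n["stayed"]["pct_of_row"] == pytest.approx(76.0, abs=0.05)
        assert n["changed"]["n"] == 357

    def test_degenerate_all_normal(self):
        tt = transition_table(["N"] * 7, ["N"] * 7)
        assert tt.cell("N", "N") == 7 and tt.counts.to_numpy().sum() == 7
        assert tt.strata["T2H"]["row_total"] == 0

    def test_uniform_cells_give_even_strata(self):
        t2 = [a for a in "LNH" for _ in "LNH"]
        t3 = [b for _ in "LNH" for b in "LNH"]
        tt = transition_table(t2, t3)
        assert (tt.counts.to_numpy() == 1).all()
        assert tt.strata["T2H"]["stayed"]["pct_of_row"] == pytest.approx(100 / 3)

    def test_counts_partition_input(self, small_cohort):
        cls = classify_cohort(small_cohort)
        both = cls.dropna(subset=["t2_label", "t3_label"])
        tt = transition_table(both["t2_label"], both["t3_label"])
        assert tt.n == len(both)
        assert tt.counts.to_numpy().sum() == len(both)


class TestGDMRule:
    @pytest.mark.parametrize(
        "gct, ogtt, expected",
        [
            (10.3, None, True),
            (11.0, None, True),
            (7.7, None, False),
            (5.0, None, False),
            (8.0, (5.3, 9.0, 8.0), True),   # fasting meets its threshold
            (8.0, (5.2, 10.6, 8.0), True),  # 1 h value meets its threshold
            (8.0, (5.2, 10.5, 9.0), True),  # 2 h value meets its threshold
            (8.0, (5.2, 10.5, 8.9), False),
            (10.2, (4.0, 5.0, 5.0), False),
        ],
    )
    def test_decision_rule(self, gct, ogtt, expected):
        assert gdm_from_glucose(gct, ogtt) is expected

    def test_indeterminate_without_ogtt(self):
        assert gdm_from_glucose(9.0) is None

    def test_invalid_gct(self):
        with pytest.raises(ValueError):
            gdm_from_glucose(float("nan"))
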