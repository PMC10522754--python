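"""CA19-9 trajectory rules, HbA1c / enzyme elevation, Lewis flag."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipmnsurv import (MarkerRuleConfig, classify_ca19_9_trajectory,
                      classify_cohort, cumulative_average,
                      detect_enzyme_elevation, detect_hba1c_elevation,
                      elevation_lead_time, flag_lewis_negative)
from ipmnsurv.cohort import DAYS_PER_YEAR

from conftest import make_series
from _oracles import oracle_classify_ca19_9, oracle_enzyme

Y = DAYS_PER_YEAR


class TestCumulativeAverage:
    def test_mean_of_strict_prefix(self):
        s = make_series("ca19_9", [0, 1, 2], [10, 20, 30])
        assert cumulative_average(s, 2) == pytest.approx(15)

    def test_constant_series(self):
        s = make_series("ca19_9", [0, 100, 200], [7, 7, 7])
        assert cumulative_average(s, 150) == pytest.approx(7)

    def test_undefined_before_first_point(self):
        s = make_series("ca19_9", [10, 20], [5, 6])
        assert cumulative_average(s, 10) is None


class TestTrajectoryClassification:
    def test_first_crossing_in_window_is_aberrant(self):
        dx = 10 * Y
        s = make_series("ca19_9", [dx - 3 * Y, dx - 1.5 * Y, dx - 0.3 * Y],
                        [10, 12, 50])
        c = classify_ca19_9_trajectory(s, dx)
        assert c.pattern == "aberrant_elevation"
        assert c.trigger == "above_uln_first_time"
        assert c.first_elevation_years == pytest.approx(0.3)

    def test_always_normal_is_low_to_low(self):
        dx = 5 * Y
        s = make_series("ca19_9", [0, 2 * Y, dx - 0.2 * Y], [10, 30, 36.9])
        assert classify_ca19_9_trajectory(s, dx).pattern == "low_to_low"

    def test_elevated_baseline_without_doubling_is_high_to_high(self):
        dx = 5 * Y
        days = np.arange(0, dx + 1, Y / 2)
        vals = 80 + 10 * np.sin(np.arange(len(days)))  # oscillates 70-90
        s = make_series("ca19_9", days, vals)
        assert classify_ca19_9_trajectory(s, dx).pattern == "high_to_high"

    def test_doubling_of_cumulative_average_triggers(self):
        dx = 4 * Y
        # baseline 50, average drifts near 55, in-window 120 >= 2 x cumavg
        s = make_series("ca19_9", [0, Y, 2 * Y, dx - 0.4 * Y],
                        [50, 55, 60, 120])
        c = classify_ca19_9_trajectory(s, dx)
        assert c.pattern == "aberrant_elevation"
        assert c.trigger == "doubling_of_cumavg"
        assert c.first_elevation_years == pytest.approx(0.4)

    def test_no_in_window_data_is_insufficient(self):
        dx = 5 * Y
        s = make_series("ca19_9", [0, Y, 2 * Y], [10, 12, 14])
        assert classify_ca19_9_trajectory(s, dx).pattern == "insufficient_data"

    def test_wrong_analyte_rejected(self):
        s = make_series("hba1c", [0], [6.0])
        with pytest.raises(ValueError, match="ca19_9"):
            classify_ca19_9_trajectory(s, 365.0)


# coarse grids for exhaustive oracle comparison
_VALUE_GRID = [10.0, 37.0, 38.0, 120.0]
_DAY_GRIDS = {
    1: [[800.0]],
    2: [[100.0, 800.0], [700.0, 900.0]],
    3: [[100.0, 500.0, 900.0], [600.0, 800.0, 1000.0]],
}


def test_classifier_agrees_with_bruteforce_oracle_exhaustively():
    """Exhaustive agreement on all short series over a coarse value grid."""
    dx = 1000.0
    n_checked = 0
    for length, day_sets in _DAY_GRIDS.items():
        for days in day_sets:
            for values in itertools.product(_VALUE_GRID, repeat=length):
                s = make_series("ca19_9", days, values)
                got = classify_ca19_9_trajectory(s, dx)
                want_pattern, want_lead, want_trigger = \
                    oracle_classify_ca19_9(days, values, dx)
                assert got.pattern == want_pattern, (days, values)
                if want_pattern == "aberrant_elevation":
                    assert got.trigger == want_trigger, (days, values)
                    assert got.first_elevation_years == pytest.approx(want_lead)
                n_checked += 1
    assert n_checked == 164  # 4 + 2*16 + 2*64 grid combinations


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([5.0, 20.0, 37.0, 40.0, 75.0, 150.0, 300.0]),
                min_size=1, max_size=6),
       st.integers(0, 10 ** 6))
def test_classifier_agrees_with_oracle_on_random_series(values, day_seed):
    rng = np.random.default_rng(day_seed)
    dx = 1200.0
    days = np.sort(rng.choice(np.arange(0, 1201, 50), size=len(values),
                              replace=False)).astype(float)
    s = make_series("ca19_9", days, values)
    got = classify_ca19_9_trajectory(s, dx)
    want_pattern, _, _ = oracle_classify_ca19_9(days, values, dx)
    assert got.pattern == want_pattern


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6), st.floats(0.1, 50.0))
def test_partition_and_scale_invariance(seed, scale):
    """Exactly one pattern; multiplying values and ULN rescales nothing."""
    rng = np.random.default_rng(seed)
    n = rng.integers(1, 9)
    days = np.sort(rng.choice(np.arange(0, 2001, 25), size=n, replace=False))
    values = rng.uniform(1, 200, size=n)
    dx = 2000.0
    s = make_series("ca19_9", days, values)
    c = classify_ca19_9_trajectory(s, dx)
    assert c.pattern in ("aberrant_elevation", "high_to_high", "low_to_low",
                         "residual_unclassified", "insufficient_data")
    if c.pattern == "low_to_low":
        assert values.max() <= 37.0
    cfg = MarkerRuleConfig(ca19_9_uln=37.0 * scale)
    s2 = make_series("ca19_9", days, values * scale)
    assert classify_ca19_9_trajectory(s2, dx, cfg).pattern == c.pattern


def test_raising_an_aberrant_value_keeps_aberrant():
    dx = 1000.0
    days = [100.0, 600.0, 900.0]
    values = np.array([10.0, 12.0, 50.0])
    base = classify_ca19_9_trajectory(make_series("ca19_9", days, values), dx)
    assert base.pattern == "aberrant_elevation"
    for bump in (1.0, 10.0, 500.0):
        values2 = values.copy()
        values2[2] += bump
        c = classify_ca19_9_trajectory(make_series("ca19_9", days, values2), dx)
        assert c.pattern == "aberrant_elevation"


class TestHbA1c:
    def test_mmol_mol_increase_detected(self):
        dx = 3 * Y
        s = make_series("hba1c", [0, Y, 2 * Y, dx - 50], [42, 42, 42, 47],
                        unit="mmol/mol")
        det = detect_hba1c_elevation(s, dx)
        assert det.elevated

    def test_stable_percent_not_detected(self):
        dx = 3 * Y
        s = make_series("hba1c", [0, Y, 2 * Y, dx - 50],
                        [6.0, 6.0, 6.0, 6.0])
        assert not detect_hba1c_elevation(s, dx).elevated

    def test_percent_jump_converted_via_ifcc_master_equation(self):
        # 6.0 % -> 42.08 mmol/mol; 6.4 % -> 46.45; delta = 4.372 >= 4
        dx = 3 * Y
        s = make_series("hba1c", [0, Y, 2 * Y, dx - 50],
                        [6.0, 6.0, 6.0, 6.4])
        det = detect_hba1c_elevation(s, dx)
        assert det.elevated
        assert det.first_elevation_years == pytest.approx(50 / Y)

    def test_sub_threshold_percent_jump_not_detected(self):
        dx = 3 * Y
        s = make_series("hba1c", [0, Y, dx - 50], [6.0, 6.0, 6.3])
        assert not detect_hba1c_elevation(s, dx).elevated  # 3.3 mmol/mol


class TestEnzymes:
    def test_large_lipase_spike_detected(self):
        dx = 2 * Y
        lip = make_series("lipase", [0, Y, dx - 100], [40, 40, 500])
        det = detect_enzyme_elevation({"lipase": lip}, dx)
        assert det.elevated and det.analyte == "lipase"
        assert det.first_elevation_years == pytest.approx(100 / Y)

    def test_below_triple_uln_not_detected(self):
        dx = 2 * Y
        lip = make_series("lipase", [0, Y, dx - 100], [40, 40, 150])
        assert not detect_enzyme_elevation({"lipase": lip}, dx).elevated

    def test_triple_uln_without_doubling_not_detected(self):
        dx = 2 * Y
        # 3.5 x ULN of 50 = 175, but cumulative average 100 -> only 1.75x
        pam = make_series("p_amylase", [0, Y, dx - 100], [100, 100, 175])
        assert not detect_enzyme_elevation({"p_amylase": pam}, dx).elevated

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_agrees_with_conjunct_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dx = 1000.0
        n = rng.integers(1, 7)
        days = np.sort(rng.choice(np.arange(0, 1001, 40), size=n,
                                  replace=False)).astype(float)
        values = rng.uniform(10, 400, size=n)
        lip = make_series("lipase", days, values)
        got = detect_enzyme_elevation({"lipase": lip}, dx)
        want, want_lead = oracle_enzyme(days, values, dx, uln=60.0)
        assert got.elevated == want
        if want:
            assert got.first_elevation_years == pytest.approx(want_lead)


class TestLeadTime:
    def test_days_to_years_conversion(self):
        dx = 1000.0
        s = make_series("ca19_9", [100, dx - 146], [10, 80])
        c = classify_ca19_9_trajectory(s, dx)
        assert round(elevation_lead_time(c), 1) == 0.4

    def test_elevation_on_diagnosis_day_is_zero(self):
        dx = 1000.0
        s = make_series("ca19_9", [100, dx], [10, 80])
        assert elevation_lead_time(classify_ca19_9_trajectory(s, dx)) == 0.0

    def test_contract_violation_for_non_elevated(self):
        dx = 1000.0
        s = make_series("ca19_9", [100, dx], [10, 20])
        with pytest.raises(ValueError):
            elevation_lead_time(classify_ca19_9_trajectory(s, dx))


class TestLewisNegative:
    def test_all_values_at_detection_limit(self):
        s = make_series("ca19_9", [0, 100, 200], [1, 1, 2], detection_limit=2)
        assert flag_lewis_negative(s)

    def test_any_real_value_clears_flag(self):
        s = make_series("ca19_9", [0, 100], [1, 15], detection_limit=2)
        assert not flag_lewis_negative(s)

    def test_requires_detection_limit(self):
        s = make_series("ca19_9", [0], [1])
        with pytest.raises(ValueError):
            flag_lewis_negative(s)


def test_lewis_exclusion_does_not_change_retained_patterns(small_cohort):
    """Sensitivity analysis: dropping Lewis-negative patients leaves every
    retained patient's trajectory assignment untouched."""
    records, _, _ = small_cohort
    full = classify_cohort(records).set_index("patient_id")
    kept = [r for r in records
            if r.diagnosis is None
            or not full.loc[r.patient_id, "lewis_negative_flag"]]
    sub = classify_cohort(kept).set_index("patient_id")
    assert (full.loc[sub.index, "pattern"] == sub["pattern"]).all()
    assert len(sub) < len(full)  # the generator plants Lewis-negative cases
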