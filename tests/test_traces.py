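"""Trace loading, phase detection, event pressures, normalization, groups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microconstrict import (
    DeformationTrace,
    SchemaError,
    compare_groups,
    detect_phases,
    extract_critical_pressures,
    load_trace,
    normalize_pressures,
    save_trace,
    spindle_metrics,
)
from microconstrict.traces import (
    DegenerateNormalizationError,
    FeatureUnavailableError,
    fold_angle,
)

from conftest import make_trace


# ----------------------------------------------------------------- schema


def test_save_load_roundtrip(tmp_path):
    tr = make_trace([0, 1, 2], [0, 0.1, 0.2], [-5, 0, 5], [-75, -70, -65])
    path = save_trace(tr, tmp_path / "cell.csv")
    back = load_trace(path)
    assert len(back) == 3
    assert back.metadata["oocyte_id"] == "t-000"
    np.testing.assert_allclose(back.data["x_front_um"], tr.data["x_front_um"])


def test_missing_column_named():
    df = pd.DataFrame({"time_s": [0, 1], "pressure_mbar": [0, 0.1],
                       "x_front_um": [-1, 0], "x_rear_um": [-70, -69]})
    with pytest.raises(SchemaError, match="aspect_ratio"):
        DeformationTrace(data=df, metadata={"d_um": 50.0})


def test_time_reversal_cites_row():
    with pytest.raises(SchemaError, match="row 2"):
        make_trace([0, 1, 0.5, 2], [0, 0, 0, 0], [-5, -4, -3, -2], [-75, -74, -73, -72])


def test_front_behind_rear_rejected():
    with pytest.raises(SchemaError, match="x_front"):
        make_trace([0, 1], [0, 0], [-80, -79], [-75, -74])


def test_missing_d_metadata():
    df = pd.DataFrame({"time_s": [0, 1], "pressure_mbar": [0, 0.1],
                       "x_front_um": [-1, 0], "x_rear_um": [-70, -69],
                       "aspect_ratio": [1.0, 1.0]})
    with pytest.raises(SchemaError, match="d_um"):
        DeformationTrace(data=df, metadata={})


# ----------------------------------------------------------------- phases


def test_all_approach_sets_no_entry_flag():
    tr = make_trace([0, 1, 2], [0, 0.1, 0.2], [-30, -20, -10], [-100, -95, -90])
    seg = detect_phases(tr)
    assert seg.no_entry
    assert set(seg.labels) == {"approach"}


def test_phase_boundaries_on_constructed_trace():
    # rear frozen for 3 frames after entry, then moves by 2 um
    t = np.arange(8.0)
    xf = np.array([-10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0, 25.0])
    xr = np.array([-80.0, -80.0, -80.0, -80.0, -80.0, -78.0, -74.0, -70.0])
    tr = make_trace(t, np.zeros(8), xf, xr)
    seg = detect_phases(tr, rear_motion_threshold=1.0)
    assert list(seg.labels) == ["approach"] * 2 + ["entry"] * 3 + ["transit"] * 3
    assert seg.entry_start == 2 and seg.transit_start == 5


def test_infinite_threshold_entry_until_full_deformation():
    t = np.arange(6.0)
    xf = np.array([-5.0, 0.0, 10.0, 30.0, 60.0, 90.0])
    xr = np.array([-80.0, -75.0, -50.0, -20.0, 1.0, 20.0])
    tr = make_trace(t, np.zeros(6), xf, xr)
    seg = detect_phases(tr, rear_motion_threshold=np.inf)
    assert list(seg.labels) == ["approach", "entry", "entry", "entry", "transit", "transit"]


# ------------------------------------------------------------ event pressures


def test_event_on_frame_takes_frame_pressure():
    tr = make_trace([0, 1, 2, 3], [0.0, 0.1, 0.2, 0.3], [-1.0, 0.0, 1.0, 2.0],
                    [-75, -74, -73, -72], d_um=3.0)
    m = extract_critical_pressures(tr)
    assert m.P_Xf0 == pytest.approx(0.1, abs=1e-12)   # crossing exactly at frame 1
    # d/2 = 1.5 falls midway between frames 2 and 3
    assert m.P_Xf_d2 == pytest.approx(0.25, abs=1e-12)


def test_unreached_event_flagged_invalid():
    tr = make_trace([0, 1, 2], [0.0, 0.1, 0.2], [-1.0, 10.0, 30.0], [-75, -70, -60], d_um=50.0)
    m = extract_critical_pressures(tr)
    assert m.valid["P_Xf0"] and m.valid["P_Xf_d2"]
    assert not m.valid["P_Xr0"]
    assert np.isnan(m.P_Xr0)


def test_ar_max_restricted_to_pre_passage_frames():
    ar = [1.0, 1.5, 2.0, 1.2]
    tr = make_trace([0, 1, 2, 3], [0.0, 0.1, 0.2, 0.3],
                    [10.0, 30.0, 60.0, 90.0], [-40.0, -20.0, -1.0, 30.0],
                    aspect_ratio=ar, d_um=50.0)
    m = extract_critical_pressures(tr)
    assert m.AR_max == pytest.approx(2.0)  # last frame (rear inside) excluded


def test_ordering_warning_set_on_inversion():
    tr = make_trace([0, 1, 2, 3], [0.0, 0.5, 0.1, 0.15], [-1.0, 0.5, 26.0, 60.0],
                    [-75.0, -70.0, -50.0, 1.0], d_um=50.0)
    m = extract_critical_pressures(tr)
    assert m.ordering_warning  # P_Xf_d2 interpolates below P_Xf0 here


# ------------------------------------------------------------- normalization


def _measurements(p_xf0_ctrl, groups=None, experiment="e1"):
    rows = []
    for i, v in enumerate(p_xf0_ctrl):
        rows.append({"oocyte_id": f"c{i}", "group": "control", "experiment_id": experiment,
                     "P_Xf0": v, "P_Xf_d2": v + 1.0, "P_Xr0": v + 2.0})
    for g in groups or []:
        rows.append(g)
    return pd.DataFrame(rows)


def test_normalization_hand_arithmetic():
    extra = {"oocyte_id": "s0", "group": "soft", "experiment_id": "e1",
             "P_Xf0": 5.0, "P_Xf_d2": 6.0, "P_Xr0": 7.0}
    df = normalize_pressures(_measurements([1, 2, 3, 4, 5], [extra]), "control")
    soft = df[df.group == "soft"].iloc[0]
    assert soft.P_Xf0_norm == pytest.approx((5.0 - 3.0) / 2.0)  # IQR = 2 (type 7)
    ctrl = df[df.group == "control"]
    assert np.median(ctrl.P_Xf0_norm) == pytest.approx(0.0, abs=1e-12)
    q1, q3 = np.percentile(ctrl.P_Xf0_norm, [25, 75])
    assert q3 - q1 == pytest.approx(1.0, rel=1e-12)


def test_normalization_per_experiment_independence():
    df1 = _measurements([1, 2, 3, 4, 5], experiment="e1")
    df2 = _measurements([11, 12, 13, 14, 15], experiment="e2")
    out = normalize_pressures(pd.concat([df1, df2], ignore_index=True), "control")
    for exp in ("e1", "e2"):
        sub = out[out.experiment_id == exp]
        assert np.median(sub.P_Xf0_norm) == pytest.approx(0.0, abs=1e-12)


def test_normalization_degenerate_iqr():
    with pytest.raises(DegenerateNormalizationError):
        normalize_pressures(_measurements([2.0, 2.0, 2.0, 2.0]), "control")


def test_normalization_needs_three_controls():
    with pytest.raises(ValueError, match=">= 3"):
        normalize_pressures(_measurements([1.0, 2.0]), "control")


def test_normalized_comparison_invariant_under_common_shift():
    rng = np.random.default_rng(0)
    base = _measurements(
        list(2.0 + rng.normal(0, 0.3, 10)),
        [{"oocyte_id": f"s{i}", "group": "soft", "experiment_id": "e1",
          "P_Xf0": v, "P_Xf_d2": v + 1, "P_Xr0": v + 2}
         for i, v in enumerate(1.0 + rng.normal(0, 0.3, 10))],
    )
    shifted = base.copy()
    for c in ("P_Xf0", "P_Xf_d2", "P_Xr0"):
        shifted[c] = shifted[c] + 5.0
    r1 = compare_groups(normalize_pressures(base, "control"), "P_Xr0_norm", "soft", "control")
    r2 = compare_groups(normalize_pressures(shifted, "control"), "P_Xr0_norm", "soft", "control")
    assert r1.statistic == r2.statistic
    assert r1.p_value == r2.p_value


# ------------------------------------------------------------------- spindle


def test_spindle_constant_gives_zero_elongation():
    t = np.arange(6.0)
    xf = np.array([-5.0, 0.0, 20.0, 40.0, 70.0, 90.0])
    xr = np.array([-80.0, -75.0, -50.0, -20.0, 1.0, 20.0])
    tr = make_trace(t, np.zeros(6), xf, xr, spindle=(np.full(6, 20.0), np.full(6, 30.0)))
    sm = spindle_metrics(tr)
    assert sm.elongation_at_full_deformation == pytest.approx(0.0, abs=1e-12)
    assert sm.elongation_max == pytest.approx(0.0, abs=1e-12)
    assert sm.angle_at_full_deformation == pytest.approx(30.0)


def test_spindle_elongation_hand_value():
    t = np.arange(5.0)
    xf = np.array([-5.0, 10.0, 40.0, 70.0, 90.0])
    xr = np.array([-80.0, -60.0, -30.0, 0.0, 20.0])  # rear enters exactly at t=3
    length = np.array([20.0, 21.0, 23.0, 25.0, 26.0])
    angle = np.array([-120.0, -120.0, -120.0, -120.0, -120.0])
    tr = make_trace(t, np.zeros(5), xf, xr, spindle=(length, angle))
    sm = spindle_metrics(tr)
    assert sm.baseline_len == pytest.approx(20.0)
    assert sm.elongation_at_full_deformation == pytest.approx(25.0)
    assert sm.elongation_max == pytest.approx(30.0)
    assert sm.angle_at_full_deformation == pytest.approx(60.0)  # fold of -120


def test_spindle_missing_columns():
    tr = make_trace([0, 1], [0, 0.1], [-5, 0], [-80, -75])
    with pytest.raises(FeatureUnavailableError):
        spindle_metrics(tr)


@settings(derandomize=True, max_examples=100)
@given(theta=st.floats(-1000.0, 1000.0))
def test_fold_angle_properties(theta):
    folded = fold_angle(theta)
    assert 0.0 <= folded <= 90.0
    assert fold_angle(theta + 180.0) == pytest.approx(folded, abs=1e-9)
    assert fold_angle(-theta) == pytest.approx(folded, abs=1e-9)


# ------------------------------------------------------------------- groups


def _frame(a, b):
    return pd.DataFrame(
        {"group": ["a"] * len(a) + ["b"] * len(b), "m": list(a) + list(b)}
    )


def test_identical_groups_p_one():
    r = compare_groups(_frame([1, 2, 3], [1, 2, 3]), "m", "a", "b")
    assert r.p_value == pytest.approx(1.0)
    assert r.direction == "a=b"


def test_fully_separated_small_groups_exact_p():
    r = compare_groups(_frame([1, 2, 3], [10, 11, 12]), "m", "a", "b")
    assert r.p_value == pytest.approx(0.1)  # 2 / C(6,3) two-sided
    assert r.direction == "a<b"


def test_compare_groups_requires_three_per_group():
    with pytest.raises(ValueError):
        compare_groups(_frame([1, 2], [1, 2, 3]), "m", "a", "b")


def test_large_groups_use_tie_corrected_normal():
    rng = np.random.default_rng(1)
    a = rng.normal(0.0, 1.0, 30).round(1)  # rounding induces ties
    b = rng.normal(1.0, 1.0, 30).round(1)
    r = compare_groups(_frame(a, b), "m", "a", "b")
    assert 0.0 <= r.p_value < 0.05
    assert r.n_a == r.n_b == 30
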