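import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laccscreen.kinetics import (
    QC_FLAT,
    QC_NO_LINEAR_WINDOW,
    QC_OK,
    KineticsParams,
    KineticTrace,
    LinearFit,
    activity_from_fit,
    quantify_plate,
    trim_to_linear,
)

from oracles import exhaustive_linear_window


def make_trace(y, well="A1", dt=1.0):
    y = np.asarray(y, dtype=float)
    return KineticTrace(well, np.arange(y.size) * dt, y)


# -- trace validation ---------------------------------------------------------


def test_trace_rejects_short_and_nonmonotonic_and_nonfinite():
    with pytest.raises(ValueError, match="at least 2 points"):
        KineticTrace("A1", [0.0], [0.1])
    with pytest.raises(ValueError, match="strictly increasing"):
        KineticTrace("A1", [0.0, 2.0, 1.0], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="non-finite"):
        KineticTrace("A1", [0.0, 1.0], [0.1, np.nan])
    with pytest.raises(ValueError, match="equal length"):
        KineticTrace("A1", [0.0, 1.0, 2.0], [0.1, 0.2])


def test_params_validation():
    with pytest.raises(ValueError):
        KineticsParams(path_length_cm=0.0)
    with pytest.raises(ValueError):
        KineticsParams(path_length_cm=1.0, r2_min=1.5)
    with pytest.raises(ValueError):
        KineticsParams(path_length_cm=1.0, min_points=1)
    with pytest.raises(ValueError):
        KineticsParams(path_length_cm=1.0, epsilon=-1)


# -- trim_to_linear -----------------------------------------------------------


def test_trim_exact_line_uses_full_window(params_1cm):
    t = np.arange(30, dtype=float)
    tr = make_trace(0.05 + 0.01 * t)
    fit = trim_to_linear(tr, params_1cm)
    assert (fit.start_index, fit.end_index) == (0, 29)
    assert fit.qc_flag == QC_OK
    assert fit.slope == pytest.approx(0.01, rel=1e-12)
    assert fit.intercept == pytest.approx(0.05, rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_trim_flat_trace_flagged_flat_with_zero_slope(params_1cm):
    fit = trim_to_linear(make_trace(np.full(20, 0.3)), params_1cm)
    assert fit.qc_flag == QC_FLAT
    assert fit.slope == 0.0
    assert (fit.start_index, fit.end_index) == (0, 19)


def test_trim_excludes_lag_and_saturation(params_1cm):
    # lag for 10 points, linear for 25, saturated (constant) thereafter;
    # small curvature at the joints keeps the full trace below the R² bar
    t = np.arange(50, dtype=float)
    y = np.piecewise(
        t,
        [t < 10, (t >= 10) & (t < 35), t >= 35],
        [0.05, lambda x: 0.05 + 0.02 * (x - 10), 0.05 + 0.02 * 25],
    )
    fit = trim_to_linear(make_trace(y), params_1cm)
    assert fit.qc_flag == QC_OK
    # the longest window at R² >= 0.999 may keep a single joint point, so the
    # slope is recovered to a few percent and the deep lag/plateau is excluded
    assert fit.slope == pytest.approx(0.02, rel=0.05)
    assert fit.start_index >= 5
    assert fit.end_index <= 40


def test_trim_pure_noise_reports_no_linear_window(params_1cm):
    rng = np.random.default_rng(7)
    y = 0.2 + rng.normal(0, 0.05, size=40)
    fit = trim_to_linear(make_trace(y), params_1cm)
    assert fit.qc_flag == QC_NO_LINEAR_WINDOW
    assert fit.n_points == params_1cm.min_points


def test_trim_errors_when_trace_shorter_than_min_points(params_1cm):
    with pytest.raises(ValueError, match="fewer than min_points"):
        trim_to_linear(make_trace(np.linspace(0, 1, 5)), params_1cm)


def test_trim_matches_bruteforce_oracle_on_mixed_traces(params_1cm):
    rng = np.random.default_rng(42)
    t = np.arange(40, dtype=float)
    for _ in range(60):
        kind = rng.integers(0, 4)
        if kind == 0:  # saturating curve
            r = rng.uniform(0.01, 0.2)
            y = 0.05 + 2.0 * (1 - np.exp(-r * t)) + rng.normal(0, 0.002, t.size)
        elif kind == 1:  # clean line
            y = rng.uniform(0, 0.2) + rng.uniform(0.001, 0.05) * t
        elif kind == 2:  # flat
            y = np.full(t.size, rng.uniform(0.05, 0.5))
        else:  # noise only
            y = 0.2 + rng.normal(0, 0.05, t.size)
        fit = trim_to_linear(make_trace(y), params_1cm)
        s, e, slope, qc = exhaustive_linear_window(
            t, y, params_1cm.r2_min, params_1cm.min_points
        )
        assert (fit.start_index, fit.end_index, fit.qc_flag) == (s, e, qc)
        assert fit.slope == pytest.approx(slope, rel=1e-8, abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(
    slope=st.floats(1e-4, 0.1),
    intercept=st.floats(0.0, 1.0),
    n=st.integers(12, 60),
)
def test_trim_recovers_any_exact_line(slope, intercept, n):
    params = KineticsParams(path_length_cm=1.0)
    t = np.arange(n, dtype=float)
    fit = trim_to_linear(make_trace(intercept + slope * t), params)
    assert (fit.start_index, fit.end_index) == (0, n - 1)
    assert fit.slope == pytest.approx(slope, rel=1e-9)


def test_trim_invariant_to_absorbance_offset(params_1cm):
    rng = np.random.default_rng(3)
    t = np.arange(40, dtype=float)
    y = 0.05 + 2.0 * (1 - np.exp(-0.02 * t)) + rng.normal(0, 0.002, t.size)
    f1 = trim_to_linear(make_trace(y), params_1cm)
    f2 = trim_to_linear(make_trace(y + 0.5), params_1cm)
    assert (f1.start_index, f1.end_index) == (f2.start_index, f2.end_index)
    assert f1.slope == pytest.approx(f2.slope, rel=1e-9)


# -- Beer-Lambert conversion --------------------------------------------------


def fit_with_slope(slope):
    return LinearFit(0, 10, slope, 0.0, 1.0, QC_OK)


def test_beer_lambert_worked_example(params_1cm):
    # slope 0.036 AU/min, epsilon 36000 1/(M cm), 1 cm, 200 µL -> 2.0e-4 U
    assert activity_from_fit(fit_with_slope(0.036), params_1cm) == pytest.approx(
        2.0e-4, rel=1e-12
    )


def test_activity_scales_with_dilution_and_inversely_with_path():
    base = activity_from_fit(fit_with_slope(0.036), KineticsParams(path_length_cm=1.0))
    diluted = activity_from_fit(
        fit_with_slope(0.036), KineticsParams(path_length_cm=1.0, dilution_factor=10.0)
    )
    halfpath = activity_from_fit(fit_with_slope(0.036), KineticsParams(path_length_cm=0.5))
    assert diluted == pytest.approx(10 * base, rel=1e-12)
    assert halfpath == pytest.approx(2 * base, rel=1e-12)


def test_negative_slope_clamped_with_warning(params_1cm):
    with pytest.warns(UserWarning, match="clamped"):
        assert activity_from_fit(fit_with_slope(-0.01), params_1cm) == 0.0


def test_failed_qc_fit_cannot_be_converted(params_1cm):
    bad = LinearFit(0, 10, 0.01, 0.0, 0.5, QC_NO_LINEAR_WINDOW)
    with pytest.raises(ValueError, match="qc_flag"):
        activity_from_fit(bad, params_1cm)


# -- quantify_plate -----------------------------------------------------------


def small_plate():
    t = np.arange(30, dtype=float)
    traces = {
        "A1": make_trace(0.05 + 0.036 * t, "A1"),
        "A2": make_trace(0.05 + 0.018 * t, "A2"),
        "A3": make_trace(0.05 + 0.001 * t, "A3"),
    }
    layout = pd.DataFrame(
        {
            "well": ["A1", "A2", "A3"],
            "strain_id": ["S1", "REF", "BLK"],
            "replicate_id": ["r1", "r1", "r1"],
            "role": ["sample", "reference", "blank"],
        }
    )
    return traces, layout


def test_quantify_plate_activities_and_blank_rows(params_1cm):
    traces, layout = small_plate()
    out = quantify_plate(traces, layout, params_1cm)
    assert list(out["strain_id"]) == ["S1", "REF"]  # blank excluded from output
    s1 = out.set_index("strain_id")["activity_U"]
    assert s1["S1"] == pytest.approx(2.0e-4, rel=1e-9)
    assert s1["REF"] == pytest.approx(1.0e-4, rel=1e-9)


def test_quantify_plate_blank_subtraction():
    traces, layout = small_plate()
    params = KineticsParams(path_length_cm=1.0, subtract_blank=True)
    out = quantify_plate(traces, layout, params).set_index("strain_id")
    # blank slope 0.001 subtracted before conversion
    expected = (0.036 - 0.001) / 36000.0 * 200e-6 * 1e6
    assert out.loc["S1", "activity_U"] == pytest.approx(expected, rel=1e-9)


def test_quantify_plate_layout_errors(params_1cm):
    traces, layout = small_plate()
    dup = pd.concat([layout, layout.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate wells"):
        quantify_plate(traces, dup, params_1cm)
    bad_role = layout.assign(role=["sample", "control", "blank"])
    with pytest.raises(ValueError, match="unknown layout roles"):
        quantify_plate(traces, bad_role, params_1cm)
    with pytest.raises(ValueError, match="missing from traces"):
        quantify_plate({}, layout, params_1cm)
    with pytest.raises(ValueError, match="missing columns"):
        quantify_plate(traces, layout.drop(columns=["role"]), params_1cm)
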