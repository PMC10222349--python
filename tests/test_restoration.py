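"""Clip detection and spline restoration: exactness on polynomials, oracle
agreement, off-rail identity and degradation with overshoot."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tibrestore import (
    ClipRun,
    SyntheticRunConfig,
    detect_clip_runs,
    generate_run,
    match_peaks,
    restore_clip_run,
    restore_trace,
)
from tibrestore.restoration import averaged_knots
from tibrestore.events import PeakRecord
from tibrestore.processing import process_trace


# ---------------------------------------------------------------------------
# detection


class TestDetectClipRuns:
    def test_unsaturated_sine_yields_nothing(self):
        t = np.arange(2000) / 1125.0
        vals = 10.0 * np.sin(2 * np.pi * 1.4 * t)
        assert detect_clip_runs(vals, 16.0) == []

    def test_single_plateau(self):
        vals = np.array([14.0, 15.5, 16.0, 16.0, 16.0, 15.2])
        runs = detect_clip_runs(vals, 16.0, rail_tol_g=0.01)
        assert runs == [ClipRun(axis="y", start=2, end=5, rail_sign=1)]

    def test_runs_with_short_gap_are_merged(self):
        vals = np.array([0, 16, 16, 15, 15, 16, 16, 0], float)
        runs = detect_clip_runs(vals, 16.0, rail_tol_g=0.01, window_len=3)
        assert runs == [ClipRun(axis="y", start=1, end=7, rail_sign=1)]

    def test_runs_with_long_gap_stay_separate(self):
        vals = np.array([0, 16, 16, 15, 15, 15, 16, 16, 0], float)
        runs = detect_clip_runs(vals, 16.0, rail_tol_g=0.01, window_len=3)
        assert [(r.start, r.end) for r in runs] == [(1, 3), (6, 8)]

    def test_negative_rail_detected_with_sign(self):
        vals = np.array([0.0, -16.0, -16.0, 0.0])
        (run,) = detect_clip_runs(vals, 16.0, rail_tol_g=0.01)
        assert (run.start, run.end, run.rail_sign) == (1, 3, -1)

    def test_rail_sign_filter_is_one_sided(self):
        vals = np.array([0.0, 16.0, 0.0, -16.0, 0.0])
        runs = detect_clip_runs(vals, 16.0, rail_tol_g=0.01, rail_sign=1)
        assert [(r.start, r.rail_sign) for r in runs] == [(1, 1)]

    def test_rail_tolerance_admits_near_rail_samples(self):
        vals = np.array([0.0, 15.96, 0.0])
        assert detect_clip_runs(vals, 16.0, rail_tol_g=0.05) != []
        assert detect_clip_runs(vals, 16.0, rail_tol_g=0.01) == []

    def test_empty_series(self):
        assert detect_clip_runs(np.array([]), 16.0) == []


# ---------------------------------------------------------------------------
# restoration of single runs

RATE = 1125.0


def _clip_and_detect(values, rail):
    clipped = np.minimum(values, rail)
    (run,) = detect_clip_runs(clipped, rail, rail_tol_g=1e-9)
    return clipped, run


def test_quartic_peak_is_recovered_exactly():
    """Order-5 spline interpolation reproduces any degree-<=4 polynomial, so a
    clipped quartic peak is restored to round-off."""
    t = (np.arange(321) - 160) / RATE  # rail crossings at t = ±0.1 s
    p = 20.0 - 400.0 * t**2  # peak 20 g at t = 0
    clipped, run = _clip_and_detect(p, 16.0)
    restored, ok = restore_clip_run(clipped, run)
    assert ok
    assert np.max(np.abs(restored - p)) <= 1e-6
    assert restored.max() == pytest.approx(20.0, abs=1e-6)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    peak=st.floats(17.0, 60.0),
    a2=st.floats(500.0, 5000.0),
    a4=st.floats(0.0, 1e7),
    a1=st.floats(-30.0, 30.0),
)
def test_polynomial_reproduction_property(peak, a2, a4, a1):
    """Any degree-<=4 polynomial clipped in its interior with >=3 clean
    samples per side restores with error <= 1e-6 g."""
    t = (np.arange(301) - 150) / RATE
    p = peak + a1 * t - a2 * t**2 - a4 * t**4
    clipped = np.minimum(p, 16.0)
    runs = detect_clip_runs(clipped, 16.0, rail_tol_g=1e-9)
    for run in runs:
        if run.start < 3 or run.end > len(p) - 3:
            continue
        restored, ok = restore_clip_run(clipped, run)
        assert ok
        idx = slice(run.start, run.end)
        assert np.max(np.abs(restored[idx] - p[idx])) <= 1e-6


def _truncated_power_oracle(x, y, knots_interior, x_eval):
    """Independent piecewise-quartic interpolant: monomials up to degree 4
    plus one truncated power term per interior knot, solved directly."""
    x = np.asarray(x, float)
    x0 = x[0]
    cols = [(x - x0) ** i for i in range(5)]
    cols += [np.where(x > xi, (x - xi) ** 4, 0.0) for xi in knots_interior]
    A = np.column_stack(cols)
    coef = np.linalg.solve(A, y)
    cols_e = [(x_eval - x0) ** i for i in range(5)]
    cols_e += [np.where(x_eval > xi, (x_eval - xi) ** 4, 0.0) for xi in knots_interior]
    return np.column_stack(cols_e) @ coef


def test_gaussian_impact_matches_independent_spline_oracle():
    """The restored values for a clipped Gaussian impact equal an independent
    truncated-power-basis construction of the same order-5 interpolant."""
    t = (np.arange(200) - 100) / RATE
    g = 24.0 * np.exp(-(t**2) / (2 * 0.008**2))
    clipped, run = _clip_and_detect(g, 16.0)
    restored, ok = restore_clip_run(clipped, run)
    assert ok
    support = np.r_[
        np.arange(run.start - 3, run.start), np.arange(run.end, run.end + 3)
    ].astype(float)
    knots = averaged_knots(support, 5)
    interior = knots[5:-5]
    x_eval = np.arange(run.start, run.end, dtype=float)
    oracle = _truncated_power_oracle(support, clipped[support.astype(int)], interior, x_eval)
    np.testing.assert_allclose(restored[run.start : run.end], oracle, rtol=1e-7, atol=1e-7)
    # the interpolant passes through all six support samples exactly
    on_support = _truncated_power_oracle(
        support, clipped[support.astype(int)], interior, support
    )
    np.testing.assert_allclose(on_support, clipped[support.astype(int)], rtol=1e-9)


def test_degenerate_runs():
    # zero-length runs cannot be constructed; a single railed sample is the
    # minimum unit of restoration, and it leaves every other sample untouched
    with pytest.raises(ValueError):
        ClipRun(axis="y", start=5, end=5, rail_sign=1)
    vals = np.arange(20.0)
    vals[5] = 16.0
    run = ClipRun(axis="y", start=5, end=6, rail_sign=1)
    out, ok = restore_clip_run(vals, run)
    assert ok
    assert np.array_equal(out[:5], vals[:5]) and np.array_equal(out[6:], vals[6:])


def test_boundary_run_is_skipped():
    vals = np.r_[np.full(4, 16.0), np.linspace(15.0, 0.0, 20)]
    (run,) = detect_clip_runs(vals, 16.0, rail_tol_g=0.01)
    restored, ok = restore_clip_run(vals, run)
    assert not ok
    assert np.array_equal(restored, vals)


def test_median_restoration_error_grows_with_overshoot():
    """On a Gaussian-impact family the restoration error degrades
    monotonically as the true peak moves further above the 16 g rail."""
    rng = np.random.default_rng(0)
    med_errors = []
    for peak in (18.0, 22.0, 26.0):
        errs = []
        for _ in range(40):
            width = rng.uniform(0.006, 0.010)
            t = (np.arange(200) - 100) / RATE + rng.uniform(-0.5, 0.5) / RATE
            g = peak * np.exp(-(t**2) / (2 * width**2))
            clipped = np.minimum(g, 16.0)
            runs = detect_clip_runs(clipped, 16.0, rail_tol_g=1e-9)
            restored = clipped
            for run in runs:
                restored, ok = restore_clip_run(restored, run)
                assert ok
            errs.append(abs(restored.max() - peak))
        med_errors.append(np.median(errs))
    assert med_errors[0] <= med_errors[1] <= med_errors[2]


# ---------------------------------------------------------------------------
# whole traces


def test_clip_free_trace_restores_to_identity():
    cfg = SyntheticRunConfig(
        n_strides=20, axial_peak_mean_g=8.0, axial_peak_sd_g=1.0, seed=3
    )
    _, low, _ = generate_run(cfg)
    out, report = restore_trace(low)
    assert np.array_equal(out.a, low.a)
    assert report.total_found == 0
    assert not out.restored_mask.any()


def test_off_rail_samples_are_bit_identical(run600):
    _, _, low, _ = run600
    out, report = restore_trace(low)
    assert report.total_found > 0
    untouched = ~out.restored_mask
    assert np.array_equal(out.a[untouched], low.a[untouched])
    assert np.array_equal(low.a, generate_run(run600[0])[1].a)  # source unchanged


def test_all_three_axes_carry_restored_samples(run600):
    _, _, low, _ = run600
    out, report = restore_trace(low)
    for axis in ("x", "y", "z"):
        assert report.runs_restored[axis] > 0
    assert out.restored_mask.any(axis=0).all()


def test_restored_peaks_track_truth_and_underestimate(run600):
    """Restored axial peaks correlate with the true per-stride peaks, and the
    signed error is negative on average (restoration underestimates)."""
    _, _, low, truth = run600
    restored, _ = restore_trace(low)
    stream = process_trace(restored, "low_restored")
    truth_peaks = [
        PeakRecord(stride_id=i, kind="axial", value_g=float(v), time_s=float(t), source="truth")
        for i, (v, t) in enumerate(zip(truth.true_axial_pta_g, truth.contact_times_s))
    ]
    match = match_peaks(stream.axial_peaks, truth_peaks, tol_s=0.2)
    assert len(match.pairs) >= 500
    test_v = np.array([p.test_value_g for p in match.pairs])
    true_v = np.array([p.ref_value_g for p in match.pairs])
    assert np.corrcoef(test_v, true_v)[0, 1] > 0.9
    res = stats.ttest_1samp(test_v - true_v, 0.0, alternative="less")
    assert res.pvalue < 0.05
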