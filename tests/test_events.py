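"""Filtering, contact detection, stride segmentation, PTA extraction and
cross-stream matching."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from tibrestore import (
    FootStrike,
    PeakRecord,
    Stride,
    detect_foot_contacts,
    extract_pta,
    generate_run,
    lowpass_filter,
    match_peaks,
    resultant,
    segment_strides,
)
from tibrestore import SyntheticRunConfig
from tibrestore.events import MatchedPair


# ---------------------------------------------------------------------------
# filter


class TestLowpassFilter:
    def test_constant_series_unchanged(self, trace_factory):
        tr = trace_factory(np.full(4000, 3.0), rate_hz=1600.0)
        out = lowpass_filter(tr)
        np.testing.assert_allclose(out.ay, 3.0, rtol=1e-9)

    def test_cutoff_sine_attenuated_to_half(self, trace_factory):
        # |H|^2 = 1/2 at the cut-off for one pass; forward-backward doubles it
        t = np.arange(16000) / 1600.0
        tr = trace_factory(np.sin(2 * np.pi * 85.0 * t), rate_hz=1600.0)
        out = lowpass_filter(tr, cutoff_hz=85.0)
        mid = out.ay[4000:-4000]
        assert np.max(np.abs(mid)) == pytest.approx(0.5, rel=0.05)

    def test_passband_sine_preserved(self, trace_factory):
        t = np.arange(16000) / 1600.0
        tr = trace_factory(np.sin(2 * np.pi * 5.0 * t), rate_hz=1600.0)
        out = lowpass_filter(tr, cutoff_hz=85.0)
        mid = out.ay[4000:-4000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)

    def test_cutoff_above_nyquist_rejected(self, trace_factory):
        tr = trace_factory(np.zeros(100), rate_hz=100.0)
        with pytest.raises(ValueError):
            lowpass_filter(tr, cutoff_hz=60.0)


# ---------------------------------------------------------------------------
# resultant


@pytest.mark.parametrize(
    "xyz,expected",
    [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((-7.0, 0.0, 0.0), 7.0)],
)
def test_resultant_vector_magnitude(trace_factory, xyz, expected):
    x, y, z = xyz
    tr = trace_factory([y, y], x=[x, x], z=[z, z])
    np.testing.assert_allclose(resultant(tr), expected)


# ---------------------------------------------------------------------------
# contacts


def _bump_series(peak_times, rate=1125.0, total=6.0, dip_offset=0.02):
    """Baseline 1 g with sharp bumps and a dip shortly before each bump."""
    t = np.arange(int(total * rate)) / rate
    y = np.full_like(t, 1.0)
    for tp in peak_times:
        y += 10.0 * np.exp(-((t - tp) ** 2) / (2 * 0.004**2))
        y -= 0.8 * np.exp(-((t - (tp - dip_offset)) ** 2) / (2 * 0.004**2))
    return t, y


class TestDetectFootContacts:
    def test_constant_series_has_no_contacts(self):
        assert detect_foot_contacts(np.full(2000, 2.0), 1125.0) == []

    def test_contact_is_minimum_before_maximum(self):
        t, y = _bump_series([2.0, 3.0])
        contacts = detect_foot_contacts(y, 1125.0)
        assert len(contacts) == 2
        for c, tp in zip(contacts, (2.0, 3.0)):
            assert c.contact_time_s == pytest.approx(tp - 0.02, abs=0.005)

    def test_minimum_separation_collapses_near_maxima(self):
        t, y = _bump_series([2.0, 2.1])
        contacts = detect_foot_contacts(y, 1125.0, min_separation_s=0.5)
        assert len(contacts) == 1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_foot_contacts(np.ones(10), 1125.0)

    def test_synthetic_contacts_recovered_within_15ms(self):
        cfg = SyntheticRunConfig(n_strides=200, seed=13)
        high, _, truth = generate_run(cfg)
        res = resultant(lowpass_filter(high))
        contacts = detect_foot_contacts(res, high.rate_hz)
        det = np.array([c.contact_time_s for c in contacts])
        hits = 0
        for tc in truth.contact_times_s:
            if np.min(np.abs(det - tc)) <= 0.015:
                hits += 1
        assert hits / len(truth.contact_times_s) >= 0.95


# ---------------------------------------------------------------------------
# strides and PTA


class TestSegmentStrides:
    def test_forty_percent_window_arithmetic(self):
        contacts = [FootStrike(0, 1.0), FootStrike(0, 2.0), FootStrike(0, 3.0)]
        strides = segment_strides(contacts)
        assert [(s.start_time_s, s.end_time_s) for s in strides] == [(1.0, 2.0), (2.0, 3.0)]
        assert [s.window_end_s for s in strides] == [1.4, 2.4]

    def test_implausibly_short_stride_dropped(self):
        contacts = [FootStrike(0, 1.0), FootStrike(0, 1.05), FootStrike(0, 2.0)]
        strides = segment_strides(contacts, min_duration_s=0.4)
        assert [(s.start_time_s, s.end_time_s) for s in strides] == [(1.05, 2.0)]

    def test_too_few_contacts(self):
        assert segment_strides([]) == []
        assert segment_strides([FootStrike(0, 1.0)]) == []


class TestExtractPta:
    def test_monotone_series_peaks_at_window_edge(self):
        rate = 1000.0
        t = np.arange(2000) / rate
        axial = t.copy()  # strictly increasing
        res = np.abs(axial)
        stride = Stride(0.5, 1.5)
        ax, rs = extract_pta(stride, axial, res, t)
        # last sample strictly inside [0.5, 0.9)
        assert ax.time_s == pytest.approx(0.899, abs=1e-9)
        assert ax.value_g == pytest.approx(0.899, abs=1e-9)

    def test_matches_brute_force_maximum(self):
        rng = np.random.default_rng(5)
        rate = 1125.0
        t = np.arange(3000) / rate
        axial = rng.normal(size=t.size)
        x = rng.normal(size=t.size)
        res = np.sqrt(axial**2 + x**2)
        stride = Stride(0.8, 1.6)
        ax, rs = extract_pta(stride, axial, res, t)
        mask = (t >= stride.start_time_s) & (t < stride.window_end_s)
        assert ax.value_g == np.max(axial[mask])
        assert rs.value_g == np.max(res[mask])
        assert rs.value_g >= ax.value_g

    def test_resultant_dominates_axial_on_synthetic_trace(self, run600):
        _, high, _, _ = run600
        filtered = lowpass_filter(high)
        res = resultant(filtered)
        contacts = detect_foot_contacts(res, high.rate_hz)
        for sid, stride in enumerate(segment_strides(contacts)):
            recs = extract_pta(stride, filtered.ay, res, filtered.t, stride_id=sid)
            if recs is None:
                continue
            assert recs[1].value_g >= recs[0].value_g

    def test_degenerate_window_returns_none(self):
        t = np.arange(100) / 10.0
        stride = Stride(0.0, 0.2)  # window [0, 0.08): one sample at 10 Hz
        assert extract_pta(stride, t, t, t) is None


# ---------------------------------------------------------------------------
# matching


def _peaks(times, values=None, kind="axial"):
    values = values if values is not None else [10.0] * len(times)
    return [
        PeakRecord(stride_id=i, kind=kind, value_g=v, time_s=t)
        for i, (t, v) in enumerate(zip(times, values))
    ]


class TestMatchPeaks:
    def test_identical_timestamps_all_matched(self):
        ref = _peaks([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        test = _peaks([1.0, 2.0, 3.0], [9.0, 11.5, 12.0])
        m = match_peaks(test, ref)
        assert len(m.pairs) == 3
        assert [p.test_time_s - p.ref_time_s for p in m.pairs] == [0.0, 0.0, 0.0]
        assert [p.diff_g for p in m.pairs] == [-1.0, 0.5, 0.0]

    def test_out_of_tolerance_reference_unmatched(self):
        ref = _peaks([1.0, 2.0])
        test = _peaks([1.15, 3.0])
        m = match_peaks(test, ref, tol_s=0.2)
        assert len(m.pairs) == 1
        assert m.pairs[0].ref_time_s == 1.0 and m.pairs[0].test_time_s == 1.15
        assert m.n_unmatched_ref == 1 and m.n_unmatched_test == 1

    def test_pair_count_bounded_by_smaller_list(self):
        ref = _peaks(list(np.arange(0.0, 5.0, 0.7)))
        test = _peaks([0.1, 0.75, 3.0])
        m = match_peaks(test, ref)
        assert len(m.pairs) <= min(len(ref), len(test))

    def test_empty_inputs(self):
        assert match_peaks([], _peaks([1.0])).pairs == []
        assert match_peaks(_peaks([1.0]), []).pairs == []

    def test_greedy_matches_optimal_assignment_on_jittered_lists(self):
        """With realistic 50 ms jitter, greedy nearest-in-time matching agrees
        with the minimum-total-|dt| assignment on >= 99% of pairs."""
        rng = np.random.default_rng(42)
        agree = total = 0
        for _ in range(200):
            n = int(rng.integers(3, 13))
            ref_t = np.cumsum(rng.uniform(0.6, 0.8, n))
            test_t = np.sort(ref_t + rng.normal(0.0, 0.05, n))
            ref = _peaks(list(ref_t))
            test = _peaks(list(test_t))
            m = match_peaks(test, ref, tol_s=0.2)
            # optimal assignment oracle on the same tolerance-limited costs
            big = 1e6
            cost = np.abs(test_t[None, :] - ref_t[:, None])
            cost[cost > 0.2] = big
            rows, cols = linear_sum_assignment(cost)
            optimal = {
                (ref_t[i], test_t[j]) for i, j in zip(rows, cols) if cost[i, j] < big
            }
            got = {(p.ref_time_s, p.test_time_s) for p in m.pairs}
            agree += len(got & optimal)
            total += max(len(optimal), len(got))
        assert agree / total >= 0.99
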