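"""Filtering, gait-event detection, peak extraction and cross-stream matching.

Processing follows the standard tibial-accelerometry chain: each axis is
low-pass filtered (2nd-order Butterworth, 85 Hz, applied forward–backward so
peaks do not shift in time), the resultant ``sqrt(x² + y² + z²)`` is formed,
initial foot contacts are found as the local minimum of the resultant within
the 75 ms preceding each qualifying local maximum, strides run from contact
to contact, and peak tibial acceleration (PTA) — axial (y-axis) and resultant
— is the maximum within the first 40% of each stride.  Peaks from two streams
recorded on a common clock are paired by nearest time within 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .trace import TriaxialTrace

__all__ = [
    "FootStrike",
    "Stride",
    "PeakRecord",
    "MatchedPair",
    "MatchResult",
    "lowpass_filter",
    "resultant",
    "detect_foot_contacts",
    "segment_strides",
    "extract_pta",
    "match_peaks",
]


@dataclass(frozen=True)
class FootStrike:
    contact_index: int
    contact_time_s: float


@dataclass(frozen=True)
class Stride:
    """Contact-to-contact interval; PTA is sought in its first ``fraction``."""

    start_time_s: float
    end_time_s: float
    fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.end_time_s <= self.start_time_s:
            raise ValueError("stride end must exceed start")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")

    @property
    def duration_s(self) -> float:
        return self.end_time_s - self.start_time_s

    @property
    def window_end_s(self) -> float:
        return self.start_time_s + self.fraction * self.duration_s


@dataclass(frozen=True)
class PeakRecord:
    """One PTA value for one stride from one signal stream."""

    stride_id: int
    kind: str  # "axial" | "resultant"
    value_g: float
    time_s: float
    source: str = ""  # "low_raw" | "low_restored" | "high" | ...
    restored_in_window: bool = False


@dataclass(frozen=True)
class MatchedPair:
    """A (test, reference) PTA pair matched in time; diff < 0 = underestimation."""

    ref_value_g: float
    test_value_g: float
    ref_time_s: float
    test_time_s: float
    kind: str = ""
    participant_id: str = ""
    restored_in_window: bool = False

    @property
    def diff_g(self) -> float:
        return self.test_value_g - self.ref_value_g

    @property
    def mean_g(self) -> float:
        return 0.5 * (self.test_value_g + self.ref_value_g)


@dataclass
class MatchResult:
    pairs: list[MatchedPair]
    n_unmatched_test: int
    n_unmatched_ref: int


def lowpass_filter(
    trace: TriaxialTrace, cutoff_hz: float = 85.0, order: int = 2
) -> TriaxialTrace:
    """Zero-phase Butterworth low-pass of every axis; length preserved.

    Forward–backward application (``filtfilt``) doubles the attenuation —
    −6 dB at the cut-off — but leaves peak times unshifted, which matters for
    the 200 ms cross-stream matching downstream.
    """
    nyq = trace.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.rate_hz, output="sos")
    out = trace.copy()
    out.a = signal.sosfiltfilt(sos, out.a, axis=0)
    return out


def resultant(trace: TriaxialTrace) -> np.ndarray:
    """Vector magnitude ``sqrt(x² + y² + z²)`` per sample."""
    return np.sqrt(np.sum(trace.a**2, axis=1))


def detect_foot_contacts(
    res: np.ndarray,
    rate_hz: float,
    min_separation_s: float = 0.5,
    min_prominence_g: float = 4.0,
    window_ms: float = 75.0,
) -> list[FootStrike]:
    """Initial contacts from a resultant-acceleration series.

    Qualifying local maxima (impact peaks) are found subject to a minimum
    separation and prominence; the contact for each maximum is the minimum of
    the resultant within the preceding ``window_ms``.  Two maxima that share
    one minimum collapse to a single contact.
    """
    res = np.asarray(res, float)
    win = int(round(window_ms / 1000.0 * rate_hz))
    if res.size <= win:
        raise ValueError("series shorter than the contact search window")
    peaks, _ = signal.find_peaks(
        res,
        distance=max(1, int(round(min_separation_s * rate_hz))),
        prominence=min_prominence_g,
    )
    contacts: list[FootStrike] = []
    seen: set[int] = set()
    for p in peaks:
        w0 = max(0, p - win)
        if p <= w0:
            continue
        i_min = w0 + int(np.argmin(res[w0:p]))
        if i_min in seen:
            continue
        seen.add(i_min)
        contacts.append(FootStrike(contact_index=i_min, contact_time_s=i_min / rate_hz))
    contacts.sort(key=lambda c: c.contact_index)
    return contacts


def segment_strides(
    contacts: list[FootStrike],
    min_duration_s: float = 0.4,
    max_duration_s: float = 1.6,
    fraction: float = 0.40,
) -> list[Stride]:
    """Consecutive contacts become strides; implausible durations are dropped.

    ``n`` contacts yield at most ``n − 1`` strides; any stride outside the
    plausibility band ``[min_duration_s, max_duration_s]`` is discarded
    (guards against spurious contacts on rough outdoor data).
    """
    strides = []
    for c0, c1 in zip(contacts[:-1], contacts[1:]):
        dur = c1.contact_time_s - c0.contact_time_s
        if min_duration_s <= dur <= max_duration_s:
            strides.append(
                Stride(c0.contact_time_s, c1.contact_time_s, fraction=fraction)
            )
    return strides


def extract_pta(
    stride: Stride,
    axial: np.ndarray,
    res: np.ndarray,
    t: np.ndarray,
    stride_id: int = 0,
    source: str = "",
    restored_any: np.ndarray | None = None,
) -> tuple[PeakRecord, PeakRecord] | None:
    """Axial and resultant PTA within the first 40% of one stride.

    The window is half-open ``[start, window_end)``; the peak time is the
    first argmax on ties.  Returns ``None`` when the window holds fewer than
    two samples (degenerate stride; callers count these).  ``restored_any``
    is an optional per-sample flag (any axis restored) used to mark peaks
    whose stride window contains reconstructed samples.
    """
    i0, i1 = np.searchsorted(t, [stride.start_time_s, stride.window_end_s])
    if i1 - i0 < 2:
        return None
    w_ax = axial[i0:i1]
    w_res = res[i0:i1]
    j_ax = int(np.argmax(w_ax))
    j_res = int(np.argmax(w_res))
    touched = bool(restored_any[i0:i1].any()) if restored_any is not None else False
    rec_ax = PeakRecord(
        stride_id=stride_id,
        kind="axial",
        value_g=float(w_ax[j_ax]),
        time_s=float(t[i0 + j_ax]),
        source=source,
        restored_in_window=touched,
    )
    rec_res = PeakRecord(
        stride_id=stride_id,
        kind="resultant",
        value_g=float(w_res[j_res]),
        time_s=float(t[i0 + j_res]),
        source=source,
        restored_in_window=touched,
    )
    return rec_ax, rec_res


def match_peaks(
    test: list[PeakRecord],
    ref: list[PeakRecord],
    tol_s: float = 0.200,
    participant_id: str = "",
) -> MatchResult:
    """Pair reference peaks with nearest-in-time test peaks within ``tol_s``.

    Greedy by ascending |Δt| with ties broken by earlier reference time; each
    peak is used at most once, so the number of pairs never exceeds the
    smaller list.  The pair difference is ``test − ref`` (negative means the
    test stream underestimates the reference).
    """
    if not test or not ref:
        return MatchResult([], len(test), len(ref))
    test_times = np.array([p.time_s for p in test])
    order = np.argsort(test_times, kind="stable")
    test_sorted = [test[i] for i in order]
    test_times = test_times[order]

    candidates: list[tuple[float, float, int, int]] = []
    for i, r in enumerate(ref):
        lo = np.searchsorted(test_times, r.time_s - tol_s, side="left")
        hi = np.searchsorted(test_times, r.time_s + tol_s, side="right")
        for j in range(lo, hi):
            candidates.append((abs(test_times[j] - r.time_s), r.time_s, i, j))
    candidates.sort()

    used_ref: set[int] = set()
    used_test: set[int] = set()
    pairs: list[MatchedPair] = []
    for _, _, i, j in candidates:
        if i in used_ref or j in used_test:
            continue
        used_ref.add(i)
        used_test.add(j)
        r, s = ref[i], test_sorted[j]
        pairs.append(
            MatchedPair(
                ref_value_g=r.value_g,
                test_value_g=s.value_g,
                ref_time_s=r.time_s,
                test_time_s=s.time_s,
                kind=r.kind,
                participant_id=participant_id,
                restored_in_window=s.restored_in_window,
            )
        )
    pairs.sort(key=lambda p: p.ref_time_s)
    return MatchResult(
        pairs=pairs,
        n_unmatched_test=len(test) - len(used_test),
        n_unmatched_ref=len(ref) - len(used_ref),
    )
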