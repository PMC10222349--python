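"""Detection and spline restoration of rail-saturated (clipped) segments.

A sensor whose operating range is exceeded outputs a flat cut-off at its rail
and the true peak is lost.  The restoration algorithm reconstructs each
clipped segment from the clean samples flanking it: a window of 3 samples on
each side of the flat cut-off supports an interpolating spline of order 5
(polynomial degree 4), which is evaluated at the clipped sample positions to
replace them.  Order-5 interpolation through six support points reproduces
any polynomial of degree ≤ 4 exactly, which pins the algorithm's behaviour
independently of knot placement.

Runs too close to the series boundary to supply a full support window are
left untouched and reported as skipped; reconstructing beyond the data would
amount to quartic extrapolation, which is unstable.  No floor or cap is
applied to restored values here — physically implausible reconstructions
(e.g. a restored peak below the rail) are handled by the analysis-stage
rejection rule.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .trace import AXES, TriaxialTrace

__all__ = [
    "ClipRun",
    "RestorationReport",
    "detect_clip_runs",
    "restore_clip_run",
    "restore_trace",
    "averaged_knots",
]

#: default tolerance below the nominal rail at which a sample counts as railed
DEFAULT_RAIL_TOL_G = 0.05

#: support-window half width (samples each side of the flat cut-off)
DEFAULT_WINDOW_LEN = 3

#: spline order ("order 5" = polynomial degree 4)
DEFAULT_SPLINE_ORDER = 5


@dataclass(frozen=True)
class ClipRun:
    """A maximal contiguous railed interval on one axis, half-open [start, end)."""

    axis: str
    start: int
    end: int
    rail_sign: int

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.rail_sign not in (-1, 1):
            raise ValueError("rail_sign must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RestorationReport:
    """Accounting of what the restoration pass found and did."""

    runs_found: dict[str, int] = field(default_factory=lambda: {a: 0 for a in AXES})
    runs_restored: dict[str, int] = field(default_factory=lambda: {a: 0 for a in AXES})
    runs_skipped: dict[str, int] = field(default_factory=lambda: {a: 0 for a in AXES})
    samples_restored: dict[str, int] = field(default_factory=lambda: {a: 0 for a in AXES})

    @property
    def total_found(self) -> int:
        return sum(self.runs_found.values())

    @property
    def total_restored(self) -> int:
        return sum(self.runs_restored.values())

    @property
    def total_skipped(self) -> int:
        return sum(self.runs_skipped.values())

    def to_dict(self) -> dict:
        return asdict(self)


def detect_clip_runs(
    values: np.ndarray,
    range_g: float,
    rail_tol_g: float = DEFAULT_RAIL_TOL_G,
    window_len: int = DEFAULT_WINDOW_LEN,
    axis: str = "y",
    rail_sign: int | None = None,
) -> list[ClipRun]:
    """Find maximal runs of rail-saturated samples on one axis series.

    A sample is railed when ``|value| >= range_g - rail_tol_g``.  Maximal
    constant-sign runs are returned in order; runs separated by fewer than
    ``window_len`` clean samples are merged into one run spanning both, so
    that every support window used later contains only clean samples.

    ``rail_sign`` restricts detection to one rail (+1 or -1); the one-sided
    artificial-clipping experiment uses this.
    """
    if range_g <= 0:
        raise ValueError("range_g must be positive")
    if rail_tol_g < 0:
        raise ValueError("rail_tol_g must be non-negative")
    values = np.asarray(values, float)
    if values.size == 0:
        return []
    railed = np.abs(values) >= range_g - rail_tol_g
    if rail_sign is not None:
        railed &= np.sign(values) == rail_sign
    if not railed.any():
        return []
    # maximal constant-sign runs
    sign = np.sign(values).astype(int)
    idx = np.flatnonzero(railed)
    breaks = np.flatnonzero((np.diff(idx) != 1) | (sign[idx[1:]] != sign[idx[:-1]]))
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks] + 1, idx[-1] + 1]
    runs = [
        ClipRun(axis=axis, start=int(s), end=int(e), rail_sign=int(sign[s]))
        for s, e in zip(starts, ends)
    ]
    # merge runs whose clean gap is too short to host a support window
    merged: list[ClipRun] = [runs[0]]
    for run in runs[1:]:
        prev = merged[-1]
        if run.start - prev.end < window_len:
            merged[-1] = ClipRun(
                axis=axis, start=prev.start, end=run.end, rail_sign=prev.rail_sign
            )
        else:
            merged.append(run)
    return merged


def averaged_knots(x: np.ndarray, order: int) -> np.ndarray:
    """Averaged-interior-knot vector for interpolation at sites ``x``.

    The standard rule for order-``m`` (degree ``m−1``) spline interpolation at
    ``n`` sites: full-multiplicity boundary knots plus ``n − m`` interior knots,
    each the mean of ``m − 1`` consecutive interior sites.  This is the knot
    choice that guarantees the Schoenberg–Whitney conditions hold.
    """
    x = np.asarray(x, float)
    n = x.size
    k = order - 1  # polynomial degree
    if n < order:
        raise ValueError(f"need at least {order} sites for order-{order} interpolation")
    interior = [np.mean(x[j : j + k]) for j in range(1, n - k)]
    return np.r_[[x[0]] * order, interior, [x[-1]] * order]


def restore_clip_run(
    values: np.ndarray,
    run: ClipRun,
    window_len: int = DEFAULT_WINDOW_LEN,
    spline_order: int = DEFAULT_SPLINE_ORDER,
) -> tuple[np.ndarray, bool]:
    """Reconstruct one clipped run by windowed spline interpolation.

    The ``window_len`` samples immediately before ``run.start`` and after
    ``run.end`` are interpolated by a spline of order ``spline_order`` with
    averaged interior knots; the spline is evaluated at the clipped sample
    positions and those values replace the railed samples.

    Returns ``(restored_values, ok)``.  When the run lies within
    ``window_len`` samples of a series boundary there is no full support
    window; the series is returned unchanged with ``ok = False``.
    """
    values = np.asarray(values, float)
    n = values.size
    if run.length == 0:  # degenerate; nothing to do
        return values.copy(), True
    if run.start - window_len < 0 or run.end + window_len > n:
        return values.copy(), False
    left = np.arange(run.start - window_len, run.start)
    right = np.arange(run.end, run.end + window_len)
    support = np.r_[left, right]
    x = support.astype(float)  # uniform clock: indices are affine in time
    y = values[support]
    knots = averaged_knots(x, spline_order)
    spline = make_interp_spline(x, y, k=spline_order - 1, t=knots)
    out = values.copy()
    out[run.start : run.end] = spline(np.arange(run.start, run.end, dtype=float))
    return out, True


def restore_trace(
    trace: TriaxialTrace,
    window_len: int = DEFAULT_WINDOW_LEN,
    spline_order: int = DEFAULT_SPLINE_ORDER,
    rail_tol_g: float = DEFAULT_RAIL_TOL_G,
    rail_sign: int | None = None,
    axes: tuple[str, ...] = AXES,
    range_g: float | None = None,
) -> tuple[TriaxialTrace, RestorationReport]:
    """Detect and restore clipped runs on each axis of a trace independently.

    The source trace is left unchanged.  The returned trace carries a
    ``restored_mask`` flagging replaced samples, and the report counts runs
    found, restored and skipped per axis.  ``range_g`` overrides the trace's
    own operating range (the artificial-clipping experiment restores at a
    rail below the sensor's).
    """
    rail = trace.range_g if range_g is None else range_g
    out = trace.copy()
    mask = np.zeros_like(out.a, dtype=bool)
    report = RestorationReport()
    for ai, axis in enumerate(AXES):
        if axis not in axes:
            continue
        series = trace.a[:, ai]
        runs = detect_clip_runs(
            series, rail, rail_tol_g=rail_tol_g, window_len=window_len,
            axis=axis, rail_sign=rail_sign,
        )
        report.runs_found[axis] = len(runs)
        restored = series
        for run in runs:
            restored, ok = restore_clip_run(
                restored, run, window_len=window_len, spline_order=spline_order
            )
            if ok:
                report.runs_restored[axis] += 1
                report.samples_restored[axis] += run.length
                mask[run.start : run.end, ai] = True
            else:
                report.runs_skipped[axis] += 1
        out.a[:, ai] = restored
    out.restored_mask = mask
    return out, report
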