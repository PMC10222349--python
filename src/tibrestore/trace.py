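"""Uniformly sampled tri-axial acceleration traces and their on-disk text format.

A :class:`TriaxialTrace` holds one sensor recording: a common time base and one
acceleration series per axis, in units of g, together with the sampling rate and
the sensor operating range (the ± full-scale acceleration beyond which the
hardware saturates).  Traces are written as plain delimited text with columns
``time_s, ax_g, ay_g, az_g`` and a one-line ``#`` header carrying the metadata,
so files round-trip without sidecar information.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: axis names in storage order
AXES = ("x", "y", "z")

#: tolerance on uniform sample spacing, seconds
_DT_TOL_S = 1e-6


@dataclass
class TriaxialTrace:
    """One tri-axial accelerometer recording on a uniform clock.

    Parameters
    ----------
    t
        Sample times in seconds, uniformly spaced at ``1 / rate_hz``.
    a
        Acceleration array of shape ``(n, 3)`` in g, columns x, y, z.  The
        y-axis is aligned with the long axis of the tibia (axial direction).
    rate_hz
        Sampling rate in Hz.
    range_g
        Operating range of the sensor in g; samples saturate at ``±range_g``.
    restored_mask
        Optional boolean array of shape ``(n, 3)`` flagging samples that were
        replaced by the restoration algorithm.  ``None`` means no sample was
        touched.
    """

    t: np.ndarray
    a: np.ndarray
    rate_hz: float
    range_g: float
    restored_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValueError("acceleration array must have shape (n, 3)")
        if self.t.shape[0] != self.a.shape[0]:
            raise ValueError("time and acceleration arrays differ in length")
        if self.t.shape[0] < 2:
            raise ValueError("a trace needs at least 2 samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.range_g <= 0:
            raise ValueError("range_g must be positive")
        dt = np.diff(self.t)
        if np.any(np.abs(dt - 1.0 / self.rate_hz) > _DT_TOL_S):
            raise ValueError("sample times are not uniform at rate_hz")
        if self.restored_mask is not None:
            self.restored_mask = np.asarray(self.restored_mask, dtype=bool)
            if self.restored_mask.shape != self.a.shape:
                raise ValueError("restored_mask shape must match acceleration")

    # -- convenience views -------------------------------------------------

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def ax(self) -> np.ndarray:
        return self.a[:, 0]

    @property
    def ay(self) -> np.ndarray:
        """Axial (tibia-aligned) component."""
        return self.a[:, 1]

    @property
    def az(self) -> np.ndarray:
        return self.a[:, 2]

    def axis(self, name: str) -> np.ndarray:
        """Return one axis series by name ('x', 'y' or 'z')."""
        return self.a[:, AXES.index(name)]

    def copy(self) -> "TriaxialTrace":
        return TriaxialTrace(
            t=self.t.copy(),
            a=self.a.copy(),
            rate_hz=self.rate_hz,
            range_g=self.range_g,
            restored_mask=None if self.restored_mask is None else self.restored_mask.copy(),
        )

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "ax_g": self.ax,
                "ay_g": self.ay,
                "az_g": self.az,
            }
        )

    def write(self, path: str | Path, float_format: str = "%.6f") -> None:
        """Write the trace as delimited text with a metadata header line."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# rate_hz={self.rate_hz:g} range_g={self.range_g:g}\n")
            self.to_frame().to_csv(fh, index=False, float_format=float_format)

    @classmethod
    def read(
        cls,
        path: str | Path,
        rate_hz: float | None = None,
        range_g: float | None = None,
    ) -> "TriaxialTrace":
        """Read a trace written by :meth:`write`.

        ``rate_hz`` / ``range_g`` override or supply metadata for files lacking
        the ``#`` header; the rate falls back to the median sample spacing.
        """
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            m_rate = re.search(r"rate_hz=([\d.eE+-]+)", first)
            m_range = re.search(r"range_g=([\d.eE+-]+)", first)
            if rate_hz is None and m_rate:
                rate_hz = float(m_rate.group(1))
            if range_g is None and m_range:
                range_g = float(m_range.group(1))
        df = pd.read_csv(path, comment="#")
        required = {"time_s", "ax_g", "ay_g", "az_g"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        t = df["time_s"].to_numpy(float)
        if rate_hz is None:
            rate_hz = 1.0 / float(np.median(np.diff(t)))
        if range_g is None:
            raise ValueError(f"{path}: no range_g metadata; pass range_g=")
        # re-grid onto the exact uniform clock to absorb text round-off
        t = t[0] + np.arange(len(t)) / rate_hz
        a = df[["ax_g", "ay_g", "az_g"]].to_numpy(float)
        return cls(t=t, a=a, rate_hz=rate_hz, range_g=range_g)
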