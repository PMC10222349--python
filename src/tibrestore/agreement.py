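"""Agreement statistics: rejection accounting, Bland–Altman limits of
agreement, magnitude stratification, Welch t-tests and Cohen's d.

Bland–Altman analysis summarises method agreement by the mean and SD of the
per-pair differences (test − reference); the 95% limits of agreement (LOA)
are ``mean ± 1.96 · SD``.  Differences here are restored-minus-true peak
values, so a negative mean difference means the restored stream
underestimates the reference.  Cohen's d uses the classical pooled-SD
definition and the conventional bins: trivial (|d| < 0.2), small
(0.2 ≤ |d| < 0.5), medium (0.5 ≤ |d| < 0.8) and large (|d| ≥ 0.8).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .events import MatchedPair

__all__ = [
    "AgreementSummary",
    "EffectResult",
    "reject_restored",
    "select_reference_above",
    "bland_altman",
    "ba_coordinates",
    "stratify_pairs",
    "welch_t_and_d",
    "cohens_d",
    "classify_effect",
]

LOA_MULTIPLIER = 1.96
D_BINS = (0.2, 0.5, 0.8)


@dataclass
class AgreementSummary:
    """Bland–Altman summary for one stratum of matched pairs."""

    stratum: str
    n_pairs: int
    mean_diff_g: float
    sd_diff_g: float
    loa_low_g: float
    loa_high_g: float
    n_rejected: int = 0

    @property
    def pct_rejected(self) -> float:
        denom = self.n_pairs + self.n_rejected
        return 100.0 * self.n_rejected / denom if denom > 0 else 0.0

    @property
    def sd_defined(self) -> bool:
        return np.isfinite(self.sd_diff_g)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pct_rejected"] = self.pct_rejected
        return d


@dataclass
class EffectResult:
    """Per-participant two-sample comparison of one peak kind."""

    participant_id: str
    kind: str
    comparison: str
    p_value: float
    cohens_d: float
    label: str
    n_test: int
    n_ref: int

    def to_dict(self) -> dict:
        return asdict(self)


def _diffs(pairs: Sequence[MatchedPair]) -> np.ndarray:
    return np.array([p.diff_g for p in pairs], dtype=float)


def reject_restored(
    pairs: Sequence[MatchedPair], threshold_g: float = 16.0
) -> tuple[list[MatchedPair], int]:
    """Drop pairs whose restored (test) peak is smaller than the rail.

    A reconstructed peak below the operating range is physically implausible
    — had the true peak been inside the range, no reconstruction would have
    happened — so such peaks are rejected and counted.  The comparison is
    strict: a test value exactly at the threshold is kept.
    """
    kept = [p for p in pairs if p.test_value_g >= threshold_g]
    return kept, len(pairs) - len(kept)


def select_reference_above(
    pairs: Sequence[MatchedPair], floor_g: float = 16.0
) -> list[MatchedPair]:
    """Keep pairs whose reference (true) peak is strictly above ``floor_g``."""
    return [p for p in pairs if p.ref_value_g > floor_g]


def bland_altman(
    pairs: Sequence[MatchedPair],
    stratum: str = "overall",
    loa_multiplier: float = LOA_MULTIPLIER,
    n_rejected: int = 0,
) -> AgreementSummary:
    """Mean, sample SD (n−1) and limits of agreement of the pair differences.

    With fewer than two pairs the SD and LOA are undefined and reported as
    NaN (``sd_defined`` is False on the summary).
    """
    d = _diffs(pairs)
    if d.size == 0:
        return AgreementSummary(stratum, 0, np.nan, np.nan, np.nan, np.nan, n_rejected)
    mean = float(np.mean(d))
    if d.size < 2:
        return AgreementSummary(stratum, 1, mean, np.nan, np.nan, np.nan, n_rejected)
    sd = float(np.std(d, ddof=1))
    return AgreementSummary(
        stratum=stratum,
        n_pairs=int(d.size),
        mean_diff_g=mean,
        sd_diff_g=sd,
        loa_low_g=mean - loa_multiplier * sd,
        loa_high_g=mean + loa_multiplier * sd,
        n_rejected=n_rejected,
    )


def ba_coordinates(pairs: Sequence[MatchedPair]) -> tuple[np.ndarray, np.ndarray]:
    """(mean of pair, difference) coordinates for a Bland–Altman plot."""
    means = np.array([p.mean_g for p in pairs], dtype=float)
    return means, _diffs(pairs)


def stratify_pairs(
    pairs: Sequence[MatchedPair],
    edges_g: Sequence[float] = (16.0, 20.0, 24.0, 28.0),
    loa_multiplier: float = LOA_MULTIPLIER,
) -> dict[str, AgreementSummary]:
    """Bin pairs by reference magnitude into right-open strata and summarise.

    Edges ``(16, 20, 24, 28)`` yield strata [16, 20), [20, 24) and [24, 28);
    pairs at or above the top edge belong to no stratum (they remain in any
    overall summary computed separately).
    """
    edges = list(edges_g)
    if any(b <= a for a, b in zip(edges[:-1], edges[1:])):
        raise ValueError("edges must be strictly increasing")
    out: dict[str, AgreementSummary] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"{lo:g}-{hi:g}"
        members = [p for p in pairs if lo <= p.ref_value_g < hi]
        out[label] = bland_altman(members, stratum=label, loa_multiplier=loa_multiplier)
    return out


def cohens_d(test_values: np.ndarray, ref_values: np.ndarray) -> float:
    """Cohen's d with pooled SD; negative when the test group sits below the
    reference."""
    x = np.asarray(test_values, float)
    y = np.asarray(ref_values, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two values per group")
    s1, s2 = np.var(x, ddof=1), np.var(y, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    delta = float(np.mean(x) - np.mean(y))
    if pooled == 0:
        return 0.0 if delta == 0 else float(np.sign(delta)) * np.inf
    return delta / float(pooled)


def welch_t_and_d(
    test_values: Iterable[float],
    ref_values: Iterable[float],
    participant_id: str = "",
    kind: str = "",
    comparison: str = "",
    equal_var: bool = False,
) -> EffectResult:
    """Two-sample t-test (Welch by default) plus Cohen's d with its label.

    Degenerate input — both groups constant with equal means — yields
    d = 0, p = 1.
    """
    x = np.asarray(list(test_values), float)
    y = np.asarray(list(ref_values), float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two values per group")
    d = cohens_d(x, y)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        p = 1.0 if np.mean(x) == np.mean(y) else 0.0
    else:
        p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
    return EffectResult(
        participant_id=participant_id,
        kind=kind,
        comparison=comparison,
        p_value=p,
        cohens_d=d,
        label=classify_effect(d),
        n_test=int(x.size),
        n_ref=int(y.size),
    )


def classify_effect(d: float) -> str:
    """Label |d| as trivial, small, medium or large."""
    m = abs(d)
    if m < D_BINS[0]:
        return "trivial"
    if m < D_BINS[1]:
        return "small"
    if m < D_BINS[2]:
        return "medium"
    return "large"
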