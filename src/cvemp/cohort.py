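"""Cohort-level statistics: interaural asymmetry, ear agreement, descriptives.

Interaural asymmetry of the amplitude ratio is the signed percentage
``100*(R - L)/(R + L)``; its empirical central band (default 90%, i.e. the
5th-95th percentiles) gives the reference limits for a normal ear pair.
Right-left agreement is quantified with the intraclass correlation
coefficient, defaulting to the one-way random-effects, single-measurement
form ICC(1,1) (ears nested in subjects).  Group-comparison hypothesis tests
are exposed only as thin pass-throughs to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EarPair",
    "AsymmetryLimits",
    "ICCResult",
    "interaural_asymmetry",
    "asymmetry_limits",
    "icc",
    "descriptive_table",
    "compare_groups",
    "DEFAULT_AGE_BANDS",
]


@dataclass(frozen=True)
class EarPair:
    """Right/left amplitude ratios (and thresholds) for one subject and mode."""

    subject_id: str
    mode: str
    right: float | None
    left: float | None
    right_threshold: float | None = None
    left_threshold: float | None = None


@dataclass(frozen=True)
class AsymmetryLimits:
    """Empirical central band of the asymmetry distribution, in percent."""

    mode: str
    lower: float
    upper: float
    coverage: float
    n: int
    quantile_rule: str = "linear interpolation between order statistics (type 7)"

    def __post_init__(self):
        if not -100.0 <= self.lower <= self.upper <= 100.0:
            raise ValueError("asymmetry limits must satisfy -100 <= lower <= upper <= 100")


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    n: int
    form: str = "ICC(1,1) one-way random, single measurement"


def interaural_asymmetry(right: float, left: float) -> float:
    """Signed relative asymmetry ``100*(R - L)/(R + L)`` in percent."""
    right, left = float(right), float(left)
    if right + left <= 0:
        raise ValueError("asymmetry undefined: right + left must be positive")
    return 100.0 * (right - left) / (right + left)


def asymmetry_limits(pairs, mode: str = "AC", coverage: float = 90.0,
                     min_pairs: int = 20) -> AsymmetryLimits:
    """Empirical (coverage/2, 100-coverage/2) percentiles of the asymmetry.

    ``pairs`` is either an iterable of :class:`EarPair` or an (n, 2) array of
    right/left ratios.  The 90% default band reports the 5th and 95th
    percentiles, computed with the type-7 linear-interpolation rule.
    """
    arr = _pairs_to_array(pairs)
    if arr.shape[0] < min_pairs:
        raise ValueError(f"need at least {min_pairs} complete pairs, got {arr.shape[0]}")
    asym = np.array([interaural_asymmetry(r, l) for r, l in arr])
    tail = (100.0 - coverage) / 2.0
    lower, upper = np.percentile(asym, [tail, 100.0 - tail])
    return AsymmetryLimits(mode, float(lower), float(upper), coverage, arr.shape[0])


def _pairs_to_array(pairs) -> np.ndarray:
    if isinstance(pairs, np.ndarray):
        arr = pairs
    else:
        pairs = list(pairs)
        if pairs and isinstance(pairs[0], EarPair):
            arr = np.array([[p.right, p.left] for p in pairs], dtype=float)
        else:
            arr = np.asarray(pairs, dtype=float)
    arr = arr.reshape(-1, 2)
    return arr[np.all(np.isfinite(arr), axis=1)]


def icc(pairs, alpha: float = 0.05, min_pairs: int = 10) -> ICCResult:
    """One-way random-effects intraclass correlation for ear pairs.

    ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW) with k = 2 measurements per
    subject; the confidence interval is the exact F-based interval.
    """
    arr = _pairs_to_array(pairs)
    n, k = arr.shape
    if n < min_pairs:
        raise ValueError(f"need at least {min_pairs} complete pairs, got {n}")
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((arr - row_means[:, None]) ** 2) / (n * (k - 1))
    if msb + msw <= 0:
        raise ValueError("total variance is zero; ICC undefined")
    if msw == 0:
        return ICCResult(1.0, 1.0, 1.0, n)
    f_obs = msb / msw
    est = (f_obs - 1.0) / (f_obs + k - 1.0)
    f_hi = stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    f_lo = stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    fl, fu = f_obs / f_hi, f_obs * f_lo
    return ICCResult(float(est),
                     float((fl - 1.0) / (fl + k - 1.0)),
                     float((fu - 1.0) / (fu + k - 1.0)), n)


#: Yearly bands through childhood, then the adult bands of the published table.
DEFAULT_AGE_BANDS = tuple(float(a) for a in range(0, 17)) + (21.0, 41.0, 62.0)


def descriptive_table(df: pd.DataFrame, age_bands: Sequence[float] = DEFAULT_AGE_BANDS,
                      value_cols: Sequence[str] = ("amplitude_ratio", "p_latency_ms",
                                                   "n_latency_ms", "threshold_dbnhl"),
                      mode_col: str = "mode", age_col: str = "age_years") -> pd.DataFrame:
    """Per-age-band mean/SD/median/min/max of the c-VEMP measures, per mode.

    Bands are half-open ``[a, b)``; empty bands are emitted as missing rows,
    not errors.  Layout mirrors the published characteristics table: one row
    per band, measure x mode x statistic columns.
    """
    edges = list(age_bands)
    if len(edges) < 2:
        raise ValueError("need at least two band edges")
    labels = [f"{lo:g} to <{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
    work = df.copy()
    work["_band"] = pd.cut(work[age_col], bins=edges, right=False, labels=labels)
    stats_ = ["count", "mean", "std", "median", "min", "max"]
    out = (
        work.groupby(["_band", mode_col], observed=False)[list(value_cols)]
        .agg(stats_)
        .unstack(mode_col)
    )
    out.index.name = "age_band"
    # columns: (measure, stat, mode) -> reorder to (measure, mode, stat)
    out = out.reorder_levels([0, 2, 1], axis=1).sort_index(axis=1)
    return out


def compare_groups(x, y, kind: str = "wilcoxon-mann-whitney"):
    """Thin pass-throughs to the standard two-group tests (scipy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind in ("wilcoxon-mann-whitney", "mann-whitney"):
        return stats.mannwhitneyu(x, y, alternative="two-sided")
    if kind == "welch":
        return stats.ttest_ind(x, y, equal_var=False)
    if kind == "paired-t":
        return stats.ttest_rel(x, y)
    raise ValueError(f"unknown test kind: {kind!r}")
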