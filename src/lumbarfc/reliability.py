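"""Split-half temporal stability: ICC(2,1), bootstrap CIs, rating bins.

Each run is split into contiguous halves that are re-analyzed
independently; agreement of an estimate across halves is quantified by the
two-way random-effects, single-measure, absolute-agreement intraclass
correlation

    ICC(2,1) = sigma2_between / (sigma2_between + sigma2_session + sigma2_error)

estimated from the classical ANOVA mean squares with k = 2 sessions.
Negative estimates are reported as computed (not floored), which keeps the
estimator's sampling behavior intact for simulation work; they always rate
as "poor".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .denoise import FmriRun
from .exceptions import DegenerateInputError, InputError

__all__ = [
    "ICCReport",
    "split_half",
    "icc_2_1",
    "icc_bootstrap_ci",
    "rate_icc",
    "split_vs_full_test",
]

logger = logging.getLogger(__name__)

RATING_BINS = (("poor", 0.4), ("fair", 0.6), ("good", 0.75))


@dataclass
class ICCReport:
    icc: float
    sigma2_between: float
    sigma2_session: float
    sigma2_error: float
    rating: str
    n_subjects: int
    n_sessions: int = 2
    ci95: tuple = None


def split_half(run: FmriRun) -> tuple:
    """Contiguous first-half / second-half runs.

    Odd volume counts drop the final volume (logged); fewer than 6 volumes
    is an input error.
    """
    n = run.n_volumes
    if n < 6:
        raise InputError(f"need at least 6 volumes to split, got {n}")
    if n % 2:
        logger.warning("odd volume count %d: dropping the last volume", n)
        n -= 1
    half = n // 2
    return (
        run.copy_with(run.data[..., :half].copy()),
        run.copy_with(run.data[..., half:n].copy()),
    )


def rate_icc(icc: float) -> str:
    """Interpretation bin: poor < 0.4 <= fair < 0.6 <= good < 0.75 <= excellent."""
    if not np.isfinite(icc):
        raise InputError(f"icc must be finite, got {icc}")
    for name, upper in RATING_BINS:
        if icc < upper:
            return name
    return "excellent"


def _mean_squares(values: np.ndarray) -> tuple:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_total = float(((values - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(values: np.ndarray) -> ICCReport:
    """ICC(2,1) from a subjects x sessions table (two sessions = halves).

    Variance components are derived from the two-way ANOVA mean squares:
    sigma2_between = (MSR - MSE)/k, sigma2_session = (MSC - MSE)/n,
    sigma2_error = MSE.
    """
    values = np.asarray(values, float)
    if values.ndim != 2 or values.shape[1] != 2:
        raise InputError("values must be an (n_subjects, 2) table")
    n, k = values.shape
    if n < 3:
        raise InputError(f"need at least 3 subjects, got {n}")
    if not np.all(np.isfinite(values)):
        raise InputError("values must be finite")
    if np.ptp(values) == 0:
        raise DegenerateInputError("zero total variance: ICC undefined")
    msr, msc, mse = _mean_squares(values)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateInputError("degenerate variance structure: ICC undefined")
    icc = (msr - mse) / denom
    return ICCReport(
        icc=float(icc),
        sigma2_between=(msr - mse) / k,
        sigma2_session=(msc - mse) / n,
        sigma2_error=mse,
        rating=rate_icc(icc),
        n_subjects=n,
    )


def icc_bootstrap_ci(
    values: np.ndarray, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple:
    """Percentile bootstrap CI for ICC(2,1), resampling subjects with
    replacement (sessions stay paired).  Zero-variance resamples are
    skipped and counted."""
    values = np.asarray(values, float)
    if values.ndim != 2 or values.shape[0] < 3:
        raise InputError("values must be an (n_subjects >= 3, 2) table")
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    estimates = []
    n_skipped = 0
    for _ in range(n_boot):
        sample = values[rng.integers(0, n, size=n)]
        try:
            estimates.append(icc_2_1(sample).icc)
        except DegenerateInputError:
            n_skipped += 1
    if not estimates:
        raise DegenerateInputError("every bootstrap resample was degenerate")
    if n_skipped:
        logger.warning("%d degenerate bootstrap resamples skipped", n_skipped)
    lo, hi = np.percentile(estimates, [50 * (1 - level), 50 * (1 + level)])
    return float(lo), float(hi)


def split_vs_full_test(half1: dict, half2: dict, full: dict) -> pd.DataFrame:
    """Kruskal-Wallis comparison of half-1, half-2, and full-run FC value
    distributions, one row per connectivity pattern."""
    rows = []
    for pattern in full:
        groups = [np.asarray(d[pattern], float) for d in (half1, half2, full)]
        for g in groups:
            if g.size < 5:
                raise InputError(
                    f"pattern {pattern}: need >= 5 subjects per group"
                )
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            raise DegenerateInputError(
                f"pattern {pattern}: all values identical (ties only)"
            )
        h, p = scipy.stats.kruskal(*groups)
        rows.append(dict(pattern=pattern, kruskal_h=float(h), p=float(p)))
    return pd.DataFrame(rows)
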