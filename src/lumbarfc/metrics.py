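"""Signal-quality metrics per denoising pipeline.

Temporal SNR (voxel temporal mean over temporal standard deviation, with
ROI averages), explained variance R^2 of a denoising step relative to the
filtered-only baseline, the regressor-count-adjusted R^2, and the
across-pipeline statistical comparisons (Welch's unequal-variance t-test
with Benjamini-Hochberg correction, plus a Kolmogorov-Smirnov normality
screen whose rejection motivates the Welch choice).

Note on the baseline: R^2 is measured against the band-pass-filtered,
regressor-free (Baseline pipeline) time series, so R^2 quantifies variance
attributable to nuisance regressors rather than to the temporal filter,
and R^2(Baseline) = 0 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ROI_NAMES, MaskSet
from .denoise import FmriRun
from .exceptions import DegenerateInputError, InputError, ParameterError

__all__ = [
    "QualityReport",
    "tsnr",
    "explained_variance",
    "adjusted_r2",
    "pipeline_comparison",
]


@dataclass
class QualityReport:
    """Per-subject signal-quality summary for one pipeline."""

    tsnr_map: np.ndarray = None
    roi_tsnr: dict = field(default_factory=dict)
    r2: float = np.nan
    adj_r2: float = np.nan
    n: int = 0
    k: int = 0
    n_excluded_voxels: int = 0


def tsnr(run: FmriRun, masks: MaskSet) -> QualityReport:
    """Voxelwise temporal SNR map plus horn-ROI averages.

    Voxels with zero temporal standard deviation are excluded (NaN in the
    map) with a warning; ROI averages ignore them.
    """
    mean = run.data.mean(axis=3)
    sd = run.data.std(axis=3)
    tsnr_map = np.full(mean.shape, np.nan)
    ok = sd > 0
    tsnr_map[ok] = mean[ok] / sd[ok]
    cord = masks.cord
    n_excluded = int(np.sum(cord & ~ok))
    if n_excluded:
        warnings.warn(
            f"{n_excluded} cord voxel(s) with zero temporal std excluded from tSNR",
            RuntimeWarning,
            stacklevel=2,
        )
    roi_vals = {}
    for name in ROI_NAMES:
        m = masks.roi(name)
        vals = tsnr_map[m]
        roi_vals[name] = float(np.nanmean(vals)) if m.any() else np.nan
    return QualityReport(
        tsnr_map=tsnr_map,
        roi_tsnr=roi_vals,
        n=run.n_volumes,
        n_excluded_voxels=n_excluded,
    )


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Penalize R^2 for the k regressors spent: 1 - (1-R^2)(n-1)/(n-k-1)."""
    if n <= k + 1:
        raise ParameterError(f"need n > k + 1 (n={n}, k={k})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def explained_variance(
    baseline: FmriRun, denoised: FmriRun, masks: MaskSet, k: int
) -> tuple:
    """Fractional variance reduction pooled over the combined-horn mask.

    R^2 = 1 - var(denoised) / var(baseline), where each variance is the
    temporal variance summed over all horn voxels; the adjusted value
    additionally accounts for the k regressors used.
    """
    if baseline.data.shape != denoised.data.shape:
        raise InputError("baseline and denoised runs differ in shape")
    horn = np.zeros(masks.labels.shape, bool)
    for name in ROI_NAMES:
        horn |= masks.roi(name)
    if not horn.any():
        raise InputError("combined horn mask is empty")
    n = baseline.n_volumes
    if n <= k + 1:
        raise ParameterError(f"need n > k + 1 (n={n}, k={k})")
    var_base = float(baseline.data[horn].var(axis=1).sum())
    var_den = float(denoised.data[horn].var(axis=1).sum())
    if var_base == 0:
        raise DegenerateInputError("baseline variance is zero in the horn mask")
    r2 = 1.0 - var_den / var_base
    return r2, adjusted_r2(r2, n, k)


def pipeline_comparison(
    metric_by_pipeline: dict,
    ordering,
    mode: str = "sequential",
    baseline: str = "Baseline",
    alpha: float = 0.05,
) -> tuple:
    """Welch t-tests across denoising pipelines plus a normality screen.

    ``mode="sequential"`` compares each pipeline against the previous,
    less complex one in ``ordering`` (the convention for explained
    variance); ``mode="vs_baseline"`` compares every pipeline against the
    ``baseline`` entry (the convention for temporal SNR).  P-values are
    Benjamini-Hochberg corrected.  Returns ``(tests, normality)`` data
    frames.
    """
    ordering = list(ordering)
    for name in ordering:
        vals = np.asarray(metric_by_pipeline[name], float)
        if vals.size < 2:
            raise DegenerateInputError(f"pipeline {name}: need >= 2 subjects")

    if mode == "sequential":
        pairs = list(zip(ordering[1:], ordering[:-1]))
    elif mode == "vs_baseline":
        pairs = [(name, baseline) for name in ordering if name != baseline]
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    rows = []
    for a, b in pairs:
        va = np.asarray(metric_by_pipeline[a], float)
        vb = np.asarray(metric_by_pipeline[b], float)
        t, p = scipy.stats.ttest_ind(va, vb, equal_var=False)
        rows.append(
            dict(pipeline=a, reference=b,
                 mean=float(va.mean()), ref_mean=float(vb.mean()),
                 welch_t=float(t), p=float(p))
        )
    tests = pd.DataFrame(rows)
    reject, p_corr, _, _ = multipletests(tests["p"], alpha=alpha, method="fdr_bh")
    tests["p_bh"] = p_corr
    tests["significant"] = reject

    # KS screen with sample-estimated parameters (Lilliefors caveat: the
    # plain KS p-value is conservative when mean/sd come from the sample).
    norm_rows = []
    for name in ordering:
        v = np.asarray(metric_by_pipeline[name], float)
        sd = v.std(ddof=1)
        if sd == 0:
            norm_rows.append(dict(pipeline=name, ks_stat=np.nan, ks_p=np.nan))
            continue
        stat, p = scipy.stats.kstest(v, "norm", args=(v.mean(), sd))
        norm_rows.append(dict(pipeline=name, ks_stat=float(stat), ks_p=float(p)))
    return tests, pd.DataFrame(norm_rows)
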