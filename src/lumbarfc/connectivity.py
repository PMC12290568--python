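"""Slice-wise ROI-to-ROI and ROI-to-voxel functional connectivity.

The four gray-matter horn ROIs per slice (ventral-left/right, dorsal-
left/right) give one 4x4 Pearson correlation matrix per slice; averaging
raw coefficients over slices yields the subject matrix, summarized by the
four canonical patterns: ventral-ventral (VV), dorsal-dorsal (DD), within-
hemicord (W: ipsilateral ventral-dorsal pairs), and between-hemicord (B:
contralateral ventral-dorsal pairs).  Group significance per pattern uses
a Wilcoxon signed-rank test against zero median with Benjamini-Hochberg
correction across the four patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .denoise import FmriRun
from .exceptions import DegenerateInputError, InputError

__all__ = [
    "MaskSet",
    "FCResult",
    "ROI_NAMES",
    "LABEL_CODES",
    "PATTERNS",
    "roi_timecourses",
    "slice_fc",
    "fc_group_test",
    "roi_to_voxel_map",
]

logger = logging.getLogger(__name__)

ROI_NAMES = ("VL", "VR", "DL", "DR")
#: integer codes in the label volume
LABEL_CODES = {"VL": 1, "VR": 2, "DL": 3, "DR": 4, "cord_other": 5, "CSF": 6}

#: pattern -> list of (row, col) index pairs in the 4x4 matrix, averaged
PATTERNS = {
    "VV": [(0, 1)],
    "DD": [(2, 3)],
    "W": [(0, 2), (1, 3)],
    "B": [(0, 3), (1, 2)],
}


@dataclass
class MaskSet:
    """Labeled mask volume: horn ROIs, remaining cord tissue, and CSF.

    A single integer label array (codes in :data:`LABEL_CODES`) makes the
    ROIs pairwise disjoint by construction; validation additionally checks
    that distinct horn ROIs keep a one-voxel in-plane gap and that every
    horn is represented.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InputError("mask labels must be a 3-D volume (x, y, slice)")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[2]

    def roi(self, name: str, slice_index: int = None) -> np.ndarray:
        """Boolean mask for one labeled region (whole volume or one slice)."""
        code = LABEL_CODES[name]
        m = self.labels == code
        return m if slice_index is None else m[:, :, slice_index]

    @property
    def cord(self) -> np.ndarray:
        return (self.labels >= 1) & (self.labels <= 5)

    @property
    def csf(self) -> np.ndarray:
        return self.labels == LABEL_CODES["CSF"]

    def missing_labels(self) -> list:
        present = set(np.unique(self.labels))
        return [
            name
            for name in ("VL", "VR", "DL", "DR", "CSF")
            if LABEL_CODES[name] not in present
        ]

    def validate(self) -> None:
        missing = self.missing_labels()
        if missing:
            raise InputError(f"mask is missing labels: {', '.join(missing)}")
        struct = np.ones((3, 3), bool)  # 8-connected in-plane dilation
        for s in range(self.n_slices):
            horns = [self.roi(n, s) for n in ROI_NAMES]
            for i in range(4):
                if not horns[i].any():
                    continue
                grown = scipy.ndimage.binary_dilation(horns[i], structure=struct)
                for j in range(4):
                    if j != i and np.any(grown & horns[j]):
                        raise InputError(
                            f"horn ROIs {ROI_NAMES[i]} and {ROI_NAMES[j]} touch "
                            f"in slice {s} (need a one-voxel gap)"
                        )


@dataclass
class FCResult:
    """Functional connectivity of one subject under one pipeline."""

    slice_matrices: np.ndarray  # (n_slices, 4, 4), NaN for excluded slices
    subject_matrix: np.ndarray  # (4, 4) mean over valid slices
    patterns: dict  # VV, DD, W, B

    @property
    def n_valid_slices(self) -> int:
        return int(np.sum(~np.isnan(self.slice_matrices[:, 0, 0])))


def pattern_summaries(matrix: np.ndarray) -> dict:
    """VV/DD/W/B summaries of a 4x4 horn correlation matrix."""
    return {
        name: float(np.mean([matrix[i, j] for i, j in pairs]))
        for name, pairs in PATTERNS.items()
    }


def roi_timecourses(run: FmriRun, masks: MaskSet) -> np.ndarray:
    """Unweighted ROI-mean time courses, shape (n_slices, 4, n_volumes).

    Slices where an ROI is empty are filled with NaN and logged; if an ROI
    is empty in every slice, that is an input error.
    """
    if masks.labels.shape != run.data.shape[:3]:
        raise InputError("mask shape does not match the run")
    out = np.full((run.n_slices, 4, run.n_volumes), np.nan)
    any_valid = np.zeros(4, bool)
    for s in range(run.n_slices):
        for r, name in enumerate(ROI_NAMES):
            m = masks.roi(name, s)
            if not m.any():
                logger.info("slice %d: ROI %s empty, skipped", s, name)
                continue
            out[s, r] = run.data[:, :, s, :][m].mean(axis=0)
            any_valid[r] = True
    if not any_valid.all():
        bad = [ROI_NAMES[r] for r in range(4) if not any_valid[r]]
        raise InputError(f"ROI(s) empty in every slice: {', '.join(bad)}")
    return out


def slice_fc(timecourses: np.ndarray) -> FCResult:
    """Per-slice Pearson 4x4 matrices and their raw average over slices.

    Slices containing a NaN or zero-variance course are excluded from the
    average (logged).  No Fisher transform is applied at this stage.
    """
    tc = np.asarray(timecourses, float)
    if tc.ndim != 3 or tc.shape[1] != 4:
        raise InputError("timecourses must be (n_slices, 4, n_volumes)")
    if tc.shape[2] < 3:
        raise InputError("need at least 3 time points for a correlation")
    n_slices = tc.shape[0]
    mats = np.full((n_slices, 4, 4), np.nan)
    for s in range(n_slices):
        block = tc[s]
        if np.any(np.isnan(block)) or np.any(block.std(axis=1) == 0):
            logger.info("slice %d excluded from FC average", s)
            continue
        mats[s] = np.corrcoef(block)
    valid = ~np.isnan(mats[:, 0, 0])
    if not valid.any():
        raise DegenerateInputError("no slice yielded a valid correlation matrix")
    subject = mats[valid].mean(axis=0)
    return FCResult(mats, subject, pattern_summaries(subject))


def fc_group_test(pattern_values: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Group-level one-sample Wilcoxon signed-rank tests per FC pattern.

    ``pattern_values`` maps pattern name -> per-subject correlation values.
    P-values are Benjamini-Hochberg corrected across patterns.  A
    Kolmogorov-Smirnov normality screen is run on the Fisher z-transformed
    values (screening only; the test itself uses raw correlations).
    """
    rows = []
    for name, vals in pattern_values.items():
        vals = np.asarray(vals, float)
        if vals.size < 5:
            raise InputError(f"pattern {name}: need >= 5 subjects, got {vals.size}")
        if np.all(vals == 0):
            raise DegenerateInputError(f"pattern {name}: all values are zero")
        stat, p = scipy.stats.wilcoxon(vals)
        z = np.arctanh(np.clip(vals, -0.999999, 0.999999))
        ks_stat, ks_p = scipy.stats.kstest(z, "norm", args=(z.mean(), z.std(ddof=1)))
        rows.append(
            dict(pattern=name, n=vals.size, median_r=float(np.median(vals)),
                 wilcoxon_stat=float(stat), p=float(p),
                 ks_stat_fisher_z=float(ks_stat), ks_p_fisher_z=float(ks_p))
        )
    table = pd.DataFrame(rows)
    reject, p_corr, _, _ = multipletests(table["p"], alpha=alpha, method="fdr_bh")
    table["p_bh"] = p_corr
    table["significant"] = reject
    return table


def roi_to_voxel_map(
    run: FmriRun, masks: MaskSet, roi: str, slice_index: int
) -> np.ndarray:
    """Pearson correlation of the seed-ROI mean course with every voxel in
    one slice.  Returns a 2-D map; zero-variance voxels are NaN; the seed's
    own voxels are included (flag them via ``masks.roi(roi, slice_index)``).
    """
    seed_mask = masks.roi(roi, slice_index)
    if not seed_mask.any():
        raise InputError(f"ROI {roi} is empty in slice {slice_index}")
    data = run.data[:, :, slice_index, :]
    seed = data[seed_mask].mean(axis=0)
    seed_sd = seed.std()
    if seed_sd == 0:
        raise DegenerateInputError("seed time course has zero variance")
    seed_c = seed - seed.mean()
    vox = data.reshape(-1, run.n_volumes)
    vox_c = vox - vox.mean(axis=1, keepdims=True)
    sd = vox_c.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vox_c @ seed_c) / (run.n_volumes * sd * seed_sd)
    r[sd == 0] = np.nan
    return r.reshape(data.shape[:2])
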