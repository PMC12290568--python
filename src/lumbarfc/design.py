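"""Non-physiological nuisance components and the named pipeline registry.

Builds the CSF regressor (mean of the most variable CSF voxels), CompCor
principal-component regressors from the CSF compartment, demeaned in-plane
motion regressors, and framewise displacement; and assembles the twelve
named denoising pipelines (from no denoising at all up to the full
40-regressor model) as per-slice labeled design matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .denoise import FmriRun
from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
    InternalConsistencyError,
    ParameterError,
)
from .physio import SliceDesign

__all__ = [
    "MotionTrace",
    "PipelineConfig",
    "FDReport",
    "PIPELINES",
    "PIPELINE_ORDER",
    "get_pipeline",
    "csf_regressor",
    "compcor_regressors",
    "motion_regressors",
    "framewise_displacement",
    "assemble_design",
]

# columns contributed by each option when enabled
_K_PER_OPTION = {
    "use_csf": 1,
    "use_motion": 2,
    "use_compcor": 5,
    "use_cardiac": 8,
    "use_respiratory": 8,
    "use_interaction": 16,
}


@dataclass(frozen=True)
class MotionTrace:
    """Per-volume in-plane translations (mm), already averaged across
    slices by the upstream motion-correction stage."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, float))
        object.__setattr__(self, "y", np.asarray(self.y, float))
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise InputError("motion x and y must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise InputError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class PipelineConfig:
    """One named denoising pipeline: which nuisance options it includes and
    how many regressors that implies."""

    name: str
    use_csf: bool = False
    use_motion: bool = False
    use_compcor: bool = False
    use_cardiac: bool = False
    use_respiratory: bool = False
    use_interaction: bool = False

    @property
    def expected_k(self) -> int:
        return sum(
            k for flag, k in _K_PER_OPTION.items() if getattr(self, flag)
        )

    @property
    def uses_physio(self) -> bool:
        return self.use_cardiac or self.use_respiratory or self.use_interaction


def _registry() -> dict:
    rows = [
        # name, csf, motion, compcor, cardiac, respiratory, interaction
        ("Baseline", 0, 0, 0, 0, 0, 0),
        ("CSF", 1, 0, 0, 0, 0, 0),
        ("Moco", 0, 1, 0, 0, 0, 0),
        ("CompCor", 0, 0, 1, 0, 0, 0),
        ("Moco + CompCor", 0, 1, 1, 0, 0, 0),
        ("Cardiac", 0, 0, 0, 1, 0, 0),
        ("Respiratory", 0, 0, 0, 0, 1, 0),
        ("PNM", 0, 0, 0, 1, 1, 1),
        ("PNM + CSF", 1, 0, 0, 1, 1, 1),
        ("PNM + Moco", 0, 1, 0, 1, 1, 1),
        ("PNM + Moco + CSF", 1, 1, 0, 1, 1, 1),
        ("All", 1, 1, 1, 1, 1, 1),
    ]
    return {
        name: PipelineConfig(
            name,
            use_csf=bool(c),
            use_motion=bool(m),
            use_compcor=bool(cc),
            use_cardiac=bool(ca),
            use_respiratory=bool(re),
            use_interaction=bool(ix),
        )
        for name, c, m, cc, ca, re, ix in rows
    }


#: The twelve denoising pipelines, in increasing order of complexity.
PIPELINES: dict = _registry()
PIPELINE_ORDER: tuple = tuple(PIPELINES)


def get_pipeline(name: str) -> PipelineConfig:
    try:
        return PIPELINES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown pipeline {name!r}; known: {', '.join(PIPELINE_ORDER)}"
        ) from None


# ---------------------------------------------------------------------------
# nuisance components
# ---------------------------------------------------------------------------


def csf_regressor(run: FmriRun, csf_mask: np.ndarray) -> np.ndarray:
    """Mean time course of the top 10% most temporally variable CSF voxels.

    The voxel count is rounded up, so even a tiny mask contributes at least
    one voxel.
    """
    csf_mask = np.asarray(csf_mask, bool)
    if csf_mask.shape != run.data.shape[:3]:
        raise InputError("csf mask shape does not match the run")
    n = int(csf_mask.sum())
    if n == 0:
        raise InputError("csf mask is empty")
    X = run.data[csf_mask]  # (n_voxels, n_t)
    variances = X.var(axis=1)
    n_top = math.ceil(0.10 * n)
    top = np.argsort(variances)[::-1][:n_top]
    return X[top].mean(axis=0)


def compcor_regressors(run: FmriRun, csf_mask: np.ndarray, k: int = 5) -> np.ndarray:
    """Leading principal-component time courses of the CSF compartment.

    Each CSF voxel time course is linearly detrended and scaled to unit
    variance before the principal-component step; the returned (n_t, k)
    columns are mutually orthogonal, unit-normalized, and ordered by
    explained variance.
    """
    csf_mask = np.asarray(csf_mask, bool)
    if csf_mask.shape != run.data.shape[:3]:
        raise InputError("csf mask shape does not match the run")
    n_vox = int(csf_mask.sum())
    nt = run.n_volumes
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k >= min(n_vox, nt):
        raise ParameterError(
            f"k={k} must be < min(n_csf_voxels={n_vox}, n_volumes={nt})"
        )
    X = scipy.signal.detrend(run.data[csf_mask], axis=1)
    sd = X.std(axis=1)
    keep = sd > 0
    if not np.any(keep):
        raise DegenerateInputError("all CSF voxels are constant")
    X = X[keep] / sd[keep, None]
    u, s, _ = np.linalg.svd(X.T, full_matrices=False)
    return u[:, :k]


def motion_regressors(motion: MotionTrace) -> np.ndarray:
    """Demeaned x/y translation columns, shape (n_volumes, 2)."""
    cols = np.column_stack([motion.x, motion.y])
    return cols - cols.mean(axis=0)


@dataclass(frozen=True)
class FDReport:
    """Framewise displacement series and the exclusion decision."""

    fd: np.ndarray
    mean_fd: float
    exclude: bool
    threshold: float


def framewise_displacement(motion: MotionTrace, threshold: float = 0.4) -> FDReport:
    """FD_t = |dx_t| + |dy_t| over consecutive volumes; a subject is flagged
    for exclusion when the mean FD strictly exceeds ``threshold`` mm."""
    if motion.n_volumes < 2:
        raise DegenerateInputError("need >= 2 volumes to compute FD")
    fd = np.abs(np.diff(motion.x)) + np.abs(np.diff(motion.y))
    mean_fd = float(fd.mean())
    return FDReport(fd=fd, mean_fd=mean_fd, exclude=mean_fd > threshold, threshold=threshold)


# ---------------------------------------------------------------------------
# pipeline assembly
# ---------------------------------------------------------------------------

_PHYSIO_PREFIXES = {
    "use_cardiac": ("card_",),
    "use_respiratory": ("resp_",),
    "use_interaction": ("int_",),
}


def assemble_design(
    config: PipelineConfig,
    pnm=None,
    csf: np.ndarray = None,
    motion: np.ndarray = None,
    compcor: np.ndarray = None,
) -> list:
    """Stack the flagged nuisance components into per-slice designs.

    Column order is fixed: physiological (cardiac, respiratory,
    interaction, slice-specific), then csf, motion, compcor (identical
    across slices).  The total per-slice column count must equal the
    registry's expected count for this pipeline.

    ``pnm`` is the list of full physiological slice designs (one per
    slice); subsets are selected by label.  ``csf`` is a 1-D series,
    ``motion`` an (n, 2) matrix, ``compcor`` an (n, k) matrix.
    """
    if config.uses_physio:
        if pnm is None:
            raise ConfigurationError(
                f"pipeline {config.name!r} needs physiological regressors "
                "but no slice designs were provided"
            )
        n_slices = len(pnm)
        n_vol = pnm[0].n_volumes
    else:
        n_slices = len(pnm) if pnm is not None else 1
        n_vol = None

    prefixes = tuple(
        p
        for flag, pref in _PHYSIO_PREFIXES.items()
        if getattr(config, flag)
        for p in pref
    )

    shared_cols, shared_labels = [], []
    if config.use_csf:
        if csf is None:
            raise ConfigurationError(f"pipeline {config.name!r} needs a csf regressor")
        csf = np.asarray(csf, float)
        shared_cols.append(csf[:, None])
        shared_labels.append("csf")
    if config.use_motion:
        if motion is None:
            raise ConfigurationError(f"pipeline {config.name!r} needs motion regressors")
        motion = np.asarray(motion, float)
        shared_cols.append(motion)
        shared_labels += ["motion_x", "motion_y"]
    if config.use_compcor:
        if compcor is None:
            raise ConfigurationError(f"pipeline {config.name!r} needs compcor regressors")
        compcor = np.asarray(compcor, float)
        shared_cols.append(compcor)
        shared_labels += [f"compcor{j + 1}" for j in range(compcor.shape[1])]

    lengths = {c.shape[0] for c in shared_cols}
    if n_vol is not None:
        lengths.add(n_vol)
    if len(lengths) > 1:
        raise InputError(f"component lengths disagree: {sorted(lengths)}")
    if n_vol is None:
        n_vol = lengths.pop() if lengths else 0

    designs = []
    for s in range(n_slices):
        parts, labels = [], []
        if prefixes:
            sub = pnm[s].select(prefixes)
            parts.append(sub.matrix)
            labels += list(sub.labels)
        if shared_cols:
            parts.append(np.hstack(shared_cols))
            labels += shared_labels
        matrix = np.hstack(parts) if parts else np.empty((n_vol, 0))
        d = SliceDesign(s, matrix, tuple(labels))
        if d.n_regressors != config.expected_k:
            raise InternalConsistencyError(
                f"pipeline {config.name!r}: assembled {d.n_regressors} columns, "
                f"registry expects {config.expected_k}"
            )
        designs.append(d)
    return designs
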