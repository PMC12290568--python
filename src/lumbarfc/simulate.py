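"""Synthetic lumbosacral spinal-cord fMRI cohorts with known ground truth.

Each simulated subject is a 4-D run (default 27 axial slices, 360 volumes
at TR 2.5 s) whose gray-matter horn voxels mix:

* four band-limited (0.01-0.13 Hz) latent "neural" signals whose sample
  correlation matrix equals the subject's realized connectivity exactly
  (the planted matrix perturbed per subject in Fisher-z space and projected
  back to the nearest valid correlation matrix);
* physiological contamination entering through the subject's own slice-wise
  RETROICOR basis (Fourier expansion of simulated cardiac and respiratory
  phases), with independent random mixing weights per voxel;
* a shared CSF latent (also carried, with variable amplitude, by the CSF
  ring voxels) that inflates all pairwise correlations until removed;
* a motion-coupled signal derived from the recorded x/y translation trace;
* white thermal noise.

All component time courses are made mutually sample-orthogonal within each
slice (successive projection) so the per-voxel variance bookkeeping stored
in :class:`SimTruth` is exact, and the fraction of physiological variance
removable by the true RETROICOR design is known.  Geometry is deliberately
schematic: a disk cord mask with four 2x2 quadrant horn ROIs separated by
a >= 1 voxel gap inside an annular CSF ring; no anatomy, no MRI physics,
no simulated image motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import LABEL_CODES, ROI_NAMES, MaskSet
from .denoise import BandSpec, FmriRun, bandpass, default_slice_timing
from .design import MotionTrace
from .exceptions import ParameterError
from .physio import PhaseAssignment, PhysioRecording, build_pnm_design

__all__ = [
    "SimParams",
    "SimTruth",
    "default_fc",
    "nearest_correlation",
    "build_masks",
    "simulate_physio",
    "simulate_subject",
    "simulate_cohort",
]


def default_fc() -> np.ndarray:
    """Planted 4x4 horn correlation matrix (order VL, VR, DL, DR):
    ventral-ventral and dorsal-dorsal 0.3, between-hemicord 0.15,
    within-hemicord 0."""
    vv = dd = 0.3
    b = 0.15
    w = 0.0
    return np.array(
        [
            [1.0, vv, w, b],
            [vv, 1.0, b, w],
            [w, b, 1.0, dd],
            [b, w, dd, 1.0],
        ]
    )


@dataclass
class SimParams:
    """Study conditions for a simulated cohort.

    Defaults reproduce the target acquisition (27 slices, 360 volumes,
    TR 2.5 s, 15 min) with a moderately contaminated noise regime: the
    amplitude weights are standard deviations per voxel relative to the
    unit-variance neural latents.
    """

    n_subjects: int = 20
    n_slices: int = 27
    n_volumes: int = 360
    tr: float = 2.5
    grid_shape: tuple = (16, 16)
    fs_physio: float = 100.0
    heart_rate_mean: float = 70.0  # bpm
    heart_rate_sd: float = 6.0  # bpm, between-subject spread
    resp_rate_mean: float = 0.25  # Hz
    resp_rate_sd: float = 0.03  # Hz
    fc_true: np.ndarray = field(default_factory=default_fc)
    physio_weight: float = 0.6
    csf_weight: float = 0.4
    motion_weight: float = 0.3
    thermal_sd: float = 0.8
    between_subject_fc_sd: float = 0.15
    baseline_intensity: float = 100.0
    motion_step_sd: float = 0.08  # mm per volume, random-walk increments
    seed: int = 0

    def __post_init__(self) -> None:
        self.fc_true = np.asarray(self.fc_true, float)
        for name in ("n_subjects", "n_slices", "n_volumes"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive count")
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        if self.fs_physio < 50:
            raise ParameterError("fs_physio must be >= 50 Hz")
        if self.heart_rate_mean <= 0 or self.resp_rate_mean <= 0:
            raise ParameterError("physiological rates must be positive")
        if self.heart_rate_sd < 0 or self.resp_rate_sd < 0:
            raise ParameterError("rate standard deviations must be >= 0")
        for name in ("physio_weight", "csf_weight", "motion_weight", "thermal_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.between_subject_fc_sd < 0:
            raise ParameterError("between_subject_fc_sd must be >= 0")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 16:
            raise ParameterError("grid_shape must be 2-D with each side >= 16")
        R = self.fc_true
        if R.shape != (4, 4) or not np.allclose(R, R.T):
            raise ParameterError("fc_true must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ParameterError("fc_true must have a unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ParameterError("fc_true must be positive semidefinite")

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr


@dataclass
class SimTruth:
    """Everything the generator knows and downstream stages must recover."""

    subject_index: int
    realized_fc: np.ndarray  # (4, 4) valid correlation matrix
    heart_rate: float  # bpm
    resp_rate: float  # Hz
    beat_times: np.ndarray  # seconds
    resp_cycles: float  # generated respiratory cycle count
    variance_maps: dict  # component -> (nx, ny, nz) per-voxel variance
    seed: int

    def validate(self) -> None:
        if np.linalg.eigvalsh(self.realized_fc).min() < -1e-8:
            raise ParameterError("realized FC is not positive semidefinite")
        for name, v in self.variance_maps.items():
            if np.any(v < -1e-12):
                raise ParameterError(f"negative variance share in {name}")


def _rng(params: SimParams, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([params.seed & 0x7FFFFFFF, subject_index, stream])
    )


# ---------------------------------------------------------------------------
# correlation-matrix utilities
# ---------------------------------------------------------------------------


def nearest_correlation(a: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections."""
    y = np.asarray(a, float).copy()
    ds = np.zeros_like(y)
    for _ in range(max_iter):
        r = y - ds
        vals, vecs = np.linalg.eigh((r + r.T) / 2)
        x = (vecs * np.clip(vals, 0, None)) @ vecs.T
        ds = x - r
        y_new = x.copy()
        np.fill_diagonal(y_new, 1.0)
        if np.max(np.abs(y_new - y)) < tol:
            y = y_new
            break
        y = y_new
    y = (y + y.T) / 2
    np.fill_diagonal(y, 1.0)
    # final PSD guard for numerical round-off
    vals, vecs = np.linalg.eigh(y)
    if vals.min() < 0:
        y = (vecs * np.clip(vals, 1e-12, None)) @ vecs.T
        d = np.sqrt(np.diag(y))
        y = y / np.outer(d, d)
    return y


def _realized_fc(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    iu = np.triu_indices(4, 1)
    z = np.arctanh(np.clip(params.fc_true[iu], -0.999999, 0.999999))
    z = z + rng.normal(0.0, params.between_subject_fc_sd, size=z.size)
    r = np.eye(4)
    r[iu] = np.tanh(z)
    r = r + r.T - np.eye(4)
    return nearest_correlation(r)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def build_masks(params: SimParams) -> MaskSet:
    """Schematic per-slice geometry, identical across slices: a disk cord
    mask (radius 5 voxels) holding four 2x2 quadrant horn ROIs with a
    two-voxel inter-ROI corridor, surrounded by an annular CSF ring."""
    nx, ny = params.grid_shape
    nz = params.n_slices
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dist = np.hypot(xx - cx, yy - cy)
    plane = np.zeros((nx, ny), dtype=np.int16)
    plane[dist <= 5.0] = LABEL_CODES["cord_other"]
    plane[(dist >= 5.5) & (dist <= 7.45)] = LABEL_CODES["CSF"]
    ix = nx // 2
    iy = ny // 2
    left = [ix - 3, ix - 2]
    right = [ix + 1, ix + 2]
    ventral = [iy - 3, iy - 2]
    dorsal = [iy + 1, iy + 2]
    for name, xs, ys in (
        ("VL", left, ventral),
        ("VR", right, ventral),
        ("DL", left, dorsal),
        ("DR", right, dorsal),
    ):
        plane[np.ix_(xs, ys)] = LABEL_CODES[name]
    labels = np.repeat(plane[:, :, None], nz, axis=2)
    masks = MaskSet(labels)
    masks.validate()
    return masks


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------


def _physio_truth(params: SimParams, subject_index: int):
    """Generate traces plus the ground-truth beat times and cycle count."""
    rng = _rng(params, subject_index, 0)
    hr = max(30.0, params.heart_rate_mean + params.heart_rate_sd * rng.standard_normal())
    base_interval = 60.0 / hr
    # within-subject inter-beat jitter: a quarter of the between-subject
    # interval spread, so sd=0 gives strictly metronomic beats
    jitter_sd = 0.25 * 60.0 * params.heart_rate_sd / params.heart_rate_mean**2
    duration = params.duration + 2.0
    n_est = int(duration / base_interval * 1.5) + 10
    intervals = base_interval + jitter_sd * rng.standard_normal(n_est)
    intervals = np.clip(intervals, 0.3, 3.0)
    beats = 0.35 + np.concatenate(([0.0], np.cumsum(intervals)))
    beats = beats[beats < duration - 0.2]

    fs = params.fs_physio
    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs
    cardiac = np.zeros(n_samples)
    width = 0.3  # raised-cosine pulse width, s
    half = int(round(width / 2 * fs))
    for tb in beats:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n_samples, c + half + 1)
        cardiac[lo:hi] += 0.5 * (1.0 + np.cos(2.0 * np.pi * (t[lo:hi] - tb) / width))

    rr = max(0.05, params.resp_rate_mean + params.resp_rate_sd * rng.standard_normal())
    coarse_t = np.arange(0.0, duration + 10.0, 10.0)
    coarse = rng.standard_normal(coarse_t.size)
    fm = np.interp(t, coarse_t, coarse)
    f_inst = np.clip(rr * (1.0 + 0.08 * fm), 0.01, None)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
    respiratory = np.sin(phase)
    cycles = float((phase[-1] - phase[0]) / (2.0 * np.pi))

    triggers = np.arange(params.n_volumes) * params.tr
    rec = PhysioRecording(
        fs=fs, cardiac=cardiac, respiratory=respiratory, trigger_times=triggers
    )
    return rec, beats, cycles, hr, rr


def simulate_physio(params: SimParams, subject_index: int) -> PhysioRecording:
    """Quasi-periodic pulse waveform + slowly varying respiratory trace with
    one scanner trigger per volume.  Deterministic for a fixed seed."""
    return _physio_truth(params, subject_index)[0]


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------


def _demean(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def _residualize(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove the sample projection of each column of x onto span(basis)."""
    if basis.size == 0:
        return x
    beta, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ beta


def _unit_sd(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return x / sd


def simulate_subject(params: SimParams, subject_index: int):
    """Simulate one subject.

    Returns ``(run, masks, recording, motion, truth)``.
    """
    recording, beats, cycles, hr, rr = _physio_truth(params, subject_index)
    masks = build_masks(params)
    rng_fc = _rng(params, subject_index, 1)
    rng_vox = _rng(params, subject_index, 2)
    rng_mot = _rng(params, subject_index, 3)

    nt = params.n_volumes
    fs_img = 1.0 / params.tr
    band = BandSpec(0.01, 0.13)

    realized = _realized_fc(params, rng_fc)

    # motion trace: slow in-plane random walk (mean FD ~ 0.13 mm by default)
    steps = rng_mot.normal(0.0, params.motion_step_sd, size=(nt, 2))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    motion = MotionTrace(x=walk[:, 0], y=walk[:, 1])

    # shared structured signals, successively sample-orthogonalized;
    # the subject-specific CSF gain gives the CSF compartment a stable
    # per-subject amplitude (what its split-half PSD reliability measures)
    csf_gain = rng_vox.uniform(0.7, 1.4)
    csf_lat = bandpass(rng_vox.standard_normal(nt), BandSpec(0.01, 0.15), fs_img)
    csf_lat = _unit_sd(_demean(csf_lat[:, None]))[:, 0] * csf_gain

    mot_cols = _demean(walk.copy())
    mot_cols = _residualize(mot_cols, csf_lat[:, None])
    mot_cols = _unit_sd(_demean(mot_cols))

    latents = bandpass(rng_vox.standard_normal((nt, 4)), band, fs_img)
    latents = _residualize(_demean(latents), np.column_stack([csf_lat, mot_cols]))
    cov = latents.T @ latents / nt
    latents = latents @ np.linalg.inv(np.linalg.cholesky(cov)).T
    latents = latents @ np.linalg.cholesky(realized).T  # sample corr == realized

    # slice-wise RETROICOR basis from the true beat times and belt trace
    phases = PhaseAssignment(recording, beats)
    slice_timing = default_slice_timing(params.n_slices, params.tr)
    onsets = np.arange(nt) * params.tr
    slice_times = onsets[None, :] + slice_timing[:, None]
    pnm = build_pnm_design(phases, slice_times, 4, 4, 2)

    nx, ny = params.grid_shape
    data = np.zeros((nx, ny, params.n_slices, nt))
    var_maps = {
        name: np.zeros((nx, ny, params.n_slices))
        for name in ("neural", "physio", "csf", "motion", "thermal")
    }
    shared = np.column_stack([latents, csf_lat, mot_cols])  # 7 columns

    horn_codes = [LABEL_CODES[n] for n in ROI_NAMES]
    plane_labels = masks.labels[:, :, 0]
    tissue_idx = np.argwhere((plane_labels >= 1) & (plane_labels <= 5))
    csf_idx = np.argwhere(plane_labels == LABEL_CODES["CSF"])
    n_tissue, n_csf = len(tissue_idx), len(csf_idx)
    roi_of_tissue = np.array(
        [
            horn_codes.index(plane_labels[i, j]) if plane_labels[i, j] in horn_codes else -1
            for i, j in tissue_idx
        ]
    )

    for s in range(params.n_slices):
        basis = _demean(pnm[s].matrix)
        basis_o = _residualize(basis, shared)

        w = rng_vox.standard_normal((basis_o.shape[1], n_tissue))
        physio_sig = _unit_sd(basis_o @ w) * params.physio_weight

        wm = rng_vox.standard_normal((2, n_tissue))
        motion_sig = _unit_sd(mot_cols @ wm) * params.motion_weight

        span = np.column_stack([shared, basis_o])
        thermal = rng_vox.standard_normal((nt, n_tissue + n_csf))
        thermal = _unit_sd(_residualize(_demean(thermal), span)) * params.thermal_sd

        vox = np.zeros((nt, n_tissue + n_csf))
        vox[:, :n_tissue] = physio_sig + params.csf_weight * csf_lat[:, None] + motion_sig
        neural_var = np.zeros(n_tissue)
        for v in range(n_tissue):
            r = roi_of_tissue[v]
            if r >= 0:
                vox[:, v] += latents[:, r]
                neural_var[v] = latents[:, r].var()
        amp = rng_vox.uniform(0.6, 1.6, size=n_csf)
        vox[:, n_tissue:] = amp[None, :] * csf_lat[:, None]
        vox += thermal

        for v, (i, j) in enumerate(tissue_idx):
            data[i, j, s, :] = params.baseline_intensity + vox[:, v]
            var_maps["neural"][i, j, s] = neural_var[v]
            var_maps["physio"][i, j, s] = physio_sig[:, v].var()
            var_maps["csf"][i, j, s] = (params.csf_weight * csf_lat).var()
            var_maps["motion"][i, j, s] = motion_sig[:, v].var()
            var_maps["thermal"][i, j, s] = thermal[:, v].var()
        for v, (i, j) in enumerate(csf_idx):
            data[i, j, s, :] = params.baseline_intensity + vox[:, n_tissue + v]
            var_maps["csf"][i, j, s] = (amp[v] * csf_lat).var()
            var_maps["thermal"][i, j, s] = thermal[:, n_tissue + v].var()

    run = FmriRun(data=data, tr=params.tr, slice_timing=slice_timing)
    truth = SimTruth(
        subject_index=subject_index,
        realized_fc=realized,
        heart_rate=hr,
        resp_rate=rr,
        beat_times=beats,
        resp_cycles=cycles,
        variance_maps=var_maps,
        seed=params.seed,
    )
    truth.validate()
    return run, masks, recording, motion, truth


def simulate_cohort(params: SimParams):
    """Yield ``(run, masks, recording, motion, truth)`` per subject."""
    for i in range(params.n_subjects):
        yield simulate_subject(params, i)
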