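"""File formats and manifests.

Images travel as NIfTI-1 (data 4-D, masks as integer label volumes),
physiological recordings as tab-separated values with a JSON sidecar
(``SamplingFrequency``, ``StartTime``, ``Columns``), motion as two-column
plain text (x_mm, y_mm per volume), and simulation ground truth as JSON.
Voxel indices are 0-based; the slice axis is the third array axis and time
the fourth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .connectivity import MaskSet
from .denoise import FmriRun
from .design import MotionTrace
from .exceptions import LoadError
from .physio import PhysioRecording
from .simulate import SimParams, SimTruth, simulate_subject

__all__ = [
    "RunManifest",
    "save_run", "load_nifti_run",
    "save_masks", "load_masks",
    "save_physio", "load_physio",
    "save_motion", "load_motion",
    "save_truth", "load_truth",
    "load_run",
    "write_cohort",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_run(run: FmriRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), _affine(run.voxel_size))
    img.header.set_zooms(tuple(run.voxel_size) + (run.tr,))
    nib.save(img, str(path))


def load_nifti_run(path, tr: float, slice_timing=None) -> FmriRun:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # noqa: BLE001 - rewrap with the field name
        raise LoadError(f"fmri: cannot read {path}: {exc}") from exc
    if data.ndim != 4:
        raise LoadError(f"fmri: expected a 4-D image, got shape {data.shape}")
    zooms = img.header.get_zooms()
    return FmriRun(
        data=data,
        tr=tr,
        slice_timing=slice_timing,
        voxel_size=tuple(float(z) for z in zooms[:3]),
    )


def save_masks(masks: MaskSet, path, voxel_size=(1.1, 1.1, 3.0)) -> None:
    img = nib.Nifti1Image(masks.labels.astype(np.int16), _affine(voxel_size))
    nib.save(img, str(path))


def load_masks(path) -> MaskSet:
    try:
        labels = np.asarray(nib.load(str(path)).dataobj).astype(int)
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"masks: cannot read {path}: {exc}") from exc
    masks = MaskSet(labels)
    missing = masks.missing_labels()
    if missing:
        raise LoadError(f"masks: missing labels: {', '.join(missing)}")
    return masks


def save_physio(recording: PhysioRecording, path) -> None:
    """Write a 4-column TSV (time_s, cardiac, respiratory, trigger) plus a
    JSON sidecar next to it."""
    path = Path(path)
    t = recording.times
    trigger = np.zeros(recording.n_samples, int)
    idx = np.clip(
        np.round(recording.trigger_times * recording.fs).astype(int),
        0,
        recording.n_samples - 1,
    )
    trigger[idx] = 1
    cols = np.column_stack([t, recording.cardiac, recording.respiratory, trigger])
    np.savetxt(
        path,
        cols,
        delimiter="\t",
        header="time_s\tcardiac\trespiratory\ttrigger",
        comments="",
        fmt=["%.6f", "%.8g", "%.8g", "%d"],
    )
    sidecar = {
        "SamplingFrequency": recording.fs,
        "StartTime": 0.0,
        "Columns": ["time_s", "cardiac", "respiratory", "trigger"],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_physio(path) -> PhysioRecording:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        fs = float(sidecar["SamplingFrequency"])
        arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"physio: cannot read {path}: {exc}") from exc
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise LoadError(f"physio: expected 4 columns, got shape {arr.shape}")
    trig_idx = np.flatnonzero(arr[:, 3] > 0.5)
    return PhysioRecording(
        fs=fs,
        cardiac=arr[:, 1],
        respiratory=arr[:, 2],
        trigger_times=trig_idx / fs,
    )


def save_motion(motion: MotionTrace, path) -> None:
    np.savetxt(path, np.column_stack([motion.x, motion.y]), fmt="%.6f")


def load_motion(path) -> MotionTrace:
    try:
        arr = np.loadtxt(path, ndmin=2)
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"motion: cannot read {path}: {exc}") from exc
    if arr.shape[1] != 2:
        raise LoadError(f"motion: expected 2 columns, got {arr.shape[1]}")
    return MotionTrace(x=arr[:, 0], y=arr[:, 1])


def save_truth(truth: SimTruth, path) -> None:
    payload = {
        "subject_index": truth.subject_index,
        "realized_fc": truth.realized_fc.tolist(),
        "heart_rate": truth.heart_rate,
        "resp_rate": truth.resp_rate,
        "beat_times": truth.beat_times.tolist(),
        "resp_cycles": truth.resp_cycles,
        "seed": truth.seed,
        "mean_component_variance": {
            name: float(v[v > 0].mean()) if np.any(v > 0) else 0.0
            for name, v in truth.variance_maps.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_truth(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"truth: cannot read {path}: {exc}") from exc


@dataclass
class RunManifest:
    """Paths and timing for one subject's inputs."""

    subject: str
    fmri_path: str
    mask_path: str
    physio_path: str
    motion_path: str
    tr: float
    slice_timing: np.ndarray = None


def load_run(manifest: RunManifest):
    """Load and cross-validate all of one subject's inputs.

    Returns ``(run, masks, recording, motion)``; any structural mismatch
    raises :class:`LoadError` naming the offending manifest field.
    """
    run = load_nifti_run(manifest.fmri_path, manifest.tr, manifest.slice_timing)
    masks = load_masks(manifest.mask_path)
    if masks.labels.shape != run.data.shape[:3]:
        raise LoadError(
            f"masks: shape {masks.labels.shape} does not match fmri "
            f"{run.data.shape[:3]}"
        )
    recording = load_physio(manifest.physio_path)
    if recording.trigger_times.size != run.n_volumes:
        raise LoadError(
            f"physio: {recording.trigger_times.size} triggers for "
            f"{run.n_volumes} volumes"
        )
    motion = load_motion(manifest.motion_path)
    if motion.n_volumes != run.n_volumes:
        raise LoadError(
            f"motion: length {motion.n_volumes} does not match "
            f"{run.n_volumes} volumes"
        )
    return run, masks, recording, motion


def write_cohort(params: SimParams, outdir) -> list:
    """Simulate and write a cohort to disk; returns the manifests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifests = []
    for i in range(params.n_subjects):
        run, masks, recording, motion, truth = simulate_subject(params, i)
        sub = outdir / f"sub-{i:02d}"
        sub.mkdir(exist_ok=True)
        save_run(run, sub / "func.nii.gz")
        save_masks(masks, sub / "masks.nii.gz", voxel_size=run.voxel_size)
        save_physio(recording, sub / "physio.tsv")
        save_motion(motion, sub / "motion.txt")
        save_truth(truth, sub / "truth.json")
        manifests.append(
            RunManifest(
                subject=f"sub-{i:02d}",
                fmri_path=str(sub / "func.nii.gz"),
                mask_path=str(sub / "masks.nii.gz"),
                physio_path=str(sub / "physio.tsv"),
                motion_path=str(sub / "motion.txt"),
                tr=params.tr,
            )
        )
    return manifests
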