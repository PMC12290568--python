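"""Physiological noise modeling for slice-wise spinal cord fMRI denoising.

Peripheral recordings (photoplethysmograph pulse trace, respiratory belt)
are turned into retrospective-correction (RETROICOR-style) phase estimates:
a cardiac phase that grows linearly from 0 to 2*pi between consecutive
detected heartbeats, and a respiratory phase built by histogram-equalizing
the belt amplitude and signing it with the breathing direction (inhale vs
exhale).  Fourier expansions of those phases, evaluated at each slice's own
acquisition times, give the slice-wise physiological design matrix.

This module also provides the three scalar physiological summary metrics
used for split-half reliability: mean inter-beat interval, respiratory
cycle count from the Hilbert phase of the filtered belt trace, and the mean
power-spectral-density amplitude of the CSF regressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .exceptions import (
    DegenerateInputError,
    InputError,
    ParameterError,
    RangeError,
)

__all__ = [
    "PhysioRecording",
    "PhaseAssignment",
    "SliceDesign",
    "PhysioMetrics",
    "detect_cardiac_peaks",
    "cardiac_phase",
    "respiratory_phase",
    "assign_phases",
    "build_pnm_design",
    "pnm_column_count",
    "physio_metrics",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhysioRecording:
    """Synchronized peripheral physiological traces.

    Parameters
    ----------
    fs : float
        Sampling rate of both traces, Hz.
    cardiac, respiratory : ndarray
        Equal-length amplitude traces sampled uniformly at ``fs``, starting
        at time 0.
    trigger_times : ndarray
        Scanner trigger (volume onset) times in seconds, strictly
        increasing and within the trace duration.
    """

    fs: float
    cardiac: np.ndarray
    respiratory: np.ndarray
    trigger_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cardiac", np.asarray(self.cardiac, float))
        object.__setattr__(self, "respiratory", np.asarray(self.respiratory, float))
        object.__setattr__(self, "trigger_times", np.asarray(self.trigger_times, float))
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.cardiac.ndim != 1 or self.respiratory.ndim != 1:
            raise InputError("cardiac and respiratory traces must be 1-D")
        if self.cardiac.shape != self.respiratory.shape:
            raise InputError(
                "cardiac and respiratory traces must have the same length "
                f"({self.cardiac.size} vs {self.respiratory.size})"
            )
        t = self.trigger_times
        if t.size and (np.any(np.diff(t) <= 0)):
            raise InputError("trigger_times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise InputError("trigger_times must lie within the trace duration")

    @property
    def n_samples(self) -> int:
        return self.cardiac.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.cardiac.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def crop(self, t_start: float, t_stop: float) -> "PhysioRecording":
        """Extract ``[t_start, t_stop)`` as a new recording re-referenced to 0."""
        i0 = int(round(t_start * self.fs))
        i1 = int(round(t_stop * self.fs))
        if not 0 <= i0 < i1 <= self.n_samples:
            raise RangeError(f"crop window [{t_start}, {t_stop}) outside trace")
        keep = (self.trigger_times >= t_start) & (self.trigger_times < t_stop)
        return PhysioRecording(
            fs=self.fs,
            cardiac=self.cardiac[i0:i1].copy(),
            respiratory=self.respiratory[i0:i1].copy(),
            trigger_times=self.trigger_times[keep] - t_start,
        )


@dataclass
class SliceDesign:
    """Nuisance design matrix for one slice: ``n_volumes`` rows, labeled columns."""

    slice_index: int
    matrix: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.labels = tuple(self.labels)
        if self.matrix.ndim != 2:
            raise InputError("design matrix must be 2-D (n_volumes x k)")
        if len(self.labels) != self.matrix.shape[1]:
            raise InputError(
                f"{len(self.labels)} labels for {self.matrix.shape[1]} columns"
            )
        if len(set(self.labels)) != len(self.labels):
            raise InputError("design column labels must be unique")
        if self.matrix.size and not np.all(np.isfinite(self.matrix)):
            raise InputError("design matrix contains non-finite entries")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def select(self, prefixes) -> "SliceDesign":
        """Sub-design keeping columns whose label starts with any prefix,
        preserving the original column order."""
        idx = [
            j
            for j, lab in enumerate(self.labels)
            if any(lab.startswith(p) for p in prefixes)
        ]
        return SliceDesign(
            self.slice_index, self.matrix[:, idx], tuple(self.labels[j] for j in idx)
        )


@dataclass
class PhysioMetrics:
    """Scalar physiological summaries used for reliability analysis."""

    cardiac_interval_mean: float
    resp_zero_crossings: int
    csf_psd_amplitude: float


# ---------------------------------------------------------------------------
# cardiac phase
# ---------------------------------------------------------------------------


def detect_cardiac_peaks(
    recording: PhysioRecording,
    min_rate: float = 40.0,
    max_rate: float = 180.0,
) -> np.ndarray:
    """Detect heartbeat times (s) as local maxima of the pulse trace.

    A minimum inter-peak distance of ``60 / max_rate`` seconds is enforced,
    and peaks must be prominent relative to the trace range, which rejects
    sampling ripple.  Physiologic defaults bound plausible human heart
    rates (40-180 beats per minute).
    """
    if not 0 < min_rate < max_rate:
        raise ParameterError("require 0 < min_rate < max_rate")
    x = recording.cardiac
    if x.size < 2 or np.ptp(x) == 0:
        raise DegenerateInputError("cardiac trace is flat; no peaks found")
    distance = max(1, int(round(recording.fs * 60.0 / max_rate)))
    peaks, _ = scipy.signal.find_peaks(
        x, distance=distance, prominence=0.1 * np.ptp(x)
    )
    if peaks.size == 0:
        raise DegenerateInputError("no cardiac peaks found")
    return peaks / recording.fs


def cardiac_phase(peaks, query_times) -> np.ndarray:
    """Piecewise-linear cardiac phase in [0, 2*pi).

    The phase is 0 at each peak and advances linearly to 2*pi at the next
    peak.  Queries are supported up to two median inter-beat intervals
    before the first / after the last peak (periodic continuation with the
    edge interval, needed when a recording segment starts mid-beat);
    anything beyond raises :class:`RangeError`.
    """
    peaks = np.asarray(peaks, float)
    q = np.atleast_1d(np.asarray(query_times, float))
    if peaks.size < 2:
        raise DegenerateInputError("need at least 2 peaks for a cardiac phase")
    if np.any(np.diff(peaks) <= 0):
        raise InputError("peak times must be strictly increasing")
    intervals = np.diff(peaks)
    med = float(np.median(intervals))
    if np.any(q < peaks[0] - 2 * med) or np.any(q > peaks[-1] + 2 * med):
        raise RangeError(
            "query times outside the supported window "
            f"[{peaks[0] - 2 * med:.3f}, {peaks[-1] + 2 * med:.3f}] s"
        )
    ext = np.concatenate(
        (
            [peaks[0] - 2 * intervals[0], peaks[0] - intervals[0]],
            peaks,
            [peaks[-1] + intervals[-1], peaks[-1] + 2 * intervals[-1]],
        )
    )
    idx = np.clip(np.searchsorted(ext, q, side="right") - 1, 0, ext.size - 2)
    phase = 2.0 * np.pi * (q - ext[idx]) / (ext[idx + 1] - ext[idx])
    out = np.mod(phase, 2.0 * np.pi)
    return out if np.ndim(query_times) else float(out[0])


# ---------------------------------------------------------------------------
# respiratory phase (histogram-equalized amplitude, signed by breath direction)
# ---------------------------------------------------------------------------


def _respiratory_sample_phase(recording: PhysioRecording, n_bins: int = 100) -> np.ndarray:
    x = recording.respiratory
    if np.ptp(x) == 0:
        raise DegenerateInputError("respiratory trace is constant")
    # breathing direction from a lightly smoothed derivative (~0.5 s window)
    win = max(3, int(round(0.5 * recording.fs)))
    kernel = np.ones(win) / win
    xs = np.convolve(x, kernel, mode="same")
    dx = np.gradient(xs)
    hist, edges = np.histogram(x, bins=n_bins)
    cdf = np.cumsum(hist) / x.size
    bins = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    frac = cdf[bins]
    sign = np.where(dx >= 0, 1.0, -1.0)
    return np.mod(np.pi * frac * sign, 2.0 * np.pi)


def respiratory_phase(recording: PhysioRecording, query_times, n_bins: int = 100):
    """Respiratory phase in [0, 2*pi) at the requested times.

    Uses the classic amplitude-histogram equalization: the phase magnitude
    is pi times the empirical CDF of the belt amplitude, and its sign
    encodes inhalation (rising trace) versus exhalation.  The construction
    is invariant to affine rescaling of the belt trace.  Queries are mapped
    to the nearest recorded sample.
    """
    q = np.atleast_1d(np.asarray(query_times, float))
    if np.any(q < 0) or np.any(q > recording.duration):
        raise RangeError("query times outside the recording")
    ph = _respiratory_sample_phase(recording, n_bins=n_bins)
    idx = np.clip(np.round(q * recording.fs).astype(int), 0, recording.n_samples - 1)
    out = ph[idx]
    return out if np.ndim(query_times) else float(out[0])


class PhaseAssignment:
    """Cardiac and respiratory phases evaluable at arbitrary query times.

    Wraps a recording plus detected (or known) beat times; the respiratory
    sample phase is computed once and cached.
    """

    def __init__(self, recording: PhysioRecording, cardiac_peaks):
        self.recording = recording
        self.cardiac_peaks = np.asarray(cardiac_peaks, float)
        if self.cardiac_peaks.size < 2:
            raise DegenerateInputError("need at least 2 cardiac peaks")
        self._resp_phase = _respiratory_sample_phase(recording)

    def cardiac(self, query_times):
        return cardiac_phase(self.cardiac_peaks, query_times)

    def respiratory(self, query_times):
        q = np.atleast_1d(np.asarray(query_times, float))
        if np.any(q < 0) or np.any(q > self.recording.duration):
            raise RangeError("query times outside the recording")
        idx = np.clip(
            np.round(q * self.recording.fs).astype(int),
            0,
            self.recording.n_samples - 1,
        )
        out = self._resp_phase[idx]
        return out if np.ndim(query_times) else float(out[0])


def assign_phases(
    recording: PhysioRecording,
    min_rate: float = 40.0,
    max_rate: float = 180.0,
) -> PhaseAssignment:
    """Detect cardiac peaks and bundle both phase functions."""
    peaks = detect_cardiac_peaks(recording, min_rate=min_rate, max_rate=max_rate)
    return PhaseAssignment(recording, peaks)


# ---------------------------------------------------------------------------
# slice-wise Fourier design
# ---------------------------------------------------------------------------


def pnm_column_count(cardiac_order: int, resp_order: int, interaction_order: int) -> int:
    """Number of physiological regressors: sin/cos per harmonic for each
    phase, plus sum- and difference-phase sin/cos pairs for every cardiac x
    respiratory harmonic combination."""
    return 2 * cardiac_order + 2 * resp_order + 4 * interaction_order**2


def build_pnm_design(
    phases: PhaseAssignment,
    slice_times: np.ndarray,
    cardiac_order: int = 4,
    resp_order: int = 4,
    interaction_order: int = 2,
) -> list:
    """Build the slice-wise physiological design matrices.

    Parameters
    ----------
    phases : PhaseAssignment
    slice_times : ndarray, shape (n_slices, n_volumes)
        Acquisition time of each slice in each volume, seconds.
    cardiac_order, resp_order : int
        Fourier expansion orders (order 4 = base frequency plus the first
        three harmonics, i.e. 8 columns each).
    interaction_order : int
        Order of the multiplicative cardiac-respiratory terms; order 2
        yields 16 columns.

    Returns
    -------
    list of SliceDesign, one per slice, with labeled columns in the order
    cardiac, respiratory, interaction.
    """
    for name, order in (
        ("cardiac_order", cardiac_order),
        ("resp_order", resp_order),
        ("interaction_order", interaction_order),
    ):
        if order < 0 or int(order) != order:
            raise ParameterError(f"{name} must be a nonnegative integer")
    slice_times = np.asarray(slice_times, float)
    if slice_times.ndim != 2:
        raise InputError("slice_times must be (n_slices, n_volumes)")

    designs = []
    for s in range(slice_times.shape[0]):
        t = slice_times[s]
        cols, labels = [], []
        need_card = cardiac_order > 0 or interaction_order > 0
        need_resp = resp_order > 0 or interaction_order > 0
        phc = phases.cardiac(t) if need_card else None
        phr = phases.respiratory(t) if need_resp else None
        for m in range(1, cardiac_order + 1):
            cols += [np.sin(m * phc), np.cos(m * phc)]
            labels += [f"card_sin{m}", f"card_cos{m}"]
        for m in range(1, resp_order + 1):
            cols += [np.sin(m * phr), np.cos(m * phr)]
            labels += [f"resp_sin{m}", f"resp_cos{m}"]
        for m in range(1, interaction_order + 1):
            for n in range(1, interaction_order + 1):
                plus = m * phc + n * phr
                minus = m * phc - n * phr
                cols += [np.sin(plus), np.cos(plus), np.sin(minus), np.cos(minus)]
                labels += [
                    f"int_sin_{m}c+{n}r",
                    f"int_cos_{m}c+{n}r",
                    f"int_sin_{m}c-{n}r",
                    f"int_cos_{m}c-{n}r",
                ]
        matrix = (
            np.column_stack(cols) if cols else np.empty((slice_times.shape[1], 0))
        )
        designs.append(SliceDesign(s, matrix, tuple(labels)))
    return designs


# ---------------------------------------------------------------------------
# physiological summary metrics
# ---------------------------------------------------------------------------


def count_phase_zero_crossings(phase: np.ndarray) -> int:
    """Ascending zero-crossings of a wrapped [-pi, pi] phase trace,
    ignoring the 2*pi wrap jumps."""
    a, b = phase[:-1], phase[1:]
    return int(np.sum((a < 0) & (b >= 0) & (b - a < np.pi)))


def physio_metrics(
    recording: PhysioRecording,
    csf_regressor: np.ndarray,
    csf_fs: float = 0.4,
    min_rate: float = 40.0,
    max_rate: float = 180.0,
) -> PhysioMetrics:
    """Compute the three reliability metrics from one recording segment.

    * cardiac: mean inter-beat interval (s) over detected peaks;
    * respiratory: number of respiratory cycles, counted as ascending
      zero-crossings of the Hilbert phase of the belt trace after a
      0.01-0.6 Hz band-pass and a 1 s median filter;
    * CSF: mean amplitude of the power spectral density of the CSF
      nuisance regressor (sampled at ``csf_fs``, i.e. 1/TR).
    """
    peaks = detect_cardiac_peaks(recording, min_rate=min_rate, max_rate=max_rate)
    if peaks.size < 2:
        raise DegenerateInputError("fewer than 2 cardiac peaks")
    cardiac_interval = float(np.mean(np.diff(peaks)))

    sos = scipy.signal.butter(
        2, [0.01, 0.6], btype="bandpass", fs=recording.fs, output="sos"
    )
    resp = scipy.signal.sosfiltfilt(sos, recording.respiratory)
    kernel = int(round(recording.fs))
    kernel += 1 - kernel % 2  # odd length ~ 1 s
    resp = scipy.signal.medfilt(resp, kernel_size=kernel)
    phase = np.angle(scipy.signal.hilbert(resp))
    crossings = count_phase_zero_crossings(phase)

    csf = np.asarray(csf_regressor, float)
    if csf.ndim != 1 or csf.size < 4:
        raise InputError("csf regressor must be a 1-D series with >= 4 points")
    _, pxx = scipy.signal.periodogram(csf, fs=csf_fs)
    return PhysioMetrics(cardiac_interval, crossings, float(np.mean(pxx)))
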