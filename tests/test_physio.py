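"""Cardiac/respiratory phase assignment and the slice-wise Fourier design."""

import numpy as np
import pytest

from lumbarfc import SimParams, simulate_physio
from lumbarfc.exceptions import DegenerateInputError, RangeError
from lumbarfc.physio import (
    PhaseAssignment,
    PhysioRecording,
    build_pnm_design,
    cardiac_phase,
    detect_cardiac_peaks,
    physio_metrics,
    pnm_column_count,
    respiratory_phase,
)

FS = 100.0


def make_recording(cardiac, respiratory=None, fs=FS, tr=2.5):
    cardiac = np.asarray(cardiac, float)
    if respiratory is None:
        respiratory = np.sin(2 * np.pi * 0.25 * np.arange(cardiac.size) / fs)
    duration = cardiac.size / fs
    triggers = np.arange(0.0, duration - 1e-9, tr)
    return PhysioRecording(
        fs=fs, cardiac=cardiac, respiratory=respiratory, trigger_times=triggers
    )


class TestPeakDetection:
    def test_pure_sinusoid_1hz(self):
        t = np.arange(0.0, 60.0, 1 / FS)
        rec = make_recording(np.sin(2 * np.pi * t))
        peaks = detect_cardiac_peaks(rec)
        assert peaks.size == 60
        assert np.allclose(np.diff(peaks), 1.0, atol=1.5 / FS)
        assert np.allclose(peaks, np.arange(60) + 0.25, atol=1.5 / FS)

    def test_flat_trace_is_degenerate(self):
        rec = make_recording(np.ones(6000))
        with pytest.raises(DegenerateInputError):
            detect_cardiac_peaks(rec)

    def test_recovers_simulated_beats_within_one_sample(self, small_subject):
        _, _, recording, _, truth = small_subject
        peaks = detect_cardiac_peaks(recording)
        # every generated beat has a detected peak within one sample
        for tb in truth.beat_times:
            assert np.min(np.abs(peaks - tb)) <= 1.0 / recording.fs + 1e-9


class TestCardiacPhase:
    def test_zero_at_peak_and_pi_at_midpoint(self):
        peaks = np.array([1.0, 2.0, 3.5])
        assert cardiac_phase(peaks, 2.0) == pytest.approx(0.0)
        assert cardiac_phase(peaks, 1.5) == pytest.approx(np.pi)
        assert cardiac_phase(peaks, 2.75) == pytest.approx(np.pi)

    def test_matches_bruteforce_interval_search(self, rng):
        peaks = np.cumsum(rng.uniform(0.6, 1.4, size=40)) + 5.0
        queries = rng.uniform(peaks[0], peaks[-1], size=200)
        got = cardiac_phase(peaks, queries)
        # independent oracle: explicit scan over intervals
        expected = np.empty_like(queries)
        for i, t in enumerate(queries):
            for k in range(len(peaks) - 1):
                if peaks[k] <= t < peaks[k + 1]:
                    expected[i] = (
                        2 * np.pi * (t - peaks[k]) / (peaks[k + 1] - peaks[k])
                    )
                    break
            else:
                expected[i] = 0.0  # t == last peak
        assert np.allclose(got, expected, atol=1e-12)

    def test_time_shift_invariance(self, rng):
        peaks = np.cumsum(rng.uniform(0.7, 1.3, size=20))
        q = rng.uniform(peaks[0], peaks[-1], size=50)
        shift = 123.456
        assert np.allclose(
            cardiac_phase(peaks, q), cardiac_phase(peaks + shift, q + shift)
        )

    def test_out_of_window_query_raises(self):
        with pytest.raises(RangeError):
            cardiac_phase([1.0, 2.0, 3.0], 100.0)


class TestRespiratoryPhase:
    def test_sinusoid_wraps_once_per_cycle(self):
        t = np.arange(0.0, 60.0, 1 / FS)
        rec = make_recording(np.sin(2 * np.pi * t), np.sin(2 * np.pi * 0.25 * t))
        ph = respiratory_phase(rec, t)
        wraps = int(np.sum(np.diff(ph) < -np.pi))
        assert abs(wraps - 15) <= 1
        # phase advances monotonically within cycles (allowing wrap jumps)
        d = np.diff(ph)
        assert np.mean((d >= -1e-9) | (d < -np.pi)) > 0.99

    def test_amplitude_scale_invariance(self):
        t = np.arange(0.0, 60.0, 1 / FS)
        resp = np.sin(2 * np.pi * 0.3 * t) + 0.2 * np.sin(2 * np.pi * 0.07 * t)
        r1 = make_recording(np.sin(2 * np.pi * t), resp)
        r2 = make_recording(np.sin(2 * np.pi * t), 10.0 * resp)
        q = np.linspace(0.0, 59.0, 77)
        assert np.allclose(respiratory_phase(r1, q), respiratory_phase(r2, q))

    def test_constant_trace_is_degenerate(self):
        rec = make_recording(np.sin(np.arange(600) / FS * 2 * np.pi), np.ones(600))
        with pytest.raises(DegenerateInputError):
            respiratory_phase(rec, [1.0])

    def test_simulated_trace_wrap_count_matches_truth(self, small_subject):
        _, _, recording, _, truth = small_subject
        ph = respiratory_phase(recording, recording.times)
        wraps = int(np.sum(np.diff(ph) < -np.pi))
        assert abs(wraps - truth.resp_cycles) <= 1


@pytest.fixture(scope="module")
def phases():
    t = np.arange(0.0, 120.0, 1 / FS)
    rec = make_recording(np.sin(2 * np.pi * 1.1 * t), np.sin(2 * np.pi * 0.27 * t))
    peaks = detect_cardiac_peaks(rec)
    return PhaseAssignment(rec, peaks)


class TestPnmDesign:

    def test_column_count_formula_exhaustive(self, phases):
        """Column counts for all order combinations 0..6 match an
        independent combinatorial enumeration."""
        slice_times = np.linspace(5.0, 110.0, 30)[None, :]
        for c in range(7):
            for r in range(7):
                for i in range(7):
                    d = build_pnm_design(phases, slice_times, c, r, i)[0]
                    # oracle: enumerate the labels the construction implies
                    n_expected = len(
                        [(m, f) for m in range(1, c + 1) for f in ("s", "c")]
                        + [(m, f) for m in range(1, r + 1) for f in ("s", "c")]
                        + [
                            (m, n, f)
                            for m in range(1, i + 1)
                            for n in range(1, i + 1)
                            for f in ("s+", "c+", "s-", "c-")
                        ]
                    )
                    assert d.n_regressors == n_expected
                    assert pnm_column_count(c, r, i) == n_expected

    def test_columns_bounded(self, phases):
        slice_times = np.linspace(5.0, 110.0, 48).reshape(2, 24)
        for d in build_pnm_design(phases, slice_times, 4, 4, 2):
            assert np.all(np.abs(d.matrix) <= 1.0 + 1e-12)

    def test_empty_design_for_zero_orders(self, phases):
        d = build_pnm_design(phases, np.linspace(5, 110, 10)[None, :], 0, 0, 0)[0]
        assert d.n_regressors == 0
        assert d.matrix.shape == (10, 0)

    def test_cardiac_order1_closed_form(self):
        """With metronomic beats, phase is analytically 2*pi*frac((t-t0)/T)."""
        period = 0.8
        peaks = 0.5 + period * np.arange(80)
        t_trace = np.arange(0.0, 70.0, 1 / FS)
        rec = make_recording(np.cos(2 * np.pi * (t_trace - 0.5) / period))
        phases = PhaseAssignment(rec, peaks)
        q = np.linspace(1.0, 60.0, 33)
        d = build_pnm_design(phases, q[None, :], 1, 0, 0)[0]
        analytic = 2 * np.pi * np.mod((q - 0.5) / period, 1.0)
        assert np.allclose(d.matrix[:, 0], np.sin(analytic), atol=1e-9)
        assert np.allclose(d.matrix[:, 1], np.cos(analytic), atol=1e-9)
        assert d.labels[:2] == ("card_sin1", "card_cos1")

    def test_slice_specific_evaluation(self, phases):
        """Two slices with offset acquisition times get different columns."""
        base = np.linspace(5.0, 100.0, 40)
        designs = build_pnm_design(
            phases, np.vstack([base, base + 1.0]), 4, 4, 2
        )
        assert not np.allclose(designs[0].matrix, designs[1].matrix)


class TestPhysioMetrics:
    def test_metronomic_60bpm_interval(self):
        t = np.arange(0.0, 60.0, 1 / FS)
        rec = make_recording(np.sin(2 * np.pi * t))
        m = physio_metrics(rec, np.ones(24) + np.sin(np.arange(24)))
        assert m.cardiac_interval_mean == pytest.approx(1.0, abs=2 / FS)

    def test_resp_cycle_count_matches_analytic(self):
        """0.25 Hz sinusoid over 60 s: the Hilbert-phase crossing count
        equals the analytic cycle count duration * frequency = 15."""
        t = np.arange(0.0, 60.0, 1 / FS)
        rec = make_recording(np.sin(2 * np.pi * t), np.sin(2 * np.pi * 0.25 * t))
        m = physio_metrics(rec, np.sin(np.arange(24)))
        assert m.resp_zero_crossings == 15

    def test_csf_psd_quadratic_scaling(self, rng):
        t = np.arange(0.0, 30.0, 1 / FS)
        rec = make_recording(np.sin(2 * np.pi * t))
        csf = rng.standard_normal(120)
        m1 = physio_metrics(rec, csf)
        m2 = physio_metrics(rec, 2.0 * csf)
        assert m2.csf_psd_amplitude == pytest.approx(4.0 * m1.csf_psd_amplitude)
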