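"""End-to-end study orchestration: designs, cleaning, metrics, FC,
split-half reliability, and the group-level tables, for a whole cohort.

The in-memory entry points (:func:`subject_designs`, :func:`analyze_subject`,
:func:`run_study_subjects`) operate on domain objects and are what the test
suite exercises; the file-based runner in :mod:`lumbarfc.io`/CLI wraps them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity, design, metrics, physio, reliability
from .denoise import BandSpec, FmriRun, clean
from .design import (
    PIPELINE_ORDER,
    MotionTrace,
    assemble_design,
    framewise_displacement,
    get_pipeline,
)
from .exceptions import StudyError
from .physio import PhysioRecording, assign_phases, build_pnm_design

__all__ = [
    "StudyConfig",
    "SubjectResult",
    "subject_designs",
    "analyze_subject",
    "run_study_subjects",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Declarative analysis configuration with a single seed."""

    band_low: float = 0.01
    band_high: float = 0.13
    pipelines: tuple = PIPELINE_ORDER
    fd_threshold: float = 0.4
    cardiac_order: int = 4
    resp_order: int = 4
    interaction_order: int = 2
    compcor_k: int = 5
    min_heart_rate: float = 40.0
    max_heart_rate: float = 180.0
    filter_method: str = "fft"
    n_boot: int = 1000
    reliability_pipeline: str = "PNM + Moco + CSF"
    seed: int = 0

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.band_low, self.band_high)


@dataclass
class SubjectResult:
    """Per-subject outputs across pipelines (small summaries only)."""

    subject: int
    fc: dict = field(default_factory=dict)  # pipeline -> FCResult
    quality: dict = field(default_factory=dict)  # pipeline -> QualityReport
    fc_halves: dict = field(default_factory=dict)  # pipeline -> (FCResult, FCResult)
    physio_metrics_halves: tuple = None


def subject_designs(
    run: FmriRun,
    masks: connectivity.MaskSet,
    recording: PhysioRecording,
    motion: MotionTrace,
    config: StudyConfig,
) -> dict:
    """Build every requested pipeline's per-slice design for one subject."""
    phases = assign_phases(
        recording, min_rate=config.min_heart_rate, max_rate=config.max_heart_rate
    )
    pnm = build_pnm_design(
        phases,
        run.slice_times(),
        cardiac_order=config.cardiac_order,
        resp_order=config.resp_order,
        interaction_order=config.interaction_order,
    )
    csf = design.csf_regressor(run, masks.csf)
    compcor = design.compcor_regressors(run, masks.csf, k=config.compcor_k)
    mot = design.motion_regressors(motion)
    return {
        name: assemble_design(get_pipeline(name), pnm=pnm, csf=csf, motion=mot, compcor=compcor)
        for name in config.pipelines
    }


def analyze_subject(
    run: FmriRun,
    masks: connectivity.MaskSet,
    recording: PhysioRecording,
    motion: MotionTrace,
    config: StudyConfig = StudyConfig(),
    subject: int = 0,
    split: bool = False,
) -> SubjectResult:
    """Denoise one subject with every pipeline; compute quality metrics and
    slice-averaged FC.  With ``split=True`` the two contiguous halves are
    re-analyzed independently (designs rebuilt per half) for the
    reliability stage, and the per-half physiological metrics recorded."""
    designs = subject_designs(run, masks, recording, motion, config)
    result = SubjectResult(subject=subject)
    baseline = clean(run, None, config.band, method=config.filter_method)
    for name in config.pipelines:
        cfg = get_pipeline(name)
        cleaned = (
            baseline
            if cfg.expected_k == 0
            else clean(run, designs[name], config.band, method=config.filter_method)
        )
        tc = connectivity.roi_timecourses(cleaned, masks)
        result.fc[name] = connectivity.slice_fc(tc)
        report = metrics.tsnr(cleaned, masks)
        report.k = cfg.expected_k
        report.r2, report.adj_r2 = metrics.explained_variance(
            baseline, cleaned, masks, cfg.expected_k
        )
        result.quality[name] = report

    if split:
        half_len = (run.n_volumes // 2) * run.tr
        parts = list(
            zip(
                reliability.split_half(run),
                (
                    recording.crop(0.0, half_len),
                    recording.crop(half_len, 2 * half_len),
                ),
                (
                    MotionTrace(motion.x[: run.n_volumes // 2], motion.y[: run.n_volumes // 2]),
                    MotionTrace(
                        motion.x[run.n_volumes // 2 : 2 * (run.n_volumes // 2)],
                        motion.y[run.n_volumes // 2 : 2 * (run.n_volumes // 2)],
                    ),
                ),
            )
        )
        half_fc = {name: [] for name in config.pipelines}
        half_pm = []
        for h_run, h_rec, h_mot in parts:
            h_designs = subject_designs(h_run, masks, h_rec, h_mot, config)
            h_base = clean(h_run, None, config.band, method=config.filter_method)
            for name in config.pipelines:
                cfg = get_pipeline(name)
                h_clean = (
                    h_base
                    if cfg.expected_k == 0
                    else clean(h_run, h_designs[name], config.band, method=config.filter_method)
                )
                half_fc[name].append(
                    connectivity.slice_fc(connectivity.roi_timecourses(h_clean, masks))
                )
            h_csf = design.csf_regressor(h_run, masks.csf)
            half_pm.append(
                physio.physio_metrics(
                    h_rec,
                    h_csf,
                    csf_fs=1.0 / h_run.tr,
                    min_rate=config.min_heart_rate,
                    max_rate=config.max_heart_rate,
                )
            )
        result.fc_halves = {name: tuple(v) for name, v in half_fc.items()}
        result.physio_metrics_halves = tuple(half_pm)
    return result


# ---------------------------------------------------------------------------
# group-level aggregation
# ---------------------------------------------------------------------------


def _pattern_frame(results, which="fc") -> pd.DataFrame:
    rows = []
    for res in results:
        for name, fc in res.fc.items():
            for pattern, value in fc.patterns.items():
                rows.append(
                    dict(subject=res.subject, pipeline=name, pattern=pattern, r=value)
                )
    return pd.DataFrame(rows)


def _quality_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        for name, q in res.quality.items():
            row = dict(
                subject=res.subject,
                pipeline=name,
                r2=q.r2,
                adj_r2=q.adj_r2,
                n=q.n,
                k=q.k,
            )
            for roi, v in q.roi_tsnr.items():
                row[f"tsnr_{roi}"] = v
            row["tsnr_mean"] = float(np.mean(list(q.roi_tsnr.values())))
            rows.append(row)
    return pd.DataFrame(rows)


def run_study_subjects(subjects, config: StudyConfig = StudyConfig()) -> dict:
    """Run the full study on an iterable of subject tuples
    ``(run, masks, recording, motion)`` (optionally with a trailing truth
    element, ignored here).

    Returns a dict of data frames: ``exclusions``, ``fc`` (long format),
    ``quality``, ``fc_tests`` (per-pipeline Wilcoxon/BH), ``r2_tests`` and
    ``tsnr_tests`` (Welch), ``normality``, ``reliability`` (split-half ICC
    per pattern/pipeline with bootstrap CI and rating), ``physio_icc`` and
    ``split_vs_full``.
    """
    excl_rows, results = [], []
    for idx, subj in enumerate(subjects):
        run, masks, recording, motion = subj[:4]
        fd = framewise_displacement(motion, threshold=config.fd_threshold)
        excl_rows.append(
            dict(subject=idx, mean_fd=fd.mean_fd, excluded=fd.exclude)
        )
        if fd.exclude:
            logger.info("subject %d excluded (mean FD %.3f mm)", idx, fd.mean_fd)
            continue
        results.append(
            analyze_subject(
                run, masks, recording, motion, config, subject=idx, split=True
            )
        )
    if not results:
        raise StudyError("all subjects excluded by the FD screen")

    out = {
        "exclusions": pd.DataFrame(excl_rows),
        "fc": _pattern_frame(results),
        "quality": _quality_frame(results),
    }

    # group FC significance per pipeline
    fc_tables = []
    for name in config.pipelines:
        vals = {
            p: [r.fc[name].patterns[p] for r in results]
            for p in connectivity.PATTERNS
        }
        t = connectivity.fc_group_test(vals)
        t.insert(0, "pipeline", name)
        fc_tables.append(t)
    out["fc_tests"] = pd.concat(fc_tables, ignore_index=True)

    # Welch comparisons: adjusted R2 sequentially, tSNR vs baseline
    q = out["quality"]
    adj = {n: q.loc[q.pipeline == n, "adj_r2"].to_numpy() for n in config.pipelines}
    tsnr_vals = {n: q.loc[q.pipeline == n, "tsnr_mean"].to_numpy() for n in config.pipelines}
    seq = [n for n in config.pipelines if n != "Baseline"]
    out["r2_tests"], out["normality"] = metrics.pipeline_comparison(
        adj, seq, mode="sequential"
    )
    if "Baseline" in config.pipelines:
        out["tsnr_tests"], _ = metrics.pipeline_comparison(
            tsnr_vals, config.pipelines, mode="vs_baseline"
        )

    # split-half reliability of FC patterns
    rel_rows = []
    for name in config.pipelines:
        for pattern in connectivity.PATTERNS:
            table = np.array(
                [
                    [r.fc_halves[name][h].patterns[pattern] for h in (0, 1)]
                    for r in results
                ]
            )
            rep = reliability.icc_2_1(table)
            rep.ci95 = reliability.icc_bootstrap_ci(
                table, n_boot=config.n_boot, seed=config.seed
            )
            rel_rows.append(
                dict(
                    pipeline=name,
                    pattern=pattern,
                    icc=rep.icc,
                    ci_low=rep.ci95[0],
                    ci_high=rep.ci95[1],
                    rating=rep.rating,
                )
            )
    out["reliability"] = pd.DataFrame(rel_rows)

    # split-half reliability of the physiological metrics
    pm_rows = []
    for metric in ("cardiac_interval_mean", "resp_zero_crossings", "csf_psd_amplitude"):
        table = np.array(
            [
                [getattr(r.physio_metrics_halves[h], metric) for h in (0, 1)]
                for r in results
            ],
            float,
        )
        rep = reliability.icc_2_1(table)
        rep.ci95 = reliability.icc_bootstrap_ci(
            table, n_boot=config.n_boot, seed=config.seed
        )
        pm_rows.append(
            dict(
                metric=metric,
                icc=rep.icc,
                ci_low=rep.ci95[0],
                ci_high=rep.ci95[1],
                rating=rep.rating,
            )
        )
    out["physio_icc"] = pd.DataFrame(pm_rows)

    # split-half vs full FC (reliability pipeline only)
    ref = config.reliability_pipeline
    if ref in config.pipelines:
        full = {p: [r.fc[ref].patterns[p] for r in results] for p in connectivity.PATTERNS}
        h1 = {p: [r.fc_halves[ref][0].patterns[p] for r in results] for p in connectivity.PATTERNS}
        h2 = {p: [r.fc_halves[ref][1].patterns[p] for r in results] for p in connectivity.PATTERNS}
        out["split_vs_full"] = reliability.split_vs_full_test(h1, h2, full)
    return out
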