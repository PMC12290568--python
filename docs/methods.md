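# Methods

This note documents the models implemented in `lumbarfc`, the synthetic
data they are validated on, and the numerical choices made where the
underlying procedures leave freedom.

## Cleaning model

Each slice is cleaned independently (physiological regressors are
slice-specific because every slice is acquired at a different phase of the
cardiac and respiratory cycles). For a slice with voxel matrix Y (time ×
voxels) and nuisance design D (time × k):

1. demean Y and D over time;
2. apply the temporal band-pass F to both;
3. residualize: Ŷ = F(Y) − F(D) β̂ with β̂ the least-squares solution.

Filtering the confounds with the same operator before the regression makes
the filter and the confound removal act on one orthogonal space: the
composite map is a single orthogonal projection, so cleaning is idempotent,
residuals are exactly orthogonal to the filtered design, and adding columns
can never increase residual variance.

**Filter choice.** The default F is an ideal zero-phase frequency-domain
band-pass (rFFT mask, band edges inclusive, default 0.01–0.13 Hz). We chose
it over an IIR filter because it *is* an orthogonal projection — the
properties above then hold exactly rather than approximately — and because
band-limited signals pass through it unchanged, which makes ground-truth
recovery tests sharp. Its trade-off is circular-boundary ringing for
strongly non-periodic signals. A zero-phase second-order Butterworth
(forward–backward, reflective padding; the conventional smooth roll-off)
is available via `method="butterworth"` and is cross-checked against
nilearn's implementation in the test suite.

**Degenerate designs.** Design columns whose filtered norm is below 1e-10
of their unfiltered norm carry no pass-band energy; they are dropped with a
warning rather than allowed to project data onto round-off noise.
Rank-deficient designs proceed with the minimum-norm solution and a
warning. Voxel means are removed before filtering and restored afterwards
by default so temporal SNR keeps its numerator; orthogonality statements
refer to the demeaned residuals.

## Physiological phase model

Cardiac peaks are detected as prominent local maxima with a minimum
separation of 60/max_rate s (defaults 40–180 bpm — physiologic bounds;
automated detection replaces the manual inspection a human operator would
add). Cardiac phase is 0 at each peak and linear in between; queries up to
two median inter-beat intervals outside the detected range are served by
periodic continuation with the edge interval, which is needed when a
split-half segment starts mid-beat. Respiratory phase uses the classic
amplitude-histogram equalization signed by the breathing direction
(inhale/exhale from a lightly smoothed derivative), making it invariant to
belt gain and offset.

The slice-wise design evaluates both phases at each slice's own acquisition
times, by default slice s at volume onset + s·TR/n_slices (ascending
order; the slice-timing table is configurable since acquisition order is a
scanner detail). Orders: cardiac 4, respiratory 4 (base frequency plus
three harmonics, 8 columns each), interaction 2 (sin/cos of mφ_c ± nφ_r for
m, n ≤ 2, 16 columns) — 32 columns in total. The interaction construction
is the standard sum/difference-phase expansion; it is the unique such
scheme giving 16 columns at order 2.

## Nuisance components and pipelines

* CSF regressor: mean course of the ⌈10 %⌉ most temporally variable CSF
  voxels (ceiling guarantees at least one voxel for small masks).
* CompCor: each CSF voxel is linearly detrended and scaled to unit
  variance, then the K = 5 leading left singular vectors of the time ×
  voxel matrix are used (orthonormal, ordered by explained variance).
* Motion: demeaned x/y translations, no derivatives or squares.
* Framewise displacement: FD_t = |Δx_t| + |Δy_t|; exclusion is *strictly*
  mean FD > 0.4 mm.

The registry holds exactly twelve pipelines with totals
0, 1, 2, 5, 7, 8, 8, 32, 33, 34, 35, 40; assembled designs keep a fixed
column order (physiological, CSF, motion, CompCor) and are checked against
the registry count at assembly time.

## Metrics and statistics

R² is measured against the **filtered-only (Baseline) series**, not the raw
data, so R² quantifies variance attributable to nuisance regressors rather
than to the temporal filter and R²(Baseline) = 0 by construction. This is
an interpretive choice: the alternative (raw-variance baseline) mixes the
filter's large broadband removal into every pipeline's score. Adjusted
R² = 1 − (1−R²)(n−1)/(n−k−1) with n time points and k regressors.

Distributional screens use the Kolmogorov–Smirnov test with
sample-estimated parameters (anti-conservative in the Lilliefors sense;
used only to motivate nonparametric/Welch choices, never as a gate).
Explained-variance comparisons are sequential (each pipeline against the
previous, less complex one), tSNR comparisons are against Baseline, both
Welch unequal-variance t-tests with Benjamini–Hochberg correction. Group FC
tests are one-sample Wilcoxon signed-rank per pattern, BH-corrected across
the four patterns; Fisher z-transformation is applied for the normality
screen only, raw correlations are tested.

Pattern summaries: W and B average their two constituent hemicord pairs
((VL,DL)+(VR,DR))/2 and ((VL,DR)+(VR,DL))/2 — a symmetry choice, since only
single W and B values are conventionally reported. Slices with an empty ROI
or a zero-variance course are dropped from the subject average, not
imputed. Subject matrices average raw correlations over slices (no Fisher
transform at that step).

## Reliability

Runs are split into *contiguous* halves (an interleaved split would break
the temporal autocorrelation structure differently in each half); odd
volume counts drop the final volume. Every stage — design construction
included — is re-run per half. ICC(2,1) comes from the two-way
random-effects ANOVA mean squares; variance components are reported as
(MSR−MSE)/k, (MSC−MSE)/n, MSE. Negative estimates are reported as computed
(rated "poor"), preserving the estimator's sampling distribution for
simulation work. Bootstrap CIs resample subjects with replacement (halves
stay paired), percentile method, default 1000 resamples, seeded. Rating
bins: poor < 0.4 ≤ fair < 0.6 ≤ good < 0.75 ≤ excellent.

Physiological reliability metrics per half: mean inter-peak interval;
respiratory cycle count as ascending zero-crossings of the Hilbert phase of
the belt trace after a 0.01–0.6 Hz band-pass and 1 s median filter; mean
periodogram amplitude of the CSF regressor.

## Synthetic cohort

The generator emulates the target acquisition — 27 axial slices, 360
volumes, TR 2.5 s (15 min), ~1 mm in-plane grid — with schematic geometry:
a disk cord mask (radius 5 voxels), four 2×2 quadrant horn ROIs with a
two-voxel corridor between them, and an annular CSF ring. Per subject:

* **Neural latents.** Four 0.01–0.13 Hz band-limited signals whose *sample*
  correlation matrix exactly equals the subject's realized connectivity:
  the planted matrix (defaults VV = DD = 0.3, B = 0.15, W = 0) perturbed in
  Fisher-z space by N(0, 0.15) per edge and projected to the nearest
  correlation matrix (Higham). Exact whitening makes recovery tests measure
  denoising fidelity, not correlation-estimator sampling noise. The band
  matches the analysis filter so planted connectivity survives filtering.
* **Physiological noise.** Each tissue voxel receives a random linear
  combination of the subject's own 32-column slice-wise RETROICOR basis
  (built from the simulated beat times and belt trace), scaled to standard
  deviation `physio_weight`.
* **CSF latent.** One shared 0.01–0.15 Hz signal with a per-subject gain
  (uniform 0.7–1.4, giving the CSF metric its between-subject variance);
  tissue voxels carry it at weight `csf_weight`, CSF-ring voxels at
  voxel-specific amplitudes 0.6–1.6 × gain.
* **Motion coupling.** Random per-voxel combinations of the standardized
  x/y random-walk motion trace (0.08 mm step sd → mean FD ≈ 0.13 mm, below
  the exclusion threshold), weight `motion_weight`.
* **Thermal noise.** White noise at sd `thermal_sd`, plus a constant
  baseline intensity of 100 so tSNR is well defined.

All component families are made mutually sample-orthogonal within each
slice by successive projection, so the per-voxel variance decomposition
stored in `SimTruth` is exact (the bookkeeping test demands agreement
within 1 %), and the fraction of physiological variance removable by the
true basis is known. Default amplitudes (0.6/0.4/0.3/0.8 relative to
unit-variance latents) are a moderately contaminated regime chosen once: no
published amplitude estimates exist for the lumbosacral cord, so they are
exposed as free parameters.

**Cardiac model.** Beats are raised-cosine pulses (0.3 s wide); only peak
times matter downstream. The subject's rate is N(70, 6²) bpm; within-
subject inter-beat jitter has sd 0.25·60·sd/mean² s so that a zero rate-sd
yields strictly metronomic beats and the cardiac reliability metric has
between ≫ within variance. Respiration is a sinusoid with slow (10 s-scale)
frequency modulation around a subject rate of N(0.25, 0.03²) Hz.

**What the simulator does not model** — and hence what passing tests do
*not* establish about real data: anatomy (no butterfly gray matter, no
curvature, no partial voluming), MRI physics, actual image displacement
(motion enters only as a nuisance-coupled signal plus a parameter trace),
non-stationary physiology, and imperfect masks. Recovery results are upper
bounds on real-data performance: real runs have sampling error in the
latent correlations that the exact-whitening construction deliberately
removes.

## Problem sizes and determinism

Stochastic validation uses a 20-subject cohort at full acquisition scale
(27 slices, 360 volumes) for recovery and trend checks, 10 × 20-subject
cohorts for the significance-structure check, and 20–100 replications for
the ICC and bootstrap-coverage checks — sizes at which the checked
properties have comfortable margins while the whole suite stays fast. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical configurations reproduce
bit-identical cohorts and byte-identical summary tables.

## Known limitations

* Split-half stability overstates true test–retest reliability across
  sessions; the package measures the former only.
* The KS normality screen with estimated parameters is conservative.
* The ideal-filter default assumes approximate stationarity over the run;
  for data with strong transients the Butterworth option may be preferable.
* ROI-to-voxel maps are computed per slice only; intersegmental (between-
  slice-group) connectivity is out of scope.
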