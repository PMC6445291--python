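# Methods

This package re-implements, on fully synthetic data, a voxel-wise encoding
analysis of natural-sound fMRI across cortical depth: two sound models are
fit to per-sound response estimates and compared between primary (PAC) and
non-primary auditory cortex at deep, middle and superficial grey-matter
depths.  This note documents the models, the declared parameter choices,
what the synthetic generator does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Sound models

**Cochlear stage.** Waveforms (16 kHz, 1 s, RMS-equalised, 10 ms linear
ramps) pass through 128 constant-Q gammatone-family magnitude filters
spaced uniformly in log2-frequency from 180 to 7040 Hz (5.29 octaves,
reported as 5.3).  The per-channel envelope is the full-wave rectified
subband, integrated in 8 ms frames (the boxcar doubles as the envelope
low-pass), then log-compressed as `log1p(E / floor)` with `floor = 1e-4`,
so silence maps to exactly zero.  Full-wave rectification (rather than the
more traditional half-wave + low-pass) makes every downstream feature
exactly invariant to waveform polarity, which the modulation features are
required to be.  The channel half-power bandwidth is 1/8 octave: wide
enough that neighbouring channels (spaced 0.041 oct) overlap, narrow
enough that a 4 cycles/octave spectral ripple — the highest filter scale —
survives the cochlear smoothing.  At 1/4 octave it does not, and the
matched-ripple selectivity property fails.

**Frequency model.** The time-averaged cochleogram: 128 parameters, one
per channel.

**Modulation model.** 2-D log-Gaussian bandpass filters in the Fourier
domain of the (time x log-frequency) cochleogram, at temporal rates
ω ∈ {1, 3, 9, 27} Hz and spectral scales Ω ∈ {0.5, 1, 2, 4} cyc/oct
(σ of half the filter spacing on the log2 axis).  Upward and downward
ripple quadrants are analysed separately through their analytic responses
and their energies averaged, so features are direction-agnostic.  The
cochleogram is mirrored in time before filtering to limit boundary
artefacts of the 1 Hz filter on 1 s sounds.  Energies are averaged over
time and over 8 equal-octave frequency bins (16 channels each): 8 x 4 x 4
= 128 parameters, ordered bin-major (bin, then rate, then scale).

## Synthetic data

**Stimuli.** 144 sounds, 6 categories x 24, each a mixture of two moving
ripples on band-limited tone complexes plus band-filtered noise.  Category
signatures place speech-like sounds at fast rates/low scales, music-like
sounds at slow rates/high scales, etc., so category structure is
recoverable in the model spaces.  No acoustic realism is attempted — the
point is recoverable ground truth in the analysis's own feature spaces.

**Design.** 4 category-balanced sets of 36 sounds; 12 runs (TR 2.4 s), one
set per run, each set in 3 runs, so every sound is presented 3 times; ISIs
jittered over {2, 3, 4} TRs; ~8% silent trials (baseline only, no
regressor) and ~6% flagged one-back repeat trials (excluded from betas,
absorbed by a nuisance regressor).  Run length is derived as last onset +
10 volumes (typically ~135); a fixed run length that cannot hold the
schedule is rejected rather than silently truncated.

**Populations.** A grid of points x 9 depths (0.1 deep … 0.9 superficial),
one voxel per (point, depth).  Each grid point carries an MRC value (the
top half defines PAC), a tonotopic position on a smooth gradient, and
opposing rate/scale preference gradients (so the rate and scale maps are
negatively correlated, as in the data the analysis was designed for).
Voxels are tuned in one model space with unit-norm Gaussian-bump weights.
Scenarios:

* `default` — PAC deep/middle voxels frequency-tuned, PAC superficial and
  all non-PAC voxels modulation-tuned; SNR rises linearly 1.9 → 2.1 from
  deep to superficial.
* `null` — all voxels frequency-tuned, flat SNR 2.0 (calibration).
* `gain_only` — a 50/50 tuning mixture at every (region, depth) with a
  strong SNR gradient 1.0 → 3.0.

SNR is the amplitude ratio σ(noiseless signal)/σ(noise) of the voxel's
time series.  The default gradient is deliberately gentle: the scenario is
defined to carry *tuning-based* laminar structure with a depth-flat model
difference outside PAC, and calibration runs showed that steep SNR
gradients (e.g. 1 → 3) by themselves induce a depth-varying model
difference (the better model benefits more from extra SNR), which would
masquerade as laminar structure.  At 1.9 → 2.1 the non-PAC interaction
rejects at ≈ α while the PAC interaction (driven by the tuning switch) is
detected essentially always.

**Forward model.** Per-sound amplitude = true weights · feature vector in
the voxel's own space; stick functions at onset volumes convolved with a
per-voxel double-gamma HRF (peak 5 ± 0.5 s jitter, 35% undershoot,
13 taps at TR 2.4 — deliberately outside the estimator's 8-tap FIR family
so recovery is a genuine test); plus AR(1) noise (φ = 0.4) and random
Legendre drift (order 3), both scaled by 1/SNR.  Everything is
reproducible from explicit seeds (one master seed, spawned per stage).

**What the generator does not emulate.** Natural-recording acoustics,
spatial autocorrelation of voxels, vein effects and depth-dependent
spatial specificity, motion/physiological noise, subject-level anatomy.
Passing tests show the *analysis machinery* behaves as specified under
the stated statistical structure — not that the scientific conclusion
holds in real tissue.

## Response estimation

Runs are high-pass filtered (projection removing the constant and all
Fourier components ≤ 2 cycles/run) and smoothed with a causal 2-volume
boxcar.  The signal model is rank-1 bilinear: one 8-volume FIR HRF per
voxel, common to all sounds, times one beta per sound, plus order-3
Legendre drift per run.  It is fit by alternating least squares (tol 1e-6
on the HRF step, max 100 sweeps, initialised from a canonical double
gamma); the scale/sign ambiguity is fixed by a unit-norm, positive-peak
HRF.  Estimation is vectorised by precomputing stick-matrix Gram blocks
per design, so each sweep solves small per-voxel normal systems in
batches; non-converged voxels are flagged, never raised.

Cross-validation follows the sound-set/run structure: for each fold the
HRF and the 108 training betas come from the 9 training runs; the 36
test betas come from the fold's 3 test runs with the training HRF held
fixed.  Because each set is confined to its own runs, training and test
betas always derive from disjoint run sets.

**Voxel selection** uses the omnibus F-test (sounds + drift vs drift
alone) of a *linear* GLM at the canonical HRF, p < 0.05 uncorrected.
Using the bilinear fit's residuals for the same test is anticonservative
(the fitted HRF absorbs noise; measured type-I ≈ 0.80 vs 0.059 for the
linear GLM on white noise).  On smoothed (autocorrelated) pipeline data
the nominal α remains approximate — a standard fMRI caveat.

## Encoding and identification

Ridge regression per voxel on z-scored features (training sounds only)
with centred responses; the intercept is unpenalised by construction.
λ is selected per voxel from 50 log-spaced grid points in [1e-3, 1e5] by
ridge-trace stability: the smallest grid point from which the unit-
normalised coefficient vector moves less than 0.015 (max absolute change)
per step *all the way to the top of the grid*.  The suffix requirement is
load-bearing: under-determined designs (more features than training
sounds) have a second, false stability plateau as λ → 0, where the path
converges to the min-norm interpolator; a rule that only looks a few
steps ahead selects it and the resulting near-OLS fits overfit badly
(for the modulation model they flip the sign of the laminar model
comparison).  Requiring stability through the grid end always lands
above the trace's unstable transition region.  The tolerance comes from
an oracle calibration on synthetic tuned voxels at SNR 10: weight
recovery is flat for tolerances in roughly [0.0125, 0.02] (median
r ≈ 0.84–0.86, vs ≈ 0.87 for the per-voxel oracle λ) and collapses
beyond ≈ 0.03, where the rule starts accepting the λ → 0 plateau;
held-out prediction accuracy is insensitive across all these settings.
A voxel whose trace never stabilises gets the grid maximum and a flag.

Identification: the predicted pattern of each held-out sound is
correlated with every measured test-sound pattern; the rank r of the
correct sound gives the score P = 1 − (r − 1)/(S_test − 1) (1 perfect,
0.5 chance).  Before the pattern correlations, predicted and measured
matrices are z-scored per voxel across the fold's test sounds.  This
makes scores exactly invariant to per-voxel affine gain/offset — in
particular to any depth-wise multiplicative signal-strength gain — which
is what makes depth *difference* profiles interpretable despite the
surface-weighted signal.  Without it, between-voxel mean differences
dominate the correlations and the scores stop reflecting sound-specific
structure.  Ties in ranks take the average rank; correlations are
Pearson.

Scores are Fisher-transformed as z = atanh(2P − 1) (chance ↦ 0, clipped
at 1e-6 from the poles) before any t-test or ANOVA; atanh(P) is available
behind a flag.

## Laminar statistics and maps

Scores are computed per (region, depth level) over that cell's voxels,
then averaged 9 → 3 into deep {0.1–0.3}, middle {0.4–0.6}, superficial
{0.7–0.9} bins per hemisphere (n = 12 hemispheres is the analysis unit).
Per region a classical two-way within-subject ANOVA (Model x Depth, no
sphericity correction; cross-checked against pingouin in the tests) is
followed by one-sided paired t-tests (modulation > frequency) per depth,
Bonferroni x3.  PAC is the top half of grid points by MRC, ties broken by
stable point index.

Preference maps take the fold-averaged modulation weights per grid point
(averaged over depths) and assign best frequency / rate / scale as the
argmax of the corresponding weight marginal; ties take the lowest label
and are flagged; all-zero weights are undefined.  Rate and scale maps are
compared by per-hemisphere Pearson correlation (on log2 values), Fisher
transformed, then a two-tailed Wilcoxon signed-rank across hemispheres;
group maps are per-point medians over units present in ≥ 4 hemispheres.

## Problem sizes used in the tests

The replicated end-to-end checks run a reduced protocol chosen as the
smallest configuration at which the scenario's effects are reliably
detectable: 72 sounds (12 per category; the same 4-set, 12-run design
logic), 4 grid points per region x 9 depths (72 voxels per hemisphere),
12 hemispheres, full BOLD forward model and estimation (~9 s per
replicate).  Null-scenario calibration (100 replicates) and other
calibration sweeps use the direct-beta response path — betas drawn
straight from the linear model with 1/SNR noise — which skips the
hemodynamic stage that the full-path replicates and the recovery tests
cover separately.  The stimulus set is fixed across replicates, as it is
in the study design; replicates resample designs, populations and noise.

## Known limitations

* Elementwise weight recovery is only meaningful for the frequency model:
  modulation features are strongly collinear across any realistic sound
  set, so modulation weights are identified only up to that collinearity
  (median elementwise r ≈ 0.2 at SNR 10), while their argmax preferences
  (the maps) remain recoverable.  This is a property of the estimation
  problem, not of the implementation.
* A tuning *mixture* cannot make the two models exactly equal (modulation
  features partially encompass spectral tuning), so the `gain_only`
  scenario retains a small (+0.02–0.03) modulation advantage.  The
  gain-invariance claim is therefore tested as an exact property of the
  scoring (multiplicative depth gains leave scores bit-identical) rather
  than through that scenario.
* The selection F-test's α is exact on white noise but only approximate
  after temporal smoothing; the identification analysis itself does not
  depend on the selection threshold for the laminar grids.
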