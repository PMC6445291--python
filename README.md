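# laminar-encoding

Voxel-wise auditory encoding models across cortical depth, on synthetic
natural-sound fMRI.

Laminar (sub-millimetre) fMRI can separate BOLD responses from deep,
middle and superficial grey matter.  A central question in auditory
neuroscience is where along this depth axis sound processing becomes more
complex than a simple frequency analysis: responses in thalamo-recipient
middle layers of primary auditory cortex (PAC) may be well described by
pure frequency tuning, while superficial PAC and non-primary cortex are
better described by frequency-specific tuning to *spectrotemporal
modulations* (how sound energy sweeps across time and frequency).  This
package re-implements the full analysis chain used to ask that question —
and, because no in-vivo data are distributed, a synthetic-data generator
that emulates the study's stimuli, event design and laminar response
structure, so every stage is testable end to end.  It is intended for
methods work: calibrating, stress-testing and extending laminar
encoding-model analyses.

## The analysis

1. **Sound features.**  1 s, 16 kHz sounds pass a 128-channel log-spaced
   cochlear filterbank (180–7040 Hz, 5.3 octaves).  The *frequency model*
   is the time-averaged spectrogram (128 parameters).  The *spectrotemporal
   modulation model* filters the spectrogram with 2-D modulation filters
   (rates ω = 1, 3, 9, 27 Hz; scales Ω = 0.5, 1, 2, 4 cyc/oct), averages
   over time and 8 equal-octave frequency bins: 8 × 4 × 4 = 128 parameters.
2. **Response estimation.**  Per-sound response amplitudes (betas) are
   estimated from the simulated runs with a per-voxel FIR HRF common to
   all sounds (alternating least squares, unit-norm positive-peak HRF),
   after high-pass filtering and 2-volume smoothing.
3. **Encoding fit.**  Per voxel, ridge regression `Y_train = W_train R`
   in 4-fold cross-validation over the four 36-sound sets (108 training /
   36 test sounds per fold), with λ chosen per voxel from the stability
   of the ridge trace.  Test responses are predicted as
   `Y_hat_test = W_test R`.
4. **Identification score.**  Each held-out sound's predicted voxel
   pattern is correlated with all measured test patterns; the rank r of
   the correct sound gives `P = 1 − (r − 1)/(S_test − 1)` — 1 is perfect,
   0.5 chance.
5. **Laminar statistics.**  Scores per (region × depth), binned into
   deep/middle/superficial, compared between models by two-way
   repeated-measures ANOVA (Model × Cortical Depth, Fisher-transformed,
   n = 12 hemispheres) with per-depth one-sided post-hoc t-tests; plus
   argmax-weight preference maps (best frequency / rate / scale) and a
   signed-rank test on the rate–scale map correlation.  PAC is the half
   of the grid with the higher myelin-related contrast (MRC).

## Worked example

```python
from laminar_encoding import pipeline as pl

cfg = pl.PipelineConfig(n_per_category=12, n_units=12, n_voxels_per_cell=4,
                        scenario="default", response_path="bold", seed=1)
result = pl.run_experiment(cfg)
print(pl.report(result))
```

which prints (about a minute; 72 sounds, 12 hemispheres, full BOLD
simulation and estimation):

```
Sound identification (chance = 0.5)
========================================
  frequency    mean 0.888  (SEM 0.003)
  modulation   mean 0.953  (SEM 0.002)
  modulation vs frequency: t(11) = 19.15, p = 8.5e-10
...
Difference profile (modulation - frequency)
----------------------------------------
  PAC     deep         -0.024
  PAC     middle       -0.019
  PAC     superficial  +0.048
  nonPAC  deep         +0.048
  nonPAC  middle       +0.041
  nonPAC  superficial  +0.048

RM ANOVA (PAC)
  Model          F[1,11] = 7.60, p = 0.0186
  Depth          F[2,22] = 148.94, p = 1.63e-13
  Model x Depth  F[2,22] = 236.05, p = 1.36e-15
    post-hoc deep         t = -8.42, p_corr = 1
    post-hoc middle       t = -8.38, p_corr = 1
    post-hoc superficial  t = 11.83, p_corr = 2.02e-07

RM ANOVA (nonPAC)
  Model          F[1,11] = 74.45, p = 3.16e-06
  Depth          F[2,22] = 0.84, p = 0.445
  Model x Depth  F[2,22] = 1.09, p = 0.352
...
Rate-scale map correlation: mean r = -0.704 (SEM 0.048), signed-rank p = 0.000488
```

Read: both models identify held-out sounds far above chance (0.5); the
modulation model wins overall.  In PAC the model difference flips from
≈ 0 at deep/middle depths to a clear modulation advantage superficially
(significant Model × Depth interaction; the post-hoc is significant only
superficially), while in non-PAC the modulation model wins uniformly at
every depth (Model main effect, no interaction) — the laminar structure
the generator's default scenario encodes.  The preferred-rate and
preferred-scale maps are negatively correlated across the grid, as the
generator's opposing preference gradients dictate.

The same pipeline is available from the shell:

```bash
lamenc run-all --seed 1 --out results/demo          # writes CSV/JSON + report
lamenc simulate --seed 1 --out results/sim          # WAVs, designs, HDF5 truth/BOLD
```

`scenario="null"` (no tuning or SNR structure) calibrates the analysis:
the interaction then rejects at the nominal α.

## Layout

```
src/laminar_encoding/
  synthetic_data.py      sounds, designs, populations, BOLD forward model
  audio_features.py      cochleogram + modulation filterbank features
  response_estimation.py preprocessing, HRF/beta ALS, voxel selection
  encoding.py            ridge fits, ridge-trace lambda, cross-validation
  identification.py      rank scores, Fisher transform, model comparison
  laminar.py             PAC split, depth bins, RM ANOVA, preference maps
  pipeline.py            orchestration, replicates, report
  io.py                  WAV/CSV/HDF5/YAML/JSON artifact formats
  cli.py                 `lamenc` command-line front end
docs/methods.md          models, parameter choices, limitations
```
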