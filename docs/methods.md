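# Methods

This note documents the models, conventions and numerical choices behind
`neuroads`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic validation does and does not
establish.

## Synthetic session model (`neuroads.synthgen`)

The generator emulates a 20-subject ad-viewing experiment on the Emotiv
EPOC X montage: per subject one continuous 14-channel recording containing
all eight ads (four topics × {shock, comic}) in random order, each preceded
by a 5 s fixation gap, with a marker track carrying a 1 at every stimulus
onset and offset.  Default ad durations average 49 s with a ±9 s spread;
tests and the acceptance script use shorter uniform durations (8–20 s),
which only increases band-power estimation noise.

**Oscillator model.** Per epoch, channel and band (delta 0–4, theta 4–8,
alpha 8–12, beta 12–32, gamma 32–Nyquist Hz), white Gaussian noise is
band-pass filtered (zero-phase, order 4) and rescaled to an exact target
variance; bands are summed.  Targets come from a 1/f-shaped baseline
profile (40/20/15/10/3 µV² for delta…gamma) modulated by log-normal
epoch-level gain jitter (σ = 0.2 on the log-variance).  This is
deliberately simpler than AR or dipole-source models: the downstream
analysis consumes band powers, for which band-limited Gaussian noise with
controlled variances is sufficient and exactly auditable.  The generator
records the realized per-epoch component variances as ground truth.

**Planted engagement effect.** Each epoch draws a standard-normal
engagement latent e.  In nine designated frontal/fronto-temporal channels
(AF3, F3, F4, AF4, F7, F8, FC5, FC6, T8) the beta variance is multiplied by
exp(+ce/2) and the alpha variance by exp(−ce/2) (c = 0.5), so the planted
log beta/alpha ratio is c·e plus gain jitter.  The rating is a monotone
function of the same latent: a mixture g = λe + √(1−λ²)·η is mapped through
the normal CDF and a right-skew power link u^κ (κ = 0.45) onto the integer
1–10 scale.  κ = 0.45 makes roughly 75–80 % of ratings exceed the scale
midpoint, matching the strongly positive response profile typical of
awareness ads while retaining enough variance for correlation and
classification analyses.

The coupling λ is calibrated numerically (root-finding on a fixed 200,000
sample Monte-Carlo draw of the closed-form planting model, including gain
jitter and the style effect below) so that the population Pearson
correlation between the planted per-channel beta/alpha ratio and the
rating equals the requested `effect_rho`.  The calibration uses an
internal fixed seed, so identical parameters always produce identical
couplings; `planted_summary` exposes the plan-level draws for fast
verification without signal synthesis.

**Alpha discomfort effect.** Shock-style epochs of the two graphic topics
(seatbelt, helmet) have every channel's alpha variance multiplied by
1 − `alpha_suppression` (default 0.3); water/electricity epochs are
untouched, giving a near-zero contrast there by construction.

**Artifacts.** A single blink source — a train of 300–500 ms raised-cosine
bumps at `blink_rate_per_min` (default 15) — is projected onto the montage
with frontal-dominant weights (AF3/AF4 1.0 down to 0.05 posteriorly) at 10×
the background SD, giving ICA a recoverable frontal component.  Power-line
interference is a common-phase 50 Hz sinusoid (default 5 µV, ±20 %
per-channel amplitude spread).  The generator does not simulate cortical
source geometry, volume conduction, EMG, electrode drift or non-stationary
background spectra; consequently, passing recovery tests demonstrates the
*analysis* behaves correctly under its own assumptions, not that those
assumptions hold for any particular real recording.

**Sampling rate.** 128 Hz, a native EPOC X output rate, exposed in config.
At this rate the nominal 70 Hz analysis band edge exceeds Nyquist and is
clipped (see below); the gamma band effectively spans 32–63.4 Hz.

## Preprocessing (`neuroads.preprocess`)

Fixed chain: band-pass → notch → ICA → burst repair → normalize, with every
step and its parameters recorded in a provenance list.

- **Band-pass**: zero-phase (forward–backward) 3rd-order Butterworth,
  0.5–70 Hz.  A high edge at or above Nyquist is clipped to 0.99×Nyquist
  with a warning.  The effective magnitude response is the squared
  Butterworth response; tests verify the stopband against the analytic
  |H(f)|² and the zero-phase property via cross-correlation.
- **Notch**: IIR notch at 50 Hz, Q = 10 — wide enough that the ±1 Hz band
  around the line frequency loses ≥ 20 dB after the double pass while
  45/55 Hz lose < 3 dB.
- **Ocular ICA**: extended Infomax (via MNE) on the continuous recording
  (not per epoch) to maximize samples, fixed seed.  The original procedure
  used visual component inspection; here flagging is automated: any
  component whose |Pearson r| with a frontal low-frequency proxy (mean of
  AF3/AF4, band-passed 0.5–4 Hz) exceeds 0.7 is zeroed before
  back-projection.  Decomposition failure degrades to a warned
  pass-through.
- **Burst repair**: a deliberately simple stand-in for artifact subspace
  reconstruction, and documented as such: samples with channel-wise robust
  z (median/MAD) above 5 are replaced by linear interpolation from
  flanking clean samples; > 50 % flagged samples is a data-quality error.
  It preserves the pipeline role (movement-burst removal) with fully
  auditable behaviour.
- **Normalization**: per channel per epoch, population-SD convention.
  Per-channel (rather than global) scaling is the default because
  cross-channel amplitude differences on consumer headsets are largely
  hardware effects; a `global` mode is available.

Note on idempotence: the epoch-level steps are idempotent (normalization
exactly; burst repair flags nothing on its own output), but zero-phase
filters are not — each pass attenuates band-edge content again, changing a
continuous recording by a few percent RMS and short epochs by more (edge
transients).  Re-running the chain on its own output is therefore close to,
but not exactly, a no-op.

## Feature engineering (`neuroads.features`)

The registry is the single source of truth and asserts its count contracts
at build time: 41 base features (30 statistical, 11 spectral), applied to
broadband + six bands, plus a 183-entry cross-band block = 470 per channel,
6,580 over 14 channels.  The statistical block covers moments, amplitude
summaries, a percentile/IQR/MAD dispersion family, Hjorth mobility and
complexity, waveform-complexity and energy measures, histogram entropy and
crest/impulse factors; the spectral block (Welch PSD, 2 s Hann windows,
50 % overlap) covers total power, spectral moments, median/peak frequency,
spectral entropy, 90/95 % edge frequencies and flatness.  The exact base
list is a documented package default chosen to honour the published
structure (30 statistical including a dispersion family, 11 spectral);
because the registry is data, swapping in a different 41-feature list
changes no pipeline logic.

The ratio block is: 6 absolute band powers (variance of the band-limited
signal), 6 relative powers, 30 + 30 ordered pairwise ratios of absolute and
relative powers, 15 unordered broadband-normalized pair ratios, and 96
engagement-style composites ({β₁, β₂, β₁+β₂, γ} over {α, θ, δ, α+θ, α+δ,
θ+δ} × {absolute, relative} × {raw, log}).  Several of these are
numerically redundant by construction (relative-power ratios equal
absolute-power ratios); the stage-1 redundancy filter removes such
duplicates during modeling, which mirrors how an over-complete feature
inventory behaves in practice.  Degenerate inputs are handled by
convention, not NaN: zero signals map entropy-type features to 0, while a
zero band power raises an error naming the band.

Column names are `<channel>__<signal>__<feature>` with deterministic
ordering (montage order; broadband then bands; registry order), and parse
back into their parts.

## Marker analyses (`neuroads.markers`)

Engagement indices per (subject, ad, channel) epoch: EI₁ = P(β)/P(α),
EI₂ = P(β)/(P(α)+P(θ)) with β = β₁+β₂ power (12–32 Hz; configurable to a
single sub-band).  Indices are correlated with ratings across all epochs
(Pearson by default, Spearman available) and the 14 per-channel p-values
are corrected with Benjamini–Hochberg step-up at q = 0.05.  EI₁ ≥ EI₂
always (the EI₂ denominator adds non-negative theta power).  The alpha
contrast averages alpha power over channels per style within each topic;
`difference` is comic − shock, positive under discomfort-driven
suppression.  Topics missing a style are skipped with a warning.

## Classification protocol (`neuroads.modeling`)

- **Rating normalization**: per-subject min–max to [0, 1]; this is the
  convention under which the 0.5 high/low threshold is meaningful.  A
  constant-rating subject maps to 1 (high) with a warning.  No class
  rebalancing is applied anywhere.
- **Stage 1 (redundancy)**: greedy scan in registry order; a feature is
  dropped iff |r| > 0.8 with an already-kept feature (first-seen-wins
  tie-break).  Zero-variance features are dropped up front with a warning.
- **Stage 2 (relevance)**: keep |r| > 0.1 against the normalized rating,
  absolute value — a one-sided rule would silently discard negatively
  informative features.
- **SVM-RFE**: linear SVM weights rank features; the surviving set is
  halved per iteration until 32 remain, then shrinks by one; the kept size
  maximizes inner 4-fold CV accuracy (ties → fewer features).  C is tuned
  by the same inner CV over the grid {0.01, 0.1, 1, 10, 100} then
  {0.1, 0.15, 0.2, 0.25, 0.3, 0.35} (ties → smaller C).  Internally the
  elimination runs on a precomputed linear Gram matrix that is downdated as
  features are dropped — mathematically identical to refitting on the
  reduced feature set (verified against an independent primal-SVM oracle in
  the tests) and necessary to keep the nested permutation baseline cheap.
- **LOAO**: one fold per ad; all selection stages are fitted on the seven
  training ads only (a `global` selection mode exists for fidelity
  comparisons and is explicitly not leakage-safe).  Features are
  standardized with training-fold statistics.  Classifiers: RBF-SVM
  (C = 10, γ = 0.01), random forest, decision tree, logistic regression —
  the latter three at library defaults with a fixed seed, since the
  protocol specifies none.  AUC uses the rank statistic and is undefined
  (NaN) for single-class test ads; such folds are excluded from the AUC
  average only.
- **Permutation baseline**: the rating-to-epoch assignment is shuffled and
  the full training procedure refitted per permutation; stage-1 pruning is
  label-independent and therefore cached per fold.  p = (1 + #{null ≥
  observed}) / (n + 1).

## Validation scales and what they show

The test suite and `scripts/acceptance.py` use desk-scale study sizes: 20
subjects × 8 ads throughout (160 epochs, the design's sample size), with
8 s epochs for the 100-replicate marker-recovery and 10-replicate
alpha-contrast studies and 20 s epochs for the classification study;
epoch length affects only band-power estimation noise.  Under these
conditions the engagement analysis flags ≥ 8 of the 9 planted channels
with ≤ 1 false positive in ≥ 90 % of replicates at `effect_rho` = 0.5,
stays at the nominal FDR under a null effect, recovers the graphic-topic
alpha contrast directionally, and at `effect_rho` = 0.6 the LOAO SVM beats
both the majority-class rate and a 100-permutation label-shuffle baseline
at p < 0.05 while a leakage-sentinel feature yields no gain.  These are
statements about the pipeline's correctness and statistical behaviour
under the generative model above — not about effect sizes in any real
population.

## Known limitations

- The base-feature list and the ratio-block composition are documented
  package defaults satisfying the published counts, not a published
  inventory.
- The burst-repair step is a transparent stand-in, not artifact subspace
  reconstruction; it does not use a calibration covariance.
- At 128 Hz the 70 Hz band edge is unattainable (clipped to 63.4 Hz), so
  "gamma" is effectively 32–63.4 Hz.
- The EDF writer targets plain EDF with 1 s records and zero-padding to a
  whole record (true sample count kept in the reserved header field);
  EDF+ annotations are not produced.
- Grouped inference beyond LOAO (e.g. leave-one-subject-out) is out of
  scope.
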