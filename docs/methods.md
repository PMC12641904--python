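# Methods

## Stimulation protocol

The schedule is fixed: 50 ramp cycles (3000 ms bright, dark growing by
100 ms per cycle to 5000 ms), three tail cycles (3000 ms bright before
7000, 10000 and 15000 ms dark), and a repeat block of ten 3000 ms bright /
100 ms dark pairs. Epochs are half-open integer-millisecond intervals
`[onset, onset + duration)`, so every millisecond belongs to exactly one
epoch and transition samples are unambiguous. By default a closing 3000 ms
bright epoch follows the last repeat dark so that *every* dark epoch has a
measurable re-onset (63 re-onset events, 352 500 ms total);
`build_protocol(final_bright=False)` ends on the last dark instead
(62 events, 349 500 ms). The amplitude measurement is defined only at a
re-onset, which is why the trailing bright is the default. Luminance is a
two-level label; the nits values (150 bright, <1 dark) are metadata only.

## Generative model of a recording

A pupil trace is synthesised at 200 Hz (5 ms grid) per subject:

- **Recovery law.** After `d` ms of darkness the constriction amplitude is
  `A(d) = A∞ · (1 − exp(−d/τ))`, the first-order kinetics expected if the
  limiting process is photopigment regeneration. `A∞ = amp_max −
  age_slope · (age − age_ref)`, floored at zero. Group differences enter
  through τ (AMD 3600 ms vs control 1800 ms by default: recovery twice as
  slow) and through the age slope (0.004 vs 0.010 mm/yr: the age decline is
  attenuated in AMD, yielding a positive Age × Group interaction).
- **Constriction transient.** At each re-onset the diameter follows
  `D(t) = baseline + (D_pre − baseline)·exp(−t/τ_dil) − A(d)·g(t)` with the
  unimodal kernel `g(t) = (t/t_peak)·exp(1 − t/t_peak)`; `t_peak = 150 ms`
  places the trace minimum inside the 100–200 ms measurement window, and
  `g(t_peak) = 1` makes the programmed amplitude directly recoverable.
- **Dark dilation.** In darkness the diameter relaxes toward
  `baseline + dark_gain` (5.0 + 1.0 mm default) with `τ_dil = 1500 ms`.
- **Nuisance processes.** Additive hippus sinusoid (0.10 mm, 0.2 Hz, random
  phase), white measurement noise (0.05 mm SD per sample), and Poisson blink
  gaps (0.1 Hz, 100–300 ms) marked invalid with a NaN sentinel.
- **Between-subject variability.** Kinetic and amplitude parameters are
  jittered per subject by lognormal factors (σ of log: τ 0.15, A∞ 0.12,
  baseline 0.05, dark gain 0.10, τ_dil 0.10), so cohort-level variance
  components are exercised.

Default cohort: 14 AMD + 14 controls, ages N(75, 7²) shared across groups
(age-matched by construction), one eye per subject. All amplitudes are in
millimetres of pupil diameter; orderings and signs are the scientifically
constrained quantities, absolute scales are package choices.

What the simulator does **not** emulate: consensual fellow-eye responses,
gaze-dependent foreshortening, melanopsin-driven sustained constriction,
non-stationary hippus, or eyelid-partial occlusions. Passing tests therefore
demonstrate correctness of the pipeline's measurement and inference
machinery under controlled kinetics — not that real AMD cohorts will show
the same effect sizes.

Two shortcut generators bypass trace synthesis for simulation studies of
the statistics: `simulate_amplitude_table` draws amplitudes directly from
the recovery law plus iid noise, and `simulate_model_form_table` draws from
the mixed model's own linear form (used for estimator calibration, see
below).

## Cleaning

The cleaning rules are package decisions (surfaced in `CleaningConfig`,
logged in the run manifest):

- Velocity spikes: a sample is flagged when either adjacent first-difference
  velocity exceeds 50 mm/s (≈3.5 SD of the default noise process at 200 Hz);
  each flagged run is dilated by one sample on both sides. Flags derive
  from diameters only, making the operation idempotent.
- Gaps up to 300 ms are bridged by linear interpolation between the bounding
  valid samples; longer and leading/trailing gaps are left invalid
  (never extrapolated).
- A centered 25 ms (5-sample) moving average over valid samples; window 0
  disables it.

The full `clean()` records a marker in the recording metadata and is a
no-op on already-cleaned input, so the pipeline as a whole is idempotent
even though smoothing by itself is not. Cycles whose measurement windows
remain invalid are marked missing rather than imputed. Note that smoothing
slightly attenuates the measured amplitude (the trace maximum at re-onset is
averaged with post-onset decline, ≈5% at default settings); the noise-free
verification of the extraction chain therefore runs with smoothing disabled,
where recovery of the programmed amplitude is exact to the grid.

## Amplitude extraction

ROI windows are half-open relative to re-onset: maximum over [0, 100) ms,
minimum over [100, 200) ms, partitioning the 0–200 ms span without double
counting. A window needs ≥80% valid samples, else the row is missing
(`roi_invalid`; `out_of_span` when the window leaves the recording).
Negative amplitudes on noisy traces are retained — clipping would bias group
means upward. Eye averaging uses available-case means per (subject, cycle).
Only the 50 ramp cycles feed the statistical models; tail and repeat rows
are extracted and reported but excluded by default (`ModelSpec.phases`).

## Mixed-effects models

Both specifications are estimated by maximum likelihood (not REML) so that
AIC/BIC are comparable across fixed-effect structures. Group is a treatment
contrast with Control as reference: a negative Group coefficient means lower
AMD amplitude. Age is centered at the cohort mean; Time is the preceding
dark duration in milliseconds. Coefficient p-values and the marginal
(type-III) ANOVA both use residual degrees of freedom `n − rank(X)`; for
single-df terms F = t² exactly.

A random intercept on a 2-level grouping factor is retained for fidelity to
the modelling choice it reproduces, but it is statistically degenerate: the
group variance is usually estimated at the boundary (zero), where the model
collapses to OLS-like estimates. The results object reports the boundary
explicitly; when the optimizer stalls exactly there, the fit is replaced by
the closed-form boundary ML solution with `converged` kept true. A
`random="subject"` sensitivity refit is available and is the structure a
statistician would normally prefer. An optional `normalize=True` divides
amplitudes by the subject's baseline diameter when a `baseline_mm` column
is supplied.

**Calibration caveat.** Because two group levels cannot absorb per-subject
heterogeneity, the Group test is anticonservative whenever subjects differ
beyond the model's iid error — which the full trace generator deliberately
produces. Estimator calibration (type-I error at nominal 5%, parameter
recovery within 3 SE) is therefore verified on `simulate_model_form_table`
data, which matches the fitted model's assumptions exactly; sign recovery of
the group effect is verified on the full recovery-law generator. Both run at
200 replicates of the 28-subject, 50-cycle design in the test suite.

## CNN classifier

Features are the 50 ramp amplitudes ordered by dark duration (optionally
age as a 51st feature); missing cycles are linearly interpolated over dark
duration from the subject's neighbouring cycles, and subjects with >40%
missing cycles are excluded. Per cross-validation fold, features are
z-scored with training-fold statistics only, a stratified 25% inner
validation split is carved from the training fold for early stopping, and
the untouched held-out fold is scored — held-out data never enters
standardization or stopping decisions.

The network topology is fixed (two conv-ReLU blocks with max-pooling,
dense-ReLU, dropout, 2-unit softmax); sizes are configurable with defaults
16/32 filters, kernel 5, pool 2, dense 32, dropout 0.3, Adam lr 1e-3,
batch 4, patience 10, max 200 epochs. These sizes are conventional choices
for a 50-sample 1-D input and are pinned in `CNNConfig` and logged; no
hyperparameter search is performed. The implementation is pure NumPy with
analytic gradients (verified against finite differences in the tests), so
training is exactly reproducible under a seeded Generator. Sensitivity
treats AMD as the positive class. Both the mean of per-fold accuracies and
the pooled-confusion accuracy are reported, labelled separately.

Permutation-null checks (50 label-permuted cross-validation repeats) run
with `max_epochs = 30`: chance-level behaviour does not depend on training
length, and the shorter schedule keeps the simulation at desk scale.

## Pipeline and determinism

`run_pipeline` executes protocol → simulate → clean/extract → fit →
classify, writing every intermediate artifact plus a manifest with the
config hash and per-stage seeds. Stage seeds derive from the global seed by
SHA-256 over `"{seed}:{stage}"`, so stages are decoupled and reruns of the
same config produce bitwise-identical CSV/JSON artifacts.

## Known limitations

- The 2-level random intercept is structurally confounded with the fixed
  Group effect; inferential results should be read with the sensitivity
  refit in hand.
- The amplitude statistic uses raw extrema, so it carries a positive noise
  bias (max − min of noisy windows); group comparisons are unaffected
  because the bias is common to both groups at equal noise.
- Simulated hippus is a pure sinusoid and blink gaps are rectangular; real
  artifact structure is richer and may defeat the velocity heuristic.
- Classifier performance on synthetic cohorts (often 100% at default effect
  sizes) reflects the generator's clean group separation and says nothing
  about clinical accuracy.
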