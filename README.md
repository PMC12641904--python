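# pupilrecover

Dark-adaptation recovery of the pupillary light reflex (PLR), analysed the
way a VR-pupillometry screening study would: an incremental bright/dark
stimulation protocol, cycle-wise constriction amplitudes, mixed-effects
modelling of the recovery curve, and a cross-validated CNN classifier that
separates patients with age-related macular degeneration (AMD) from healthy
controls.

## The problem

AMD degrades the retinal pigment epithelium and photoreceptors, which slows
photopigment regeneration and therefore dark adaptation. That deficit is
measurable at the pupil: after light adaptation, the amplitude of the pupil
constriction elicited by re-onset of a bright screen grows with the duration
of the preceding dark interval and saturates. The *rate* of that growth — the
recovery of the PLR — is slower in AMD.

The package is built for researchers in pupillometry and visual
electrophysiology who want a fully tested, simulation-backed version of this
analysis: every stage runs on synthetic cohorts with known ground truth, so
estimator behaviour (signs, calibration, classification power) can be
verified before any real recording is analysed. Real data, when available,
enters as long-format CSV sample tables.

## The model

**Protocol.** 50 "ramp" cycles of 3 s bright (150 nits) followed by darkness
that grows by 100 ms per cycle (100 ms … 5000 ms), then three long dark
tails (7, 10, 15 s), then a 10-cycle repeat block of 3 s bright / 100 ms
dark.

**Amplitude statistic.** For each dark → bright re-onset, amplitude =
max pupil diameter in [0, 100) ms minus min diameter in [100, 200) ms after
re-onset. Plotted against dark duration *d*, amplitudes form the recovery
curve, generated in simulation by the saturating-exponential law

    A(d) = A∞(age, group) · (1 − exp(−d / τ_group)),

with τ_AMD > τ_Control (slower recovery) and an age-related decline of A∞
that is weaker in AMD (a positive Age × Group interaction).

**Inference.** Two linear mixed models, fitted by maximum likelihood:

    amplitude ~ 1 + Time + Group + (1 | Group)
    amplitude ~ 1 + Age + Time + Group + Age × Group + (1 | Group)

with Time = dark duration in ms and Control as the reference level, plus a
marginal (type-III) ANOVA with residual degrees of freedom. A 1-D CNN
(conv-ReLU-maxpool ×2, dense, dropout, softmax; Adam, categorical
cross-entropy, early stopping) classifies subjects from their 50-point
curves under stratified 5-fold cross-validation.

## Worked example

```python
from pupilrecover.pipeline import RunConfig, run_pipeline
from pupilrecover.amplitude import read_amplitude_table
from pupilrecover.lmm import fit_lmm

run_pipeline(RunConfig(out_dir="runs/demo", seed=1))
table = read_amplitude_table("runs/demo/amplitudes.csv")
print(fit_lmm(table, variant="extended").summary())
```

prints (28 simulated subjects, 14 AMD + 14 age-matched controls, 50 ramp
cycles each):

```
Linear mixed model (extended), ML estimation
  amplitude ~ Intercept + Age + Time + Group[AMD] + Age:Group[AMD] + (1 | group)
  n_obs = 1400, residual df = 1395
  logLik = 1006.820  AIC = -1999.64  BIC = -1962.93
  sigma_resid = 0.117879  random intercept sd = 1.18091e-06  (variance at boundary)
  term                    estimate          se         t           p
  Intercept               0.368534    0.007263    50.740           0
  Age                   -0.0108993   0.0007426   -14.677    1.85e-45
  Time                 0.000186295   2.183e-06    85.334           0
  Group[AMD]             -0.220064    0.006593   -33.377   4.92e-180
  Age:Group[AMD]          0.012541    0.001043    12.024    9.32e-32
```

Read: amplitudes grow with dark duration (positive Time), AMD subjects
constrict ~0.22 mm less on average (negative Group), amplitude declines with
age (negative Age) and that decline is attenuated in AMD (positive
interaction) — the qualitative pattern the generative model encodes. The
random-intercept variance for a 2-level grouping sits at the boundary (~0),
which the summary flags. On this cohort the recovery curve rises from
0.12 mm (100 ms dark) to 1.21 mm (5 s dark) in controls versus 0.09 mm to
0.99 mm in AMD, and the CNN separates the groups with mean 5-fold CV
accuracy 1.0 (`runs/demo/cv.json`).

The same pipeline is scriptable from the shell:

```bash
pupilrecover run --out-dir runs/demo --seed 1
pupilrecover plot --amplitudes runs/demo/amplitudes.csv --out recovery.png
```

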