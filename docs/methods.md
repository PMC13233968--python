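# Methods

## The problem

The QT interval, corrected for heart rate (QTc, Bazett: QT/√RR with RR
in seconds), is the screening quantity for long-QT syndrome (LQTS) —
congenital or acquired — which predisposes children to torsades de
pointes and sudden cardiac death. Automated QTc measurement in children
is harder than in adults: resting rates span ~60–220 bpm, RR variability
is larger, and T-wave morphology differs. A regression model that
estimates QTc directly from the raw multi-lead waveform can outperform
classical beat-averaging measurement, but to be *clinically* usable as a
screening tool it must also satisfy likelihood-ratio floors: a negative
likelihood ratio (NLR) below 0.2 so a negative test meaningfully rules
out LQTS, and a positive likelihood ratio (PLR) above 5 to limit false
positives. This package implements that whole chain on synthetic data:
cohort generation, two estimators, threshold-aware calibration, and the
paired diagnostic statistics needed to compare estimators.

## Synthetic cohort model

Expert-labelled pediatric ECG archives are private, so the generator is
a first-class, tested component rather than a fixture. It emulates the
marginal statistics reported for a large children's-hospital population
(~65k ECGs, ages 0–18, balanced sex).

**QTc population.** A two-component mixture: a normal core
N(421.1, 27.8²) ms plus, with weight 0.0555, a long-QT tail
N(421.1 + 79.0, 18²) ms, floored at 200 ms. The five constants were
fitted once (penalised least squares on the published quantiles and
prevalences) and frozen as defaults; they reproduce a median of
≈ 423 ms (target 424, IQR 403–445 → fitted 404/444) and prevalences
13.1% / 9.0% / 3.0% above 460 / 470 / 500 ms to within ±0.1 percentage
points, i.e. well inside binomial noise at n = 50,000. The mixture form
is a modelling choice: only quantiles and exceedance rates are published,
not a distribution family.

**Heart rate and age.** Age is drawn to match the published quartiles
(1.4 / 8.8 / 14.2 years) by a mixture of uniforms over the
inter-quartile segments. Heart rate is lognormal around an age-dependent
median — multipliers {newborn 1.58, infant 1.35, toddler 1.19,
school-age 0.99, adolescent 0.81} on the cohort median of 96 bpm,
chosen to follow typical pediatric resting rates and normalised so the
cohort median stays at 96 — with within-stratum log-SD 0.25. Age bins
follow the fairness strata (newborn < 1 month, infant < 12 months,
toddler 1–5 y, school-age 5–11 y, adolescent 11–18 y). Demographics
(sex 50/50; race mix from the published table) carry no waveform effect;
they exist so fairness analyses have strata. Age affects only heart
rate.

**Per-record labels.** QT = QTc·√RR with RR the record's generative
mean RR; the within-record RR sequence is i.i.d. Gaussian jitter with
coefficient of variation 0.05 (truncated at ±3 SD, renormalised so the
realised mean equals the generative mean — this keeps the Bazett
identity exact on stored labels). In the rare joint draw where the QT
would not fit into the cardiac cycle (fast rate + long QTc; < 0.1% of
records) the mean RR is lengthened to the shortest feasible value rather
than resampling QTc, so the QTc marginal — the quantity with fidelity
targets — is untouched.

**Waveforms.** Each beat is a sum of five Gaussian bumps (P, Q, R, S, T)
in the ECGSYN tradition, scaled per lead by a fixed amplitude vector over
the 11 leads. The T bump's centre is solved analytically so that the
tangent-method T offset (the steepest-descent tangent's intersection with
the isoelectric baseline, which for a Gaussian of width σ falls at
centre + 2σ) lands exactly QT after the template's Q onset; the Q onset
itself is located numerically on the analytic QRS by the same
derivative-threshold rule the measurer uses, making the generator a
round-trip oracle for the median-beat measurer. T width scales with QT
(0.11·QT, clipped to 28–50 ms). At fast rates with long repolarisation
the next P wave would collide with the T offset; the template fades the
P amplitude as that gap closes, mimicking the physiologic P-on-T merge.
White noise (SD 0.01 mV) and sinusoidal baseline wander (0.05 mV at
0.25 Hz, random phase) are conventions, not estimates — the source
population's noise characteristics are unpublished.

**What the generator does *not* emulate** — and hence what passing tests
do not show about real data: pathological morphologies (ST abnormalities,
T-wave inversion or alternans, ventricular rhythms), electrode artifacts,
pacemakers, age-dependent waveform shape, and any coupling between
demographics and morphology. Results on this cohort demonstrate that the
pipeline is correct and internally consistent, not that the regressor
would reach any particular accuracy on clinical ECGs.

## Median-beat baseline measurer

Modelled on the brief public descriptions of commercial median-beat
algorithms. R peaks are detected on lead II by a smoothed
squared-derivative threshold with a 200 ms refractory period (and agree
with the generator's true onsets within ±10 ms on noise-free data; the
generator also supplies true onsets for callers that want them).
Baseline wander is removed with a zero-phase 0.5 Hz second-order
high-pass — without this, 0.05 mV wander moves the tangent intercept by
up to 10 ms. Beats are windowed [−300, +600] ms around R, clipped to the
median RR (pre ≤ 0.35·RR, post ≤ RR − 60 ms), and the per-lead pointwise
median over ≥ 3 complete windows forms the median beat. Per lead
(Savitzky-Golay smoothed, window 11, order 3): Q onset is the first
sample in the 90 ms before R where |dV/dt| exceeds 2% of the peak QRS
slope for ≥ 8 ms; the T peak is the maximum above the PR-segment
baseline beyond R + 90 ms; the T offset is the tangent through the
steepest post-peak descent intersected with the baseline. QT is the
latest T offset minus the earliest Q onset across leads; leads with a
flat T (< 0.04 mV) are skipped, and a record fails measurement only if
no lead is usable. On noise-free synthetic records the round-trip error
is ≤ ~1 ms across QT 250–550 ms and heart rate 60–180 bpm (tolerance
±5 ms in tests, dominated by the 2 ms sampling grid). Under the default
noise the latest-offset-across-leads rule makes the baseline overestimate
QT by tens of ms — the same conservative bias reported for commercial
median-beat algorithms, which is exactly why it serves as the comparator.

## Residual convolutional regressor

Input is the raw `5000 × n_leads` array; the body is a stem convolution
followed by residual blocks of conv–batchnorm–ReLU–dropout–conv with an
additive skip (1×1 projection when shape changes), the final feature map
flattened into a single linear output. The full-scale configuration has
16 blocks, kernel 16, 32 base channels doubling every 4 blocks, stride 2
every other block, dropout 0.2. Training protocol (not specified by any
published source; package conventions): Adam at 1e-3, mean-squared error
on standardised targets, per-lead z-score input normalisation computed on
the training portion only, 10% inner validation split with early
stopping (patience 3) and best-epoch restoration — the inner split is
what makes patient-grouped cross-validation "nested". The implementation
is pure numpy (im2col convolutions, full backward pass, verified against
finite differences); no GPU framework is assumed. The desk-scale preset
(4 blocks, 16 channels, stem stride 8, single lead, ≤ 10 epochs) trains
on 2,000 synthetic records in ≈ 3–4 minutes on one CPU and reaches
held-out MAE ≈ 15 ms versus ≈ 25 ms for predicting the training mean;
the full-scale configuration is a config change, not a code change.
Patient-grouped k-fold assignment shuffles patients with a seeded
generator and deals them round-robin, so folds are balanced within one
patient and no patient appears on both sides of any split.

## Screening calibration

For each cutoff t ∈ {460, 470, 500} ms independently, the derivation
scans integer offsets d = 0…100 ms and takes the smallest d for which
the training-data classifier `raw ≥ t − d` attains NLR < 0.2 while
keeping PLR > 5 (strict inequalities). If no d satisfies both, the
threshold is flagged infeasible and d minimises NLR subject to PLR > 5.
Smallest-offset is the tie-break because every extra millisecond of
offset inflates the mean error of calibrated predictions.

The transform applied to held-out predictions is the monotone envelope
of the band shift: a prediction in `[t − d_t, t)` moves up by `d_t`; a
shifted value that lands inside a *higher* cutoff's band is shifted
again (the cascade terminates — each shift crosses a strictly higher
cutoff); and the running supremum over lower inputs restores
monotonicity at band edges (computed exactly via left-limits at the
finitely many jump points of the cascade). This transform reconstructs
a procedure that is described in the literature only in outline; in the
regime where bands overlap, a pointwise band shift cannot be
simultaneously monotone and band-emptying, so this implementation keeps
the plain band-shift semantics exactly when bands are disjoint and
resolves the overlap regime in favour of the two structural guarantees,
which are what the empty bands in a calibrated Bland-Altman plot
reflect. Consequences, property-tested at
scale: the transform is nondecreasing, never lowers a prediction, is the
identity away from the bands, leaves every output band `(t − d_t, t)`
empty, and never decreases sensitivity at any cutoff.

## Evaluation statistics

Error is `true − predicted` throughout, so an estimator that
overestimates QTc has negative mean error. MAE/ME/SDE per
cross-validation fold with 2,000-replicate percentile-bootstrap CIs
inside each fold; fold estimates and CI bounds are mean-pooled (the
pooling rule is a package choice; per-fold CIs are what the bootstrap
delivers). Bland-Altman agreement regresses the difference on the gold
value (the agreement plot's x-axis), tests the slope against zero with a
Wald t-test, and reports limits of agreement mean ± 1.96 SD. Diagnostic
metrics come from the TP/FP/FN/TN table; if any cell is empty the table
is recomputed with +0.5 in every cell and flagged. Prospective-cohort
CIs use the binomial normal approximation for proportions (Clopper-
Pearson exact at the 0/1 boundary) and the log-normal interval with the
standard log-variance for likelihood ratios.

Paired comparisons: McNemar with the exact binomial form at ≤ 25
discordant pairs and the plain (uncorrected) chi-square above — the
continuity-corrected variant is measurably conservative (size ≈ 0.033 at
the simulated null) while the plain form sits at ≈ 0.05. Predictive
values are compared with the Leisenring-Alonzo-Pepe generalized score
statistic: observations are (record, test) pairs where the relevant test
is positive (PPV) or negative (NPV), the score for the test-identity
covariate is evaluated under the pooled null and studentised with a
subject-clustered empirical variance, chi-square(1) reference.
Likelihood ratios are compared on the log ratio log(LR_a/LR_b) with
delta-method variance from the paired multinomial rates among diseased
and non-diseased subjects (the regression-model formulation is
asymptotically equivalent); cells are smoothed and flagged when
degenerate. All three tests are validated by seeded null simulation
(type-I error within [0.035, 0.065] at α = 0.05, n = 500, 2,000
replicates) rather than against closed forms, since no reference
implementation ships with the package. Fairness analyses compare MAE
across age/sex/race strata with rank-sum tests on absolute errors,
excluding groups under 30 records. Rater consensus uses the row mean
over all raters as the gold standard for algorithms and the
leave-one-rater-out mean for each human rater.

## Numerical conventions and problem sizes

Voltages in mV, intervals in ms, time as 0-based sample indices at
500 Hz, half-open windows. Long-QT classification is inclusive
(`QTc ≥ t`). All stochastic paths take explicit integer seeds and are
bit-reproducible; child seeds are spawned per record for waveform noise.
The envelope's left-limit probes sit 1e-9 ms below each jump point (an
ulp-sized step can round back onto the boundary when an offset is
added). Test and acceptance problem sizes — 50,000 labels for
distribution fidelity, two 20,000-record cohorts for the held-out
mandate, 2,000 waveform records for the learning check, 2,000 null
replicates for test calibration — were chosen as the smallest sizes at
which binomial/bootstrap noise is comfortably below the tolerances being
checked.

## Known limitations

The generator's waveform realism is deliberately minimal (see above);
the median-beat baseline implements a brief public sketch, not any
vendor's actual algorithm; the calibration transform is a
reconstruction whose original is not public; full-scale (16-block,
65k-record) training is supported by configuration but not exercised by
the test suite; and likelihood-ratio comparison uses an asymptotic
delta-method variance that requires smoothing in small or degenerate
cells.
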