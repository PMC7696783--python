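# Methods

## The measurement being modelled

A breath sample is injected into a chamber holding 14 MOS gas sensors.
Each sensor's heater is cycled; during data collection the analyzer samples
all channels at 50 Hz for 90 s, transmitting the thermal-cycling pattern
about nine times. The class-discriminating information lives in the heating
transient — the segment from the cooling→heating turning point to the
heating→cooling turning point, 3.5 s long, i.e. 175 samples per cycle per
sensor.

## Simulator

`simulate_recording` builds each channel as a periodic template plus noise:

- **Template.** Within a 10 s cycle (500 samples): a linear ramp from the
  per-sensor baseline up to baseline + amplitude over the 175-sample
  heating window, then exponential relaxation back toward baseline with
  time constant `cooling_tau` (default 2 s). The within-cycle minimum is
  exactly at sample 0, the cooling→heating turning point.
- **Class effect.** For pathological subjects a per-sensor additive offset
  (`class_effect`, scaled by `effect_scale`) is applied inside heating
  windows only — under thermal modulation, MOS selectivity is expressed in
  the transient, not the steady state. With noise off, the cancer−healthy
  difference is exactly `effect_scale × class_effect` on the heating mask
  and zero elsewhere, which the tests exploit as a closed-form oracle.
- **Noise.** i.i.d. Gaussian per sample (`noise_sd`, default 5 ADC counts)
  plus a per-cycle Gaussian random-walk drift (`drift_sd`, default 2 counts
  per cycle step), the simplest model exposing both fast and slow
  variation. Noise streams are drawn independently of the label, so
  zero-effect cohorts are exchangeable by construction.
- **Defaults.** Baselines 400–920 and ramp amplitudes 150–280 ADC counts
  across the array (arbitrary linear ADC units; the real sensors' identities
  and response ranges are not modelled); `class_effect` a fixed mixed-sign
  vector with mean magnitude ≈4 counts. At `effect_scale = 1` this gives a
  clearly separable but imperfect cohort (cross-validated AUC ≈ 0.95–1 at
  desk scale); `effect_scale` is the single dial for separability studies,
  with 0 the exchangeable null.
- **Seeding.** One master seed; subject *i* draws its signal seed from
  `SeedSequence([seed, i])` and its metadata seed from
  `SeedSequence([seed, i, 1])`, so enlarging a cohort never reshuffles
  existing subjects. Subject metadata (age, sex, localization, stage,
  drawn to resemble a mixed head-and-neck/lung screening population) is
  stored with each recording but never enters the feature path.

What the simulator deliberately does **not** capture: real VOC chemistry
and cross-sensitivities, sensor aging, humidity/temperature confounds,
inter-subject covariance structure, or any nonlinearity of the class
signature. Passing tests on simulated cohorts therefore demonstrate that
the pipeline recovers a known planted effect and is unbiased under the
null — not that the instrument achieves any particular clinical accuracy.

## Featurization

1. **Turning-point detection.** The channel-mean trace is folded at the
   configured cycle period and averaged over the ~9 cycles; the argmin of
   the folded profile is the common phase of the cooling→heating turning
   points, and starts are laid one period apart. Folding was chosen over a
   per-window local-minimum search because the cooling tail is nearly flat
   near its end: per-cycle argmins wander tens of samples under realistic
   noise, while the folded estimate stays within a few samples of truth
   (tested at ±5). Drift that is constant within a cycle leaves the folded
   profile's argmin unchanged.
2. **Windows.** One 175-sample window per cycle starting at each turning
   point; trailing starts with no room for a complete window are dropped.
3. **Aggregation.** Windows are averaged across cycles (default). A
   `first-cycle` mode is retained for sensitivity analysis; concatenating
   all ~9 cycles is excluded because it would contradict the fixed
   238-value input dimension.
4. **Decimation.** Every 10th sample of the aggregated window, indices
   0, 10, …, 160 — floor(175/10) = 17 values per sensor. (Taking a ceiling
   or including index 170 would give 18 and break the 17 × 14 = 238
   geometry.) The decimation phase is fixed at 0; other phases are a shift
   of the same information and are not exposed.
5. **Scaling.** Per-feature min-max to [−1, 1], fitted on training-fold
   subjects only, clamped on unseen data; a zero-range feature maps to 0
   with a warning. Scaling is not part of the instrument's description but
   tanh units saturate on raw ADC counts in the hundreds; a `none` mode
   preserves the raw reading.

The heating:cooling duration ratio (4:1-style configuration of which cycle
segments feed the network) is recorded in configuration for provenance but
does not alter computation: the turning-point-anchored 175-sample window is
the only quantitatively pinned quantity.

## Network and training

238-476-1 fully connected, tanh everywhere, targets +1 (pathology) / −1
(healthy). Loss is mean squared error; updates are full-batch gradient
descent at learning rate 0.01 — full batch makes "epoch" well-defined and
runs bit-reproducible, and cohorts of ≤121 subjects make it cheap. Weights
initialize uniformly in [−0.1, 0.1] from a configured seed.

Early stopping: every `validation_check_interval` epochs (default 100) the
training and validation MSE are recorded; training stops when validation
MSE has not improved for `patience` consecutive checks (default 20), or at
`max_epochs` (default 1,000,000 — in practice the patience rule fires
long before). The returned weights are the snapshot at the minimum recorded
validation MSE, never the final epoch. Inside cross-validation each
training fold is split 80/20 (stratified, seeded) to provide the monitor
without touching held-out subjects; degenerate fold sizes fall back to
monitoring the training error itself. A non-finite loss or gradient raises
a divergence error naming the epoch.

Gradient correctness is enforced by tests comparing the analytic
backpropagation gradients against central finite differences (relative
tolerance 1e−6) over random architectures.

## Evaluation protocol

- **Balancing.** When a cohort is dominated by healthy subjects, training
  drifts toward low sensitivity; experiments on a single tumor site
  therefore undersample the majority class to 50/50 (all minority subjects
  kept, seeded uniform draw of the majority, order shuffled).
- **Cross-validation.** Leave-one-out by default (one out-of-fold score
  per subject, matching per-subject scatter reporting); stratified or
  plain k-fold configurable. The feature scaler and the network are
  refitted within each training fold — a leakage test asserts fitted
  statistics are functions of the training subjects only. A fold whose
  training data would contain one class fails loudly.
- **ROC.** All distinct scores serve as thresholds under the rule
  score > t ⇒ pathological; tied scores move the curve diagonally; AUC is
  the trapezoidal area, which equals the tie-aware normalized Mann–Whitney
  statistic (asserted exactly against exhaustive pair counting, and against
  scikit-learn's implementation as an independent oracle, in tests only).
- **Threshold.** The analysis selects the cut-point maximizing Youden's
  J = TPR − FPR, ties broken toward the larger threshold (higher
  specificity). The criterion is a package choice; any ROC-derived
  operating point can be substituted by thresholding `cv_scores.csv`.
- **Reporting.** Confusion counts are stored exactly; accuracy,
  sensitivity and specificity are percentages rounded half-to-even at two
  decimals only for display/serialization.

## Experiment presets and problem sizes

`RunConfig` presets pin the three cohort compositions studied with this
class of device: all tumor sites (69 healthy + 52 cancer, unbalanced),
lung (69 + 21 balanced to 21 + 21 = 42) and laryngeal/oropharyngeal
(69 + 31 balanced to 31 + 31 = 62). Per-stage seeds derive from the master
seed by fixed offsets, so a stage can be re-run in isolation and an
identical config reproduces byte-identical reports.

The test suite and the acceptance script run the end-to-end checks on the
42-subject lung preset with stratified 7-fold cross-validation and an epoch
budget of 1500 (checks every 50, patience 4). Two choices deserve note.
The epoch budget is a scaled-down stand-in for the 1,000,000-epoch default:
on [−1, 1]-scaled features the patience rule converges the fold models well
within it, and AUC — a rank statistic — stabilizes earlier than the loss.
Stratified k-fold (rather than leave-one-out) is used for the null-cohort
check because LOO trains every fold with the held-out subject's class
underrepresented 20:21; under the null this induces a systematic
anti-correlation between scores and labels (fold models lean toward the
overrepresented class), biasing AUC below 0.5 for reasons unrelated to the
pipeline. Stratified folds keep every training fold balanced and still
score each subject exactly once.

## Known limitations

- The simulator's additive, time-invariant class effect is far simpler
  than real VOC signatures; absolute performance numbers on synthetic
  cohorts characterize the pipeline, not the device.
- Turning-point detection assumes a stable cycle period across the
  recording (true of the simulator and of a crystal-clocked instrument);
  period jitter would need per-cycle refinement.
- No confidence intervals on AUC or the derived metrics, no calibration
  analysis, and no multi-site (lung vs laryngeal vs oropharyngeal)
  discrimination — the classifier only separates pathology from healthy.
- Online (per-sample) update order, alternative losses and optimizers are
  out of scope by design; the training scheme is the classical full-batch
  backpropagation the architecture calls for.
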