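# Methods

This package reimplements, as a tested pipeline over synthetic cohorts, a
proof-of-concept analysis in which plasma dofetilide concentration is
estimated directly from the raw 12-lead surface ECG by a convolutional
neural network and compared against the clinical reference — a linear model
on the rate-corrected QT interval.  Everything below is the package's own
account of what it computes and why; all quantitative statements are
reproduced by the test suite or by `scripts/acceptance.py`.

## The scientific setting

Dofetilide blocks the rapid delayed-rectifier potassium current (IKr),
prolonging ventricular repolarization and hence the QT interval.  Because
of its torsadogenic risk the drug requires concentration-aware dosing, yet
levels are monitored indirectly through the QTc.  The hypothesis under
test: the ECG waveform carries concentration information *beyond* the QT
duration (T-wave amplitude and shape changes), which a network consuming
the raw signal can exploit while a QTc-only model cannot.

## Synthetic cohort generator

The generator emulates a thorough-QT-style single-dose study:

* **Protocol grids.** Protocol A: one predose draw plus 15 post-dose draws
  at 0.5–24 h after a single morning dose.  Protocol B: one predose draw at
  −0.5 h plus 13 post-dose draws, with three administrations during the day
  (dose times are a configurable default of 0/5/10 h — the source protocol
  does not publish them).  Each blood draw carries triplicate 10-s, 12-lead,
  500-Hz ECGs.
* **Pharmacokinetics.** One-compartment first-order oral model,
  C(t) = Σ_doses S·D·ka/(ka−ke)·(e^{−ke·Δt} − e^{−ka·Δt}), with defaults
  ka = 1.5 /h, ke = 0.07 /h, D = 500 µg and S chosen so the single-dose peak
  is ≈ 2000 pg/ml — plausible dofetilide-like scales that keep errors
  commensurate with pg/ml levels.  ka = ke is rejected as degenerate rather
  than special-cased.
* **Pharmacodynamics.** QT prolongation follows a sigmoid-Emax law
  ΔQT = Emax·C/(EC50+C), Emax = 80 ms, EC50 = 1000 pg/ml.  An optional
  reverse-use-dependence factor (RR/1 s)^γ is available and off by default.
* **Subjects.** Sexes alternate by study id (balanced ±1).  Inter-subject
  variability enters through the rate-corrected baseline QTc ~ N(390, 20) ms,
  baseline heart rate ~ N(64, 6) bpm, and a morphology gain ~ N(1, 0.15).
  The uncorrected baseline QT at each draw scales as √(RR/1 s), as healthy
  repolarization does, so baseline QTc is rate-stable across subjects — a
  fixed raw QT independent of heart rate would be unphysiological and would
  inflate between-subject QTc variance.
* **Waveforms.** Each beat is a sum of Gaussian deflections (P, Q, R, S and
  an asymmetric T) with lead-specific amplitudes, truncated at ±4σ so the
  inter-beat baseline is exactly isoelectric when noise is off.  RR is
  modulated sinusoidally by ±2% within the record so rate estimation is
  non-degenerate; white noise of 6 µV (default) is added per sample.
* **True QT by construction.** Two tangent landmarks define QT
  analytically: for a Gaussian flank a·e^{−(t−μ)²/2σ²}, the steepest-slope
  tangent meets the baseline at μ−2σ (QRS onset, Q flank) and μ+2σ (T end,
  right T flank), independent of amplitude.  The generator places the
  T-wave centre so the tangent T end lands exactly `qt_ms` after the
  tangent QRS onset.
* **The morphology channel.** Under `duration_plus_morphology`, drug level
  additionally modulates T-wave amplitude (×(1 + 0.35·m)) and left/right
  asymmetry (σ_left/σ_right = 1.15 + 0.25·m) through an offset
  m = gain·C/2000 pg/ml (capped at 2).  The offset is *near-linear* in
  concentration: T-wave shape is modelled as indexing instantaneous channel
  block, while the QT effect keeps its saturating sigmoid.  An earlier
  design coupling m to the saturated effect fraction C/(C+EC50) was
  discarded after a ceiling analysis: even a perfect readout of that offset
  correlates with concentration at only r ≈ 0.84, which defeats the purpose
  of the configuration (isolating information beyond QT duration).  Both
  modulations leave the two tangent landmarks — and hence measured QT —
  untouched, so the channel is invisible to any QT-only model.  Under
  `duration_only` the offset is identically zero.

What the generator does **not** model: ionic-current dynamics, U waves,
ectopy or rhythm disturbance, electrode noise structure (baseline wander,
powerline), steady-state dosing, and circadian autonomic variation.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that its comparative behaviour holds under the stated
statistical structure — not that the published real-data numbers transfer.

## Delineation

R peaks are detected on the squared first derivative (QRS upstrokes are an
order of magnitude steeper than T waves, so slope energy separates beats
even when T amplitude rivals R), then refined to the apex of the raw
deflection.  Per lead and beat, the isoelectric baseline is the median of
the PR segment; QRS onset and T end are tangent projections of the
steepest Q-downslope and T-flank onto that baseline.  The signal is
smoothed with a 7-sample (14 ms) moving average before slope estimation;
this stabilizes the steepest-slope pick under noise at the cost of a small
constant onset bias (≈ +4 ms in QT, well inside the ±10 ms recovery
budget).  QT is the mean over all complete beats (≥ 5 required, following
the 5–10-beat averaging guidance), aggregated across leads by the median;
≥ 8 usable leads are required or the record is flagged unusable.  Every
threshold is relative, making the whole measurement invariant to amplitude
rescaling.  Bazett (QT/√RR[s]) and Hodges (QT + 1.75·(HR−60)) corrections
are both computed; Bazett feeds the linear model, which matched the
reference analysis's choice.

The uncertainty in this design: the source analysis does not state its QT
measurement algorithm.  The tangent method at both landmarks is this
package's choice, made symmetric so the generator can define ground truth
against the same operational definition.

## Models

**Linear reference.**  Ordinary least squares of concentration (pg/ml) on
Bazett QTc (ms), one pooled model over all training replicates.  Negative
predictions are reported as-is by default (the estimator stays affine);
degenerate designs (< 3 pairs, zero QTc variance) are refused.

**Deep model.**  Input is the raw [12 × 5000] record.  Six temporal
convolution blocks ([1×k] kernels, zero padding, k non-increasing and the
filter count non-decreasing with depth) run per lead, each followed by
batch normalization and ReLU; a seventh [12×1] convolution combines the
leads; the flattened features feed fully connected layers of 128 and 64
units (BN, ReLU, dropout 0.5 each) and a single linear output neuron.
Weights are Xavier-initialized; the loss is MSE with no additional
regularization; optimization is Adam.  Per-layer temporal downsampling is
implemented as the convolution's stride (mathematically identical to
keeping every p-th output sample, and ~5× cheaper at the first layer);
the first layer also skips its unused input gradient.  All layers are
NumPy with hand-written backpropagation, gradient-checked against central
differences in the test suite.

Sizes the reference analysis leaves unstated are configuration: the
default configuration uses filters (16,16,32,32,64,64), kernels
(64,32,16,16,8,8) and downsampling 2 per layer (≈ 7.8×10⁵ parameters); the
*demo* configuration used by the analysis scripts and acceptance run uses
filters (4,4,8,8,16,16), kernels (16,16,8,8,8,8), downsampling
(5,5,4,2,2,2) and a 16-filter combiner (≈ 3×10⁴ parameters), sized to
train in minutes on one CPU.

Inputs are z-scored per lead with training-set statistics; targets are
standardized and de-standardized at prediction.  10% of the training
*subjects* (not records) form the internal validation set: replicates of
one subject are strongly correlated, so a record-level split would select
checkpoints for within-subject memorization rather than the cross-subject
generalization the test protocol measures.  The checkpoint with minimum
validation MSE is kept.  The learning rate (3×10⁻³ in the demo recipe,
batch 64) decays by 1/3 after two thirds of the epochs.  Training is
deterministic given the seed on a fixed platform/BLAS.

## Evaluation protocol

Subjects are split by study-id order within sex: the last six male and six
female subjects form the test set (30/12 for the 42-subject study); small
synthetic cohorts scale the rule to ⌈n_sex/7⌉ per sex, recorded in report
metadata.  Each replicate ECG is predicted separately; the median of the
triplicate predictions is the draw-level estimate (aggregate first,
correlate second).  Reported per model: Pearson r between draw-level
predictions and measured levels, and the mean ± SD of the absolute error
in pg/ml.  The "± SD" reading of the published error summaries is adopted
(their SDs exceed a standard error's plausible size and the values are
non-negative, consistent with |error|); a signed-error mode exists behind
a flag.  Reports include the per-subject baseline/peak QTc table (baseline
= predose draw; peak = draw at maximal measured concentration, flagged
rather than fabricated for all-placebo subjects) and per-subject
time-course plots.  A leakage guard asserts from artifact provenance that
no test subject contributed to training.

## Numerical choices and degenerate inputs

* Quantization to the 2.5 µV acquisition grid is an explicit optional step;
  WFDB-dialect storage (format 16, 400 ADU/mV) quantizes by construction,
  bounding round-trip error at half a step (1.25 µV).
* Ties in steepest-slope location break toward the earlier sample
  (`argmin` semantics).
* Leads are mapped by name, never position; a missing lead is an error
  naming the lead.
* `ka = ke` in the PK model raises a degenerate-PK error; the limiting form
  is intentionally not implemented.
* Records whose heart rate falls outside 30–200 bpm, leads with < 5
  complete beats, and records with < 8 usable leads are flagged/missing
  rather than silently imputed.

## Problem sizes used by the shipped runs

The analysis scripts, the acceptance run and the heavyweight tests use the
42-subject protocol-A cohort (30 train / 12 test; 2016 records) with the
demo network configuration, 12–24 epochs — about 10 s per epoch on one CPU.
The 2-point memorization audit uses 40 records; the label-permutation null
uses a 10-subject cohort.  These sizes are the package's choices for a
desk-scale, single-CPU reproduction of the study's comparative claim.

## Known limitations

* The published headline values (r = 0.85 vs 0.64; errors 296±347 vs
  487±432 pg/ml) were computed on the external trial recordings and are
  not reproduction targets here; the synthetic analogue reproduces the
  qualitative ordering and magnitude, not those numbers.
* The real-data harness's annotation mapping is best-effort and untested
  against the deposited databases' native layouts.
* The NumPy network trains small configurations comfortably but is not a
  general-purpose deep-learning stack (no GPU, no autodiff beyond the
  layers implemented).
* Placebo arms are supported and tested, but the default study condition
  is all-dofetilide (the source trials were cross-over; the analysed
  samples are drug exposures).
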