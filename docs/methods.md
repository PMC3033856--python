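# Methods

This note documents the models and procedures implemented in `fhrscreen`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic-data experiments do and do not show.

## Signal model and preprocessing

The input is a single-channel fetal heart rate (FHR) series in beats per
minute, uniformly sampled at 4 Hz (the rate commercial cardiotocographs
emit), nominally 20 minutes long (4800 samples). Two artifact classes are
handled before any analysis:

* **Spikes** — single samples produced by autocorrelation errors. A sample
  deviating from *both* neighbours, in the same direction, by more than
  `jump_bpm` (default 25 bpm) is replaced by the neighbour mean. Spike
  correction runs before dropout removal so that a spike adjacent to a
  dropout run does not widen it.
* **Missing beats** — dropouts from transducer displacement, encoded as
  0 bpm or values outside the physiological 50–220 bpm band. Maximal
  dropout runs are excised recursively (the first run is removed and the
  procedure recurses on the concatenation); an optional mode bridges runs
  shorter than `interpolate_below_s` seconds by linear interpolation
  instead. Excision shortens the trace; the downstream decomposition is
  length-agnostic, and this matches the convention that dropout segments
  are eliminated rather than imputed. A trace losing more than
  `usability_cutoff` (default 0.4) of its samples is flagged unusable and
  excluded from analysis, with the exclusion logged.

## Empirical mode decomposition

`fhrscreen.emd` implements classical sifting. For the current iterate q:
local maxima and minima are located (a plateau flanked by opposite slopes
contributes one extremum at its midpoint, floored); each extrema set is
extended by mirroring its two outermost points about the corresponding
trace end, which suppresses spline end-swings; natural cubic splines
through the extended maxima and minima give the upper and lower envelopes,
and their pointwise mean m is subtracted, q ← q − m. The pass repeats
until the sum-of-difference between successive iterates,

    S_D = Σ_t |q_{k−1}(t) − q_k(t)|² / q²_{k−1}(t),

drops below `threshold` (default 0.2, the conservative end of the
conventional 0.2–0.3 range) *and* the iterate satisfies the IMF condition
(extrema and zero-crossing counts differ by at most one), or `max_iter`
passes have run. The accepted IMF is subtracted from the signal and the
procedure repeats on the residual until it has fewer than two maxima or
two minima, or `max_imfs` (default ⌊log₂ n⌋) components exist.

Numerical notes:

* Terms of S_D with q²_{k−1}(t) < 1e−12 are excluded from the sum; if all
  terms are excluded the criterion returns +∞. On long bpm-scale traces
  the surviving near-zero denominators still dominate the sum, so S_D in
  practice stalls far above 0.2 and `max_iter` (default 100) is the
  binding stop for most components. The cap is therefore a real model
  parameter, not merely a safety rail: it sets the sifting depth, and 100
  passes drives the envelope mean essentially to zero.
* Over-sifting can transiently re-break the extrema/zero-crossing
  condition (envelope overshoot spawns small extrema without sign
  changes). The sifting loop therefore remembers the most recent iterate
  that satisfied the condition and restores it if the budget runs out on
  an invalid one, so every accepted IMF satisfies the condition.
* The envelope splines are computed by a direct tridiagonal (Thomas)
  solve with natural end conditions, numerically identical (≤ 1e−14) to
  `scipy.interpolate.CubicSpline(bc_type="natural")` but evaluated on the
  integer sample grid in O(n), which keeps a 4800-sample decomposition
  around 0.2 s.
* Reconstruction x = Σ cᵢ + r holds to float round-off by construction
  (every residual is formed by exact subtraction).
* If a signal is monotonic (no two maxima/minima) no IMF is extractable
  and the decomposition returns zero IMFs with the signal as residue;
  `sift_imf` called directly on such input raises `MonotonicSignalError`.

## Noise-order estimation and denoising

Low-order IMFs of FHR traces carry wideband measurement noise and have
zero mean. For M = 1, 2, … a two-sided one-sample t-test asks whether the
mean of the partial sum c₁+…+c_M over samples deviates from zero at level
`alpha` (default 0.05). P_t is the largest M before the first rejection
(0 if M = 1 already rejects; the IMF count if nothing rejects). To avoid
over-smoothing the removal depth is capped: P_f = min(P_t, 3). Denoising
is partial reconstruction over the retained suffix c_{P_f+1}…c_{N_f}, the
residue included.

The t-test deliberately treats samples of the partial sum as independent;
no autocorrelation correction is applied. This overstates the effective
sample size, making the test anti-conservative, and is retained as part
of the procedure being implemented. A consequence seen on synthetic data:
IMFs of a sifted decomposition are almost exactly zero-mean, so the test
often never rejects, P_t equals the IMF count, and the cap P_f = 3 binds.
Denoising then always removes the three fastest components. When the
clean physiological signal itself has power in the fast band, that costs
signal — the denoised trace can correlate *less* with the clean signal
than the noisy input does. The denoising test in the suite therefore uses
low-variability traces (smooth clean signal, noise confined above 1.2 Hz),
where removal is a fair win; this is a genuine limitation of fixed-cap
partial reconstruction, not an implementation artifact.

## Features

Each retained component is summarised by its sample standard deviation
(N−1 denominator). The feature vector has a fixed width of 10 slots —
denoised 20-minute traces retain about 7–10 components — indexed by
*post-cut position*: slot k is the k-th retained (fast-to-slow) component
regardless of each trace's P_f, so slot semantics are comparable across
records. Slots beyond the retained count hold a pad value (default 0,
which maps near the scaling midpoint after [−1, 1] scaling; mean-fill is
configurable). Components beyond the 10th, the slowest, are dropped.

The discriminative premise is clinical: reduced beat-to-beat variability
(an at-risk marker) depresses the SD of the fast retained components;
decelerations inflate the slow-component SDs. Neither is assumed by the
code — the classifier receives all 10 SDs.

## Classifier

A soft-margin SVM with RBF kernel K(a,b) = exp(−γ‖a−b‖²). Features are
affinely scaled to [−1, 1] with training-set minima/maxima (degenerate
features map to the midpoint); the identical transform is applied at
prediction time. Class imbalance is handled by per-class penalties with
C⁺/C⁻ equal to the inverse cardinality ratio n⁻/n⁺; the weights are
realised as multipliers n/(2 n_class) on a single base C, which fixes the
ratio while keeping the geometric mean of the penalties near C. The dual
quadratic programme is solved by scikit-learn's SVC (tolerance 1e−3);
support vectors, dual coefficients αᵢdᵢ and bias are then extracted and
all predictions are computed by this package's own kernel path, so a
model serialised to JSON text reloads with bit-identical predictions.
A decision value of exactly zero maps to +1 (normal).

(C, γ) defaults are 4 and 2 — the operating point the original procedure
estimated for clinical data — but for a new dataset the classification
procedure prescribes selection: a coarse pass over exponential grids
(C = 2⁻⁵…2¹⁵, γ = 2⁻¹⁵…2³, two-octave steps) followed by a half-octave
refinement around the best cell, scored by stratified CV accuracy with
ties broken towards smaller C then smaller γ. The end-to-end evaluations
in this package use that grid search rather than the fixed (4, 2), which
was tuned to a different dataset.

## Evaluation

"At risk" (−1) is the positive class; this is the only assignment
consistent with the reference design's printed rates and class counts.
Sensitivity S_T = tp/(tp+fn), specificity S_P = tn/(tn+fp), geometric
mean G_M = √(S_T·S_P) (the imbalance-robust summary), accuracy, and
Cohen's kappa κ = (p_a − p_e)/(1 − p_e) with p_e from the marginal
products. The 95 % CI is the large-sample form κ ± 1.96·SE with
SE = √(p_a(1−p_a)/(n(1−p_e)²)). Stratified k-fold CV (default k = 5)
refits the scaling transform and the class weights on each training
portion; CV accuracy is pooled (total correct / n), not mean-of-folds.
An empty class leaves the affected rate undefined (NaN), not zero.
Rates are reported in percent to two decimals.

## Synthetic FHR generator

Each trace is baseline (110–160 bpm) + band-limited variability (40
random-phase sinusoids with frequencies uniform in 0.03–1 Hz, scaled so
the RMS is half the variability amplitude, default 10 bpm) + Gaussian-bell
accelerations (+15 bpm) and decelerations (−25 bpm) of ~40 s + Poisson
spikes (±35–55 bpm, default 0.5/min) + zeroed dropout runs of 1–10 s
placed to hit the target missing fraction exactly. Values outside
dropouts stay within 50–220 bpm. Class presets: normal draws variability
from 8–14 bpm with 2–5 accelerations and no decelerations; at-risk scales
variability by 1 − 0.6·effect_size (0.4× at full effect, within the
clinical "reduced variability" convention), replaces accelerations with
2–4 decelerations, and is otherwise identical. `effect_size = 0` makes
the class distributions identical (a null configuration); 1 is the
default study condition. All per-trace seeds derive from one dataset
seed.

What the generator does *not* emulate: beat-level cardiac dynamics (the
pipeline only consumes the 4 Hz trace, so spectral realism in the
0.03–1 Hz band suffices), uterine activity, sinusoidal pathology
patterns, gestational-age effects, or expert-labelling noise. Passing
tests therefore show that the pipeline recovers class structure of this
kind at these effect sizes — not that it reproduces clinical performance
figures, whose recordings are not publicly available.

## Problem sizes used in the test suite

End-to-end checks use the reference design's cohort sizes: 60 records
(20 normal / 40 at-risk) for cross-validation experiments and 30/30 for
the feature-premise replicates, with 20-minute traces. The 20-replicate
null experiment (effect_size = 0) uses 10-minute traces: the null
hypothesis concerns label-independence of the features, which trace
duration does not affect, and the shorter traces keep the replicated
experiment proportionate. The acceptance script runs the full 90-record,
20-minute design.

## Known limitations

* The S_D stopping criterion is effectively inoperative on long traces
  (see above); sifting depth is governed by `max_iter`.
* The partial-sum t-test ignores autocorrelation and the P_f cap can
  remove genuine fast physiological content.
* Feature slots are positional after the P_f cut; if P_f varied wildly
  across records, slot semantics would drift (observed P_f values are
  stable at 3 on synthetic data).
* Binary classification only; no probability calibration; RBF kernel
  only.
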