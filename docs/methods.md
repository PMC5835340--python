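# Methods

This note records the models the package implements, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and do
not demonstrate.

## Signal model of the synthetic generator

Each trial is a channels × time array sampled at `sampling_rate` (default
128 Hz): a pre-stimulus baseline of `baseline_duration` s followed by a
post-stimulus interval of `trial_duration` s. Every channel is a sum of
unit-amplitude cosines, one per carrier frequency (default: 20 Hz, in the
beta band), plus white Gaussian noise of SD `noise_sd`.

Phases are piecewise constant: they are redrawn once per `jitter_refresh`
seconds (default 1 s, deliberately equal to the analysis epoch length, so
the generator's independence structure matches the PLV estimator's
ensemble). After stimulus onset, the two channels of a planted edge share a
common uniform phase per segment, each perturbed by independent Gaussian
jitter of SD `coupling_pos` (class +1) or `coupling_neg` (class −1); all
other channels, and every channel during the baseline, draw independent
uniform phases. Because the planted phase difference is N(0, 2·sd²), the
population PLV of a planted edge is exactly exp(−sd²) — the generator's
knob maps analytically onto the quantity the connectivity stage estimates.
A channel listed in several planted edges follows the lowest-indexed edge
containing it. One seeded generator is consumed in a documented order
(trial permutation first, then per-trial draws), so identical configs are
bit-identical.

Defaults are chosen to emulate the canonical task-EEG design this package
targets: 61 sensors, 280 trials split 100/180 between classes, 20 planted
edges, and a beta-band carrier. Two deliberate departures from typical
acquisition parameters:

* the sampling rate is 128 Hz rather than 1000 Hz — all analysis bands lie
  below 40 Hz, and the tenfold smaller arrays keep the full benchmark
  (280 × 61 × 12 s) cheap to regenerate;
* the baseline is 4 s rather than the few hundred milliseconds typical of
  ERP designs. This is forced by the wavelet width below: with σ_t = 7/f,
  the truncated support margin is 4σ_t = 2 s at 14 Hz, and a baseline must
  contain at least two fully valid 1-s epochs to serve as a normalization
  reference at every beta-band frequency.

What the generator does **not** emulate: 1/f background spectra, volume
conduction (instantaneous mixing that inflates zero-lag synchrony between
neighboring sensors), evoked components, and artifacts. Passing the
planted-edge benchmarks therefore shows that the estimator–selector–
classifier chain recovers a known coupling structure at realistic sample
sizes; it does not show robustness to mixing or artifacts in real EEG.

## PLV estimation

Instantaneous phase at frequency f is the argument of the convolution with
a complex Morlet atom with σ_t = 7/f, truncated at ±4σ_t; the atom is
scaled so a unit cosine at f has unit amplitude (the PLV is amplitude-blind
either way). Samples within the truncated support of a recording edge are
flagged invalid, and only epochs lying entirely in the valid region enter
any ensemble.

The estimator treats the nonoverlapping 1-s post-stimulus segments of a
single recording as the averaging ensemble: per within-epoch time bin, the
modulus of the mean unit phasor of the phase difference across epochs;
then the mean over bins; then the arithmetic mean over the band's center
frequencies (default grid: 1 Hz spacing across the band; named bands
Low 1–8 Hz, Medium 8–30 Hz, High 30–80 Hz, beta 14–30 Hz — Low starts at
1 Hz to match the 1–100 Hz acquisition band-pass).

Two finite-ensemble facts matter when reading PLV values:

* with E epochs, the null (uncoupled) PLV concentrates near √(π/4E)
  (≈ 0.36 at the default E = 6), not 0;
* the wavelet's 2σ_t ≈ 0.7 s smoothing is not small against the 1-s
  segments, which correlates neighboring epochs slightly and biases the
  empirical null a little below the iid value, and leaks a little
  baseline into the first post-stimulus epoch. Tests assert the analytic
  values exactly at the phase level and with small tolerances at the
  pipeline level.

**Baseline normalization.** The pre-stimulus epochs give a per-frequency
baseline PLV time course; post-stimulus per-bin values are z-scored
against its mean and SD before bin- and band-averaging. Normalization is
defined for PLV only; correlation features are always raw. Note the
baseline ensemble (2 epochs at the defaults) is smaller than the
post-stimulus one, so the two null levels differ and normalized null edges
sit at a nonzero offset — harmless for classification (the offset is
class-independent) but visible in the values.

**Default measure: raw PLV.** On the planted-edge benchmark the
baseline-normalized features recover the planted set markedly worse than
raw PLV (Fisher precision@20 0.75 vs 1.0): with a 2-epoch baseline the
z-score's denominator is itself a noisy estimate and its trial-to-trial
variability swamps the class contrast. Normalization earns its keep when a
stable baseline reference exists (many trials, or long baselines); with
per-recording references it mostly injects estimator noise, so the package
defaults to raw PLV and leaves `plv_normalized` selectable.

## Classifiers

All solvers are dense and deterministic; every fitted model records its
solver status. Decision value 0 predicts +1; a twin-model tie predicts +1.

**Soft-margin SVM** is solved by libsvm (scikit-learn `SVC`, tol 1e−8)
behind the package's estimator surface; the full-length dual vector α
(0 ≤ αᵢ ≤ C, Σαᵢyᵢ = 0) is exposed for the RFE criterion. Tests verify the
dual objective against a hand-coded SLSQP QP on small instances.

**Twin-bounded SVM.** Each subproblem
min ½‖Aw + e b‖² + (c₃/2)(‖w‖² + b²) + c₁eᵀξ s.t. −(Bw + e b) + ξ ≥ e,
ξ ≥ 0 is solved through its dual, a box-constrained QP with Hessian
G(HᵀH + c₃I)⁻¹Gᵀ, minimized by L-BFGS-B; c₃, c₄ > 0 make the inverses
well-posed (this is why the bounded variant, not the original twin
formulation, is the default; the original is the limit c₁ = c₂ = ε). The
kernel variant substitutes K(A, 𝕏) and K(B, 𝕏) over the class-sorted
training matrix; the prediction rule normalizes by the feature-space norm
√(u_kᵀK𝕏𝕏u_k). The regularizer is applied to b as printed in the
formulation (whether the offset should be penalized is a formulation-level
ambiguity; implemented as written).

**ξ-SOCP SVM.** The two cone constraints share a single scalar slack ξ (as
formulated — not per-point slacks). The offset b appears in no objective
term, so the solver eliminates it: a feasible b exists iff
vᵀ(μ₁ − μ₂) − κ₁‖v‖_Σ₁ − κ₂‖v‖_Σ₂ ≥ 2(1 − ξ), leaving a reduced convex
program over (v, ξ) solved by SLSQP with analytic gradients and a smoothed
norm √(vᵀΣv + ε), ε ≈ 1e−12·tr(Σ)/d. Both constraint functions are
positively homogeneous in v, so at any optimum with v ≠ 0 the summed
constraint is tight and b is the single point of its interval (the solver
takes the interval midpoint, which coincides there). Covariances are
biased (1/m_k) estimates, symmetrized, negative eigenvalues clipped, plus
a ridge of 1e−8·trace/dim — the kernel-space Ξ_k is rank-deficient by
construction and needs this. The kernelized program replaces
(w, I, μ_k, Σ_k) by (s, K, g_k, Ξ_k) with the kernel blocks built from the
chosen kernel function and the centering matrix (I − (1/m_k)e eᵀ); under
the linear kernel it reproduces the input-space model's decision values
(tested to 1e−4). Solver failure raises — the fit never silently returns a
guess.

η₁ applies to the class labelled +1 and η₂ to −1; which experimental class
is "positive" is the caller's configuration.

## Edge selection

The Fisher score uses |μ⁺ − μ⁻| in the numerator over the summed class
variances: the printed form of this criterion is sign-sensitive, which
would make the ranking depend on an arbitrary class-labelling choice; the
signed value is stored alongside. Features constant in both classes score
0 with a warning. All ties, everywhere, break toward the lower column
index so reruns are deterministic.

RFE eliminates in chunks down the evaluated grid
{d, 1000, 500, 250, 100, 50, 20, 10} rather than one feature at a time —
refitting 1830 times per fold would be pointless when only these counts
are ever evaluated. Criteria per round: kernel models use the margin
sensitivity |W²(α) − W²₍₋ⱼ₎(α)| with α frozen (computed in O(m²) per
feature via the one-feature kernel update); linear models — including the
linear ξ-SOCP, whose RFE combination is the package's headline selector —
use |w_j|, which is the same criterion exactly (W² − W²₍₋ⱼ₎ = w_j²,
tested to 1e−8). The kernel ξ-SOCP criterion freezes s instead of α and is
flagged experimental. Two perfectly correlated informative features split
their weight; at most one survives an aggressive schedule step — this is
inherent to margin-based backward elimination and documented rather than
patched.

Consensus selection intersects the top-k edges of two rankings (default
pairing: Fisher and linear-RFE), ordered by the better of the two rank
positions. A plain intersection is used, not a rank product; disjoint
top-k sets yield a valid empty result. k defaults to the evaluation
stage's optimal edge count, with an explicit override.

## Evaluation protocol

Outer 10-fold and inner 5-fold splits are both stratified — with a
100/180 class split, unstratified folds can lose a class entirely; the
inner fold count is a package default where only "further split" is
specified. Edges are ranked once per outer fold on the full outer-training
set (the inner loop then tunes hyperparameters and the edge count against
that ranking); outer test rows reach nothing before the final scoring, an
invariant the tests assert by instrumenting the ranking stage. Reported
accuracy is the plain test accuracy averaged over outer folds (matching
the conventional tabulated form) with balanced accuracy logged alongside:
under label permutation, plain accuracy concentrates at the majority rate
(64.3% at 100/180), so the chance-level calibration check is asserted on
balanced accuracy, whose null is 50% for any class prior. A single master
seed expands deterministically into all fold seeds; a `budget` option caps
the hyperparameter enumeration for smoke runs.

## Benchmarks and what passing them means

* **strong** (0.3 vs 1.2 rad jitter, noise SD 0.5): planted population
  PLVs 0.91 vs 0.24. Fisher precision@20 and consensus(top-50) recall are
  ~1.0, nested-CV accuracy ~100%: the chain recovers a clear planted
  structure essentially perfectly, and the permutation null stays at
  chance — no selection-induced optimism leaks through the nesting.
* **weak** (0.9 vs 1.3 rad, noise SD 1.0): planted PLVs 0.44 vs 0.27
  against a 0.36 ensemble floor. Accuracies fall to the 60–75% range and
  the accuracy-versus-count curve peaks at small edge counts, ~5–11
  points above the all-1830-edges accuracy: the regime where discarding
  noise edges is what buys performance.

Both benchmarks fix all generator parameters, including seeds derived from
a single CLI seed; their sizes (280 trials × 1830 edges, ~40 s of feature
extraction and ~1 min of nested CV each) were chosen so the full
validation cycle stays in single-digit minutes on one CPU.

## Known limitations

Sensor-space analysis only (no source reconstruction, no leakage
correction); synchrony measures limited to correlation and PLV; the SOCP
solver is dense and intended for the moderate dimensions that follow
feature selection, not for d ≈ 10³ fits inside tight loops; EDF files are
read (via MNE) but not written; evoked-activity subtraction is out of
scope — the generator produces no evoked component, and removing one
requires repeated identical stimuli.
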