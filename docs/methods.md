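# Methods

This note records the models, numerical choices and limitations behind
`gaitsym`, in the order the pipeline runs them.

## Synthetic bilateral GRF generator

**What it emulates.** Overground running-stance recordings from a single
force plate sampled at 1000 Hz: one ~0.25 s contact per trial, flanked by
0.1 s of sub-threshold "flight" ripple (5–20 N vertical) so stance
detection is exercised rather than trivial. The design is 14 subjects × 3
trials × 2 sides × 2 conditions (pre/post fatigue) by default; subject
masses are drawn from Normal(70.17, 6.57²) kg truncated to [50, 95] and
ages from Normal(22.93, 1.07²), matching the descriptive statistics of the
amateur-runner cohort this design mirrors.

**Waveform model.** Each axis is a sum of Gaussian bumps in normalized
stance time, pinned to exactly zero at both contact endpoints by removing
the straight line through the (tiny) endpoint tails; the vertical axis is
additionally clipped at zero. Defaults: vertical impact peak 0.9 BW at 13%
stance (σ 4.5%) plus active peak 2.5 BW at 45% (σ 18%); anterior–posterior
braking −0.3 BW at 25% and propulsion +0.3 BW at 75%; two mediolateral
bumps ≤ 0.15 BW. No published waveform parameterization exists for this
cohort, so these values are chosen to reproduce textbook running-GRF
morphology (distinct impact/active vertical peaks of 1–3 BW, braking →
propulsion zero crossing near mid-stance, small mediolateral forces); they
are a modelling choice, not a fit. Gaussian mixtures were picked because
they are smooth, differentiable and parameter-sparse.

**Asymmetry injection.** Asymmetry is applied to the left limb only, per
axis: an amplitude ratio, a time shift (stance fraction), additive regional
Gaussian bumps, and an optional fatigue bump active only in the post
condition. Three presets exist: `null` (identity), `dominance`
(mediolateral ratio 1.10 plus a broad 0.05 BW mid-stance bump, with 3%/1%
amplitude ratios on Y/Z), and `dominance+fatigue`, which adds a 0.06 BW
late-stance mediolateral bump in the post condition.

The fatigue bump's height was fixed a priori by a power argument: with
noise sd 0.02 BW per curve, the left−right difference has sd ≈ 0.028 BW,
and the folded-normal mean shift from adding 0.06 BW is ≈ 0.038 BW. Scaled
by the SF amplitude on the mediolateral axis (A ≈ 6–7), averaged over 3
trials and differenced across conditions within subject, the expected
paired-t at the bump centre is ≈ 8 at n = 14 — comfortably above 1D
random-field thresholds (~3.9) without being degenerate. The bump is
centred at template fraction 0.828 (σ 0.025): the 30 N detector crops the
sub-threshold template tails (≈ [0.02, 0.93] of the full contact at the
mean mass), so that fraction lands at ~89% of the *detected* stance, i.e.
the effect occupies nodes ~86–92 of the 101-node grid.

**Noise.** White Gaussian noise convolved with a Gaussian kernel of stated
FWHM (default 12 nodes on the 101-node grid, converted to raw samples),
with independent draws beyond the edges so the field is stationary with
exactly unit marginal variance, then scaled to the target sd (default 0.02
BW). This makes the smoothness assumption of random-field inference
literally true, which is the point: the generator is a calibration
instrument for the inference machinery. What it does **not** model —
inter-stride waveform variability beyond additive noise, subject-specific
waveform shapes, footwear/speed effects, non-stationary noise near impact,
cross-axis noise correlation — means passing tests validate the *analysis
chain*, not claims about real runners.

## Preprocessing

Stance is the longest run of samples with vertical force ≥ 30 N (inclusive
at both ends; runs shorter than 0.1 s are discarded as aiming steps or
plate grazes, ties go to the earliest). All three axes are cropped with the
single vertical window, resampled to 101 nodes with an interpolating cubic
spline over normalized time (endpoint samples reproduced exactly;
extrapolation never occurs because cropping is inclusive), and divided by
10 × body mass. No filtering is applied by default — a zero-phase
Butterworth low-pass hook exists but is off, since the processing
convention this package follows applies none.

## Symmetry function

The pointwise field `SF(t) = A·|x_r − x_l|` with `A = 2/(range x_r +
range x_l)` is the primary object; the printed-integral form is exposed as
its trapezoidal summary over normalized time in [0, 1]. The asymmetry
threshold comparison is strict (SF > 0.05). Left/right trials are paired
i-th with i-th within (subject, condition) in trial-index order — sides are
collected in separate passes in this design, so no intrinsic pairing
exists; index pairing is the deterministic choice. Trial-mean SF curves are
the default aggregation for summaries; pooled per-trial curves remain
available. Two constant curves make A undefined and raise
`DegenerateAmplitude` rather than returning infinity. Note SF is sensitive
to an additive offset on one limb even though both ranges are unchanged —
intentional, and asserted in tests.

## 1D SPM paired inference

Per node, the paired t statistic with ν = n−1 (sd with n−1 denominator);
nodes with zero difference variance and nonzero mean are flagged ±∞,
excluded from smoothness estimation, and reported. Smoothness is the
residual-gradient estimator: residuals scaled to unit variance per node,
FWHM = √(4 ln 2 / ⟨grad²⟩), clipped to [1, 1000] nodes (all-zero residuals
→ upper clip, i.e. "infinitely smooth"). Resels = 100/FWHM. The critical
threshold solves E[EC](t*) = α (α/2 per tail; two-tailed is the default
since differences in either limb's favour are of interest) by bisection on
[0, 100]; at resels → 0 it reduces to the Student quantile, which the tests
assert to 1e−6. Thresholds around 3.5–3.6 at ν = 13 correspond to resels ≈
5–7 by inverting the same equation (`implied_resels`), bracketing the range
reported for comparable bilateral running data.

Cluster p-values come from sign-flip permutation of the paired differences,
using the null of the maximum suprathreshold cluster extent: Monte Carlo
`p = (1 + #{null ≥ obs})/(n_perm + 1)`, or the exact proportion over all 2ⁿ
sign patterns when that is no larger than the permutation budget (n = 4
pairs is enumerated, and the tests compare against an independent
brute-force oracle). Permutation was chosen as the primary cluster-p
backend because it is exact, assumption-light and enumerable in tests;
RFT expected-cluster-extent p-values would be an alternative backend.
Cluster edges snap to integer nodes (no fractional interpolation), matching
how such intervals are conventionally reported. SPM comparisons in the
pipeline run on subject-mean curves (ν = 13 for 14 subjects), not pooled
trials.

Calibration, measured not assumed: over 500 null simulations with smooth
noise, the familywise rate of any suprathreshold cluster at α = 0.05 is
≈ 0.03–0.07 (seed-dependent), and the injected fatigue effect is recovered
as a significant cluster overlapping nodes 86–92 in ≳ 90% of replicates
with no Y/Z clusters in ≳ 90% — both recomputed by `scripts/acceptance.py`
and the test suite.

## Kernel SVM

The soft-margin dual is solved by a from-scratch SMO loop with libsvm-style
working-set selection (first-order choice of i, second-order choice of j),
β initialized at 0, deterministic for a fixed row order. Dual feasibility
(0 ≤ β ≤ C, Σβᵢyᵢ = 0) holds exactly at every iteration by construction.
The stopping tolerance is 1e−3 on the maximal KKT violation — libsvm's own
default — with 30 000 pair updates as the iteration budget; on strongly
overlapping classes at large C, polishing the dual to much tighter
tolerances takes millions of working-set steps for any SMO (including
libsvm) while leaving predictions unchanged, so the solver then returns the
current feasible iterate with `converged=False` and a warning
(`strict=True` raises instead). Held-out predictions agree with libsvm via
scikit-learn on random problems (asserted ≥ 95% in tests; observed ~100%).

Kernels: LINEAR `u·v`; RBF `exp(−G‖u−v‖²)`, i.e. σ² = 1/(2G) — the G
reported by grid search is the libsvm gamma, stated here prominently
because width conventions differ; POLY `(u·v+1)^d` with default order
d = 3 (configurable; order 2 is common in gait-video work). Features (101
stance nodes) are standardized per node with training-fold statistics only,
so no leakage enters cross-validation. Grid search defaults to C ∈ 2^{−5..15},
G ∈ 2^{−15..3} in log₂ steps of 2 (the pipeline uses a compact 4 × 4 grid
for routine runs); ties break toward smaller C then smaller G. Five-fold
stratified cross-validation with seeded fold assignment is the model
selection criterion.

Two recognition tasks: left-vs-right from per-trial GRF stance curves
(feature 1 = left = −1, feature 2 = right = +1; both conditions pooled by
default since the task definition is side, not state), and pre-vs-post
fatigue from per-trial SF curves. Hold-out fractions default to ~20% (LR)
and ~29% (fatigue), echoing test-set sizes of 34/168 and 24/84; an optional
subject-grouped split is provided because trial-level splitting lets
subject identity leak between train and test — the grouped option is the
honest protocol, the trial-level default mirrors common practice.

ACC/SEN/SEP are computed exactly as `ACC = (T1+T2)/n`, `SEN = T1/(T1+F2)`,
`SEP = T2/(T2+F1)`, where T1/T2 are correctly recognized feature-1/2
samples and F1/F2 are feature-1/2 samples misrecognized. These are the
conventional printed formulas in this literature; note their denominators
are predicted-class totals, not true-class totals, and the package keeps
them verbatim because the confusion-matrix inversion solver must invert
exactly what is printed. The solver enumerates all non-negative integer
(T1, T2, F1, F2) summing to n and keeps matrices whose exact metrics round
to the stated values at their printed precision; it reports a unique
solution, all solutions (`AmbiguousSolution`), or `NoSolution`. Two metrics
plus n sometimes suffice (the n = 24 ACC/SEP pair has a unique solution);
others need the full triple (the n = 24 ACC/SEN pair admits 7 matrices).
One published-style n = 34 triple (85.294%, 84.2%, 93.3%) is certified
internally inconsistent by exhaustive enumeration — no integer confusion
matrix produces it. Relatedly, two different C values (33.506 vs 35.506)
appear for the same model in the source material's text versus its table;
the package takes no side, as neither value enters any computation here.

## Pipeline and reproducibility

One root seed drives everything; stages derive their seeds by fixed offsets
(simulate +0, SPM +101, classify +211), so single stages re-run from
intermediate files reproduce full-run outputs exactly, and two runs with
the same config are identical modulo the output directory. All
intermediates are plain CSV/JSON. `validate_config` returns every
violation at once rather than failing on the first.

Default problem sizes — 14 subjects × 3 trials for datasets, 500 null
simulations for calibration, 25–50 replicates for recovery rates, 199–999
permutations, 4 × 4 pipeline grids — were chosen so a complete run and the
full test suite each finish in minutes on one CPU while keeping Monte Carlo
error well inside the asserted bands.

## Known limitations

* The generator's amplitudes cannot be validated against published values
  (none exist for this design); they are calibration-free by construction.
* RFT thresholds use the single-interval EC expansion; very rough fields
  (FWHM < ~3 nodes) push its accuracy, though the permutation backend does
  not depend on it.
* The SMO solver targets problems of a few hundred samples (no kernel-row
  caching or shrinking); it is not meant for large-scale use.
* Real-data SF magnitudes and classifier accuracies depend on cohort,
  footwear and speed; the synthetic defaults reproduce qualitative
  orderings (mediolateral most asymmetric; left/right easier to recognize
  than fatigue state), not any particular published percentage.
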