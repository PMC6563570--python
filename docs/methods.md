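# Methods

This note documents the statistical procedures `readerstudy` implements,
the generative model behind its synthetic cohorts, the calibration of the
defaults, and the numerical choices that matter at the edges.

## The study design being analyzed

A multi-reader multi-case (MRMC) crossover study: R readers each label the
same N cases in two sessions — reading plain CTA examinations, and reading
them with an AI segmentation model's regions of interest overlaid — with a
washout period between arms to limit recall. Readers split into two groups
that take the arms in opposite order; within a group, half read the cases in
a fixed random order and half in its exact reversal. Each read produces a
binary call ("at least one clinically significant aneurysm", defined as
diameter > 3 mm) and a logged entry time. The default design is R = 8
(6 board-certified radiologists, 1 neurosurgeon, 1 resident), N = 115 at
50% prevalence, and a 14-day washout.

Because every reader reads every case under both conditions, the reader is
the unit of paired inference, and the case set is identical across arms, so
agreement comparisons are exchangeable at the case level under the null.

## Accuracy metrics

Per reader-session, confusion counts give sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy (TP+TN)/N. Metrics with zero denominators
raise an error rather than returning NaN — a NaN here would silently
propagate into the t tests.

The **microaverage** sums counts across readers first: with 8 readers × 115
cases the pooled denominators are 464 (58 positives × 8), 456 and 920. The
pooled metric equals Σ numerators / Σ denominators, which the test suite
asserts as an identity.

**Wilson score intervals** (95% default) quantify uncertainty on every
proportion. The implementation delegates to statsmodels'
`proportion_confint(method="wilson")`; the closed form is

    center = (p̂ + z²/2n) / (1 + z²/n),
    half-width = z·sqrt(p̂(1−p̂)/n + z²/4n²) / (1 + z²/n),

with z the exact normal quantile (1.959964…, not 1.96) — both choices
reproduce 3-decimal printed intervals, but the exact quantile is the
defined estimator. Bounds are clipped to [0,1] and snapped to bracket the
point estimate, absorbing ~1e−16 rounding at p̂ ∈ {0, 1}. Rounding is for
display only; all computation keeps full precision.

**Segmentation binarisation.** A voxel-probability volume becomes a case
call of 1 iff any voxel strictly exceeds the threshold (default 0.5). The
strict ">" is deliberate and documented because a "≥" dialect changes the
boundary case; the rule is monotone in the threshold, which a property test
asserts.

## Paired inference

One-tailed paired t tests on per-reader differences (augmented −
unaugmented), df = R − 1 on the exact Student t distribution — never a
normal approximation at n = 8. Improvement means an increase for
sensitivity/specificity/accuracy/κ and a decrease for reading time; the
direction is encoded per hypothesis, not globally. Two-sided 95% t
intervals for the mean difference are reported alongside the one-tailed p,
matching the conventional presentation. Constant differences raise a
degenerate-variance error.

The **radiologist sensitivity analysis** reruns the same machinery on the
board-certified-radiologist subset (df = 5 by default), checking that
results are not driven by the resident or the neurosurgeon.

## Interrater agreement

"Exact Fleiss κ" is implemented as **Conger's multi-rater statistic**:

    P_o = (1 / (N·R·(R−1))) Σ_cases Σ_categories n_cj (n_cj − 1)
    P_e = (2 / (R(R−1))) Σ_{r<r'} Σ_categories p_rj · p_r'j

with p_rj the rater-specific marginal rate. P_o is the average pairwise
percent agreement; P_e averages pairwise chance agreement over rater pairs,
so for R = 2 the statistic reduces exactly to Cohen's κ (asserted against
an independent implementation). "Exact Fleiss κ" is the name agreement
software commonly uses for Conger's variant; because the classic Fleiss
statistic (pooled marginals, P_e = Σ p̄_j²) is a plausible alternative
reading, it is provided behind `variant="fleiss"` and cross-checked against
statsmodels. When every rater puts every case in one category, P_e = 1 and
κ is undefined; this raises a degeneracy error with an explanatory message.

**Permutation test for the κ difference.** Under the null that augmentation
leaves agreement unchanged, each case's pair of label rows (all readers) is
exchangeable between sessions. Each of B = 10 000 permutations therefore
swaps whole case rows between the two matrices independently with
probability ½, recomputes both κ values, and the p-value is the proportion
of null differences *strictly greater* than the observed difference.
Choices worth recording:

* **Swap unit.** Case-level row swaps preserve within-case inter-rater
  correlation, which is the correlation structure the statistic measures;
  the alternative — swapping individual reader-case cells — is a stricter
  null that destroys it. Cell-level swapping is exposed as
  `unit="cell"` for comparison; case-level is the default and the
  documented interpretation.
* **Strict inequality.** With identical inputs the observed difference and
  every permuted difference are 0, so the strict rule yields p = 0; the
  package emits a degeneracy warning in that case, and a smoothed
  (count+1)/(B+1) estimator is available for users who need a
  guaranteed-positive p.
* The permutation stream is vectorised (the per-case agreement
  contributions and row sums are precomputed, so each permutation costs a
  few matrix products) and seeded independently of the simulator's stream.

## Reading time

Durations are consecutive differences of entry times within a
reader-session, restored to reading order by sorting on entry time — N
cases yield N−1 durations. The alternative reading of "difference between
the mean entry times of consecutive diagnoses" (difference of session
means) was rejected because the 5-longest/5-shortest exclusion operates on
per-case times, which only exist under the consecutive-difference reading.
Trimming removes the k = 5 largest and smallest values per reader-session
*before* any pooling (stable order on ties, length shrinks by exactly 2k,
error if ≤ 2k values); the microaveraged mean time pools the trimmed
durations across readers. Means carry two-sided 95% Student-t intervals.

## Multiplicity

Benjamini–Hochberg step-up adjustment (via statsmodels `fdr_bh`):
p_adj(i) = min_{j≥i} (m·p_(j)/j) capped at 1, original order restored. The
registered family of a full run has m = 8 members — sensitivity,
specificity, accuracy × {all clinicians, radiologists}, reading time, and
the κ difference — and is explicit in the configuration, never implicit.
BH controls the false discovery rate; the package reports both unadjusted
and adjusted p-values. Display follows journal style (two decimals, three
below .01, "<.001" floor) while machine-readable files keep full precision.

## Synthetic cohort: generative model and calibration

The generator exists so every pipeline stage is testable without imaging
data. It is a **probit latent-threshold model**:

* Truth: the positive count is deterministic, round-half-up(N·prevalence) —
  mirroring stratified 50/50 test-set construction, and giving 58/57 at
  N = 115 (these are the counts whose pooled Wilson intervals match the
  published ones). Positive cases draw a diameter from size strata
  3–7 / 7–12 / 12–24 / 24–40 mm with weights 148:108:61:11 and carry a
  second lesion with probability 20/328.
* Labels: for a positive case with shared difficulty d ~ N(0,1), reader r
  in session s is positive with probability
  Φ(a_r + δ_sens·[s=aug] − τ·d); for a negative case with latent e ~ N(0,1),
  Φ(b_r + δ_spec·[s=aug] + τ·e), δ_spec ≤ 0. Latents are drawn once per
  case and shared across readers *and* sessions, so the same hard cases are
  missed in both arms — the right structure for a crossover on identical
  cases. Given the latents, reader draws are independent.
* Calibration: integrating the latent out gives marginal
  Φ(a/√(1+τ²)), so propensities are set from session-marginal targets:
  a = Φ⁻¹(sens_target)·√(1+τ²), etc. Defaults target 0.831 → 0.890
  sensitivity and 0.960 → 0.975 specificity. Reader heterogeneity is a
  symmetric mean-zero grid of offsets (half-range 0.25 on the probit
  scale) applied to *both* a_r and b_r — a single operating-point shift, so
  liberal readers gain sensitivity and lose specificity together. Symmetric
  mean-zero offsets keep the roster-average marginals at the targets to
  second order (residual bias < 0.003).
* The coupling τ has no published counterpart and sets the agreement
  level: τ = 1.75 puts the exact κ at ≈ 0.80 unaugmented → 0.86 augmented,
  the level reported for this kind of reader population, while leaving the
  marginal calibration untouched (κ is monotone in τ, which a test asserts
  on a grid). Replicate studies at the defaults give a mean κ difference of
  ≈ +0.055 with a single-study Monte-Carlo SD of ≈ 0.03 — one simulated
  study can easily show a negative κ difference, which is worth remembering
  when reading any single run.
* Times: lognormal durations with median 50 s and mean 57 s
  (σ_log = √(2·ln(57/50)) ≈ 0.51), plus a Uniform(300, 1200) s
  "interruption" added with probability 0.02 — a two-component mixture that
  gives the 5/5 trimming rule something to remove. The expected trimmed
  mean is ≈ 56.3 s: trimming a right-skewed distribution pulls the mean
  down slightly more than the rare interruptions push it up. Entry times
  are cumulative sums along each reader's assigned case order.
* Segmentation toys: negatives are sub-threshold noise; positives add one
  contiguous Gaussian blob with peak in (0.7, 0.95) and width scaled to the
  lesion diameter, so binarisation recovers the truth by construction.
  These are geometric stand-ins, not emulations of scanner physics or CNN
  behavior.

All randomness flows from a single seed; each stage (truth, crossover,
labels, times, segmentation, permutation) uses a substream derived by a
fixed offset, so any stage reproduces independently.

### What the generator does not emulate

Reader learning or fatigue across the reading list, order or carryover
effects surviving the washout, case-specific difficulty that differs
between sessions, non-stationary reading speed, and any dependence of
label quality on reading time. Passing tests therefore validate the
*analysis machinery* and its operating characteristics under a plausible
correlation structure — not the behavior of real readers.

## Problem sizes used in the test suite

Statistical validation runs at sizes chosen to make Monte-Carlo error small
relative to the tolerances asserted: 1000 random matrices for the κ oracle
equivalence (tolerance 1e−12), 200 replicate null datasets × 400
permutations for p-value uniformity (KS at α = 0.01), 500 replicate
studies for effect-recovery bias (tolerance ±0.01 around the configured
+0.059) and 1000 for type-I error (bound α + 3·MC-SE), and 2000 direct
draws for the trimmed-mean oracle. Unit and property tests use small
fixtures throughout; the whole suite runs in well under a minute.

## Known limitations

* The analysis treats readers as fixed and cases as the only sampling unit
  in the Wilson intervals; pooled intervals ignore between-reader
  correlation (as microaveraged presentations conventionally do). The
  paired t tests, by contrast, are exactly calibrated for reader-level
  inference, which is why both are reported.
* No ROC/AUC MRMC machinery (Obuchowski–Rockette, DBM): the task analyzed
  is single-threshold binary labeling.
* No per-lesion (FROC) scoring; a case is the unit of truth.
* The permutation test's case-level swap is one defensible reading of
  "relabelling a random subset of the test set"; the cell-level variant is
  provided but not the default.
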