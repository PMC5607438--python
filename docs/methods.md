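# Methods

## Measurement model

Items follow Samejima's graded response model in the slope–threshold
logistic metric: for item *i* with discrimination `a_i > 0` and strictly
increasing thresholds `b_i1 < b_i2 < b_i3 < b_i4`, the probability of
responding in category `k` or above is
`P*_ik(θ) = logistic(a_i (θ − b_ik))`, with `P*_i0 ≡ 1` and `P*_i5 ≡ 0`;
category probabilities are adjacent differences. No `D = 1.7` scaling
constant is applied — published PROMIS-style parameters are reported in
the logistic metric, and files calibrated with the normal-ogive scaling
must be converted by the user before loading.

Scoring is maximum likelihood restricted to the reporting scale
`θ ∈ [−4, 4]` (community-normed, 0 = population mean, positive = more
severe). The log-likelihood of a fixed response pattern is unimodal in
θ; the maximiser is located by a coarse scan (0.1 steps) whose best
point brackets a bounded Brent refinement with tolerance 1e−6 — the scan
costs little and removes any dependence on a starting value. The
standard error is `1/√I(θ̂)` using the *expected* (Fisher) test
information, the standard quantity behind test information curves;
observed information would differ only for non-ML scoring or
non-canonical models.

Degenerate inputs: all-minimum and all-maximum patterns have monotone
likelihoods, so θ̂ is clamped to −4 or +4, flagged `boundary=True`, and
the SE is reported as undefined (NaN) — the information-based SE has no
meaning at a constrained optimum. This clamping rule is this package's
choice: reporting scales bounded at ±4 are common, but there is no
universal convention for extreme patterns. Missing responses are simply
dropped from the likelihood (`n_items_used` records the count); scoring
an all-missing pattern is an error.

## Half-form construction

Input: a bank whose items carry a *content pairing* — a perfect matching
of clinically similar items (e.g. "sad" with "depressed"). The pairing
is supplied, never computed: it encodes clinician judgement about
symptom constellations and has no faithful algorithmic substitute.

`initial_split` sends one member of each pair to each form (a supplied
assignment, otherwise a seeded coin flip per pair), which guarantees the
two forms cover the same clinical content. Residual psychometric
imbalance is the mean absolute difference of the two forms' test
information curves on 81 uniform grid points over `[−4, 4]` (an L1
average: robust, in information units, and zero exactly when the curves
coincide on the grid). `balance_by_swaps` then repeatedly applies the
single whole-pair swap that most reduces this gap, stopping when no swap
improves it (or after `max_swaps`, default one per pair). Greedy descent
formalises the manual "switch one pair to the other form" adjustment
used in practice; it never increases the gap, and on small banks
(≤ 10 pairs, verified by exhaustive enumeration in the tests) it lands
within 10% of the optimal assignment in the large majority of random
banks. It is a heuristic — a pathological bank can trap it in a local
minimum, which is acceptable given the construction it models was itself
a manual single swap. Information is model-implied (computed from the
item parameters), not resampled from calibration data.

## Synthetic data generator

The generator emulates a two-visit crossed design at a community
mental-health clinic:

* **Cohort**: `n_participants = 129`; latent severity
  `θ ~ N(0.91, 0.98²)` truncated to `[−4, 4]` (truncation rejects a
  negligible ~0.1% of draws). These defaults are the study conditions
  the package is calibrated against; both are configurable.
* **Bank**: 28 items in 14 pairs. Discriminations uniform on
  `[1.5, 4.0]` and thresholds ordered within `[−1.5, 3.5]` — the ranges
  typical of strongly discriminating clinical depression banks, whose
  categories mostly separate above the community mean. Pair members are
  jittered copies of a shared prototype (≈5% log-normal jitter on `a`,
  ±0.08 on thresholds), so pairing is psychometrically meaningful.
* **Design**: an 8-cell randomisation — independent fair coin flips for
  electronic device (mobile phone vs tablet), modality order (paper
  first vs electronic first) and form order (A first vs B first). Each
  participant contributes exactly two administrations: one paper, one
  electronic (on their assigned device), one Form A, one Form B.
* **Responses**: drawn from the GRM at an *effective* theta — the
  participant's θ plus additive shifts for modality, form and
  modality-by-form cell (all zero by default, the equivalence null).
  Additive location shifts are the simplest alternative hypothesis
  consistent with equivalence testing; per-item differential functioning
  is out of scope. Sampling uses one uniform draw per item:
  `X = #{k : u < P*_k(θ)}`, which has exactly the GRM distribution.

What passing tests on these data do *not* show about real data: the
generator produces locally independent, model-faithful responses from a
stationary trait. Real administrations include careless responding,
order/fatigue effects, local dependence among similar items, and
device-specific presentation differences beyond a location shift — none
of which are modelled. Calibration results (type-I error, power) are
therefore statements about the analysis pipeline under the model, not
about robustness to model violation.

## Analysis

The outcome table has two theta rows per participant. Two linear mixed
models with a participant random intercept are always fitted by REML
(statsmodels `MixedLM`): modality + form + modality:form, then
modality + form. Fitting both unconditionally mirrors the conventional
report-then-reduce sequence without making the second fit conditional on
the first's p-value.

Per-term Wald F statistics use the fixed-effect covariance from the REML
fit. Denominator degrees of freedom follow a containment-style rule,
`N_subjects − (number of fixed-effect terms + 1)`: with two observations
per subject and within-subject factors, the relevant error stratum has
`N − 4` df under the interaction model and `N − 3` without it (125/126
at N = 129; 113/114 at N = 117). Exact small-sample df for mixed models
are software conventions; the containment rule is transparent,
deterministic, and matches the two-per-subject design. A
`df_method="residual"` option (`N_obs − rank`) is provided for
comparison; Satterthwaite approximation is not implemented — for this
balanced two-row design it would differ negligibly while adding a
numerically delicate derivative computation.

t tests: repeated-measures comparisons (Form A vs B; paper vs phone and
paper vs tablet within device subgroups) use the paired t on
within-participant differences, `df = n − 1`. The phone-vs-tablet
comparison is an independent-groups pooled-variance Student t, available
both from raw score vectors and from published group summary statistics
(mean, SD, N) — the two routes agree to machine precision. **Cohen's d
always uses the pooled SD of the two original groups**, not the SD of
paired differences; the paired-difference convention would roughly
double d whenever the two measurements correlate strongly, and the
original-group convention keeps paired and independent effect sizes
comparable. All p-values are two-sided. No multiple-testing correction
is applied (the analyses are planned comparisons in an equivalence
framing, where uncorrected tests are conservative against falsely
declaring equivalence).

Sensitivity analysis: participants can be *flagged* and excluded
entirely (both rows). The built-in rule flags any participant with a
boundary theta estimate — a deliberate stand-in, since flagging criteria
(rushed completions, inconsistent responding, staff notes) are
study-specific; the rule is a pluggable predicate.

## Numerical choices

* Scoring tolerance 1e−6 on θ; dense-grid oracles in the tests use
  1e−3 steps and require agreement within 1e−3.
* Probability sums are exact to 1e−12; information additivity likewise.
* Ties in greedy balancing (two swaps reducing the gap equally) resolve
  to the first pair in bank order; an improvement must exceed 1e−15 to
  count, so the procedure terminates.
* Mixed-model fits with collapsed variance components (e.g. zero
  residual variance when the two rows of every participant are
  identical) return F = 0 for terms whose contrast estimate is zero
  rather than propagating a 0/0.
* Artifact files carry 6 significant digits; computation is double
  precision throughout.
* Every pipeline stage draws its seed as a hash of the master seed and a
  stage tag, so stages are independently reproducible and adding a stage
  never perturbs another stage's stream.

## Problem sizes

The test suite's Monte-Carlo batteries use 500 replicate cohorts
(N = 129) for type-I-error calibration of the five tests at α = .05,
200 replicates for power against a 0.5-SD electronic-modality shift, 200
replicates for the null Form A − B difference, 1,000 simulees for
recovery bias/RMSE, and 200 random patterns for the scoring-oracle
comparison — sizes at which the binomial error of an estimated 5%
rejection rate is about ±1% (1 SE) and the calibration bands are
informative.

## Known limitations

* The information-gap optimum is certified only for small banks (where
  enumeration is feasible); for 14 pairs the greedy result is a
  well-behaved heuristic, not a proven optimum.
* SEs come from expected information at θ̂ and ignore the truncation at
  ±4; near the bounds they are optimistic.
* The mixed model assumes homoscedastic residuals across modalities and
  forms; the equivalence question could also be posed as formal TOST
  bounds, which are not the headline analysis here.
* Scored thetas enter the mixed model as known quantities; their
  measurement error (≈ 0.25–0.35 SE per administration for a 14-item
  form at moderate severity) is absorbed into the residual variance
  rather than modelled.
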