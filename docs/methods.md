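# Methods

## The model

The package implements the *linear z-score* variant of subtype-and-stage
inference (SuStaIn) for regional biomarker data, as used for tau-PET
subtyping in early-onset Alzheimer's disease. The data are per-scan vectors
of regional values (the reference application: mean [18F]Flortaucipir SUVR
in 10 unilateral lobar composites — left/right frontal, parietal, lateral
temporal, occipital, medial temporal), standardized per region against
the control group's baseline mean and SD (n−1 denominator).

Progression is discretized into **events**: region *i* crossing severity
threshold *z\_ir* (R thresholds per region; B regions; N = Σ R\_i events —
20 in the reference configuration). A **subtype** c is an ordering
S\_c of all N events; a subject at **stage** k has completed the first k
events of its subtype's sequence. The expected z-score of region *i* at
stage k, g\_i(k), is the piecewise-linear interpolant through

    (0, 0), (p(i,1), z_i1), …, (p(i,R), z_iR), (N, z_max_i)

where p(i,r) is the 1-based position of event (i, r) in S_c and z\_max\_i a
per-region ceiling; the last knot is dropped when p(i,R) = N. Sequences are
constrained so lower thresholds precede higher ones within a region, which
makes every g\_i non-decreasing in stage. Observations are modelled as
x\_i = g\_i(k) + ε\_i with ε\_i ~ N(0, σ\_i²); σ\_i defaults to 1 because the
inputs are control-referenced z-scores (configurable per region).

With a uniform stage prior over 0..N and mixing fractions f_c,

    P(x) = Σ_c f_c · (1/(N+1)) Σ_k Π_i N(x_i; g_i(k), σ_i),

computed throughout in log space with log-sum-exp.

## Fitting

* **Sequence optimization** is greedy coordinate ascent: events are swept in
  a seeded-random order; each is removed and re-inserted at the valid
  position that maximizes the responsibility-weighted data log-likelihood.
  Moves require strict improvement, ties resolve to the earliest position in
  enumeration order, and sweeps repeat to a fixed point, so the objective
  never decreases and the procedure terminates. At N ≤ 6 the optimizer was
  checked against exhaustive enumeration of all valid permutations
  (`tausustain.oracle_agreement`).
* **EM**: E-step responsibilities from current fractions and per-subtype
  marginals; M-step re-optimizes each sequence against its responsibilities
  and sets fractions to mean responsibility. Stops at relative
  log-likelihood change < 1e-6 or 100 iterations; best of 10 seeded random
  starts (both configurable). Starts that collapse a subtype below weight
  1/(10n) are discarded; the monotone-likelihood property is asserted at
  every iteration.
* **Divisive hierarchy**: the (C+1)-subtype model is grown from the
  C-subtype one by hard-assigning subjects to their maximum-likelihood
  subtype, splitting each sufficiently large subtype (≥ 2(C+1) members)
  with a 2-subtype EM fit on its members, refining every candidate by EM on
  the full data, and keeping the best. A duplicate-largest-subtype fallback
  candidate reproduces the C-subtype mixture exactly, guaranteeing the
  training likelihood is non-decreasing in C.
* **MCMC**: Metropolis over sequences (uniform subtype/event/valid-position
  proposal, acceptance min(1, L_new/L_old) on the total data likelihood)
  with fractions frozen at their EM estimates — a deliberate simplification
  relative to samplers that also perturb fractions, chosen for a clean,
  deterministic acceptance rule. Default 5000 iterations, 10% burn-in;
  positional-variance matrices are tallied from retained samples.
* **Model selection**: k-fold cross-validation (default 5) over subjects;
  held-out log-likelihood uses the training fold's EM point estimate
  (fractions included), not an MCMC average — recorded as a simplification
  of the information-criterion variants in the reference ecosystem.
  CVIC(C) = −2 Σ_folds log P(test | trained C-model). The curve is reported
  rather than auto-selected; where a scalar "elbow" is needed
  (`cvic_elbow`), it is the smallest C within 5% of the curve's minimum,
  measured against the drop from C = 1.

## Thresholds

Event thresholds come from a 2-component univariate Gaussian mixture fitted
per region on pooled control + patient baseline z-scores (EM, deterministic
median-split initialization, components relabelled m1 < m2). The default
mapping to thresholds is: z1 = the equal-posterior boundary between the
components, floored at 1.0; z2 = m2 (the abnormal component's mean);
z\_max = m2 + 2·sd2; the triple is repaired to strict ascent if pieces
collide, and non-bracketed boundaries fall back to the component midpoint
with a warning. A fixed policy (z ∈ {2, 5}, z\_max = 10) ships as a preset.
These mappings are documented package choices, not claims about any
specific study's unpublished rule.

## Assignment, deviation, and longitudinal stability

Each scan independently gets the subtype with the highest posterior
(f\_c-weighted marginal), then the highest-probability stage within it; ties
go to the lowest index/stage. Scans whose maximum subtype posterior is
below a threshold (default 50%; 0%/80% for sensitivity) are flagged
poorly-fitted but keep their assignment. Stage-0 scans are additionally
flagged `stage_zero` (their subtype posterior reduces to the fractions
prior). The **deviation** statistic binarizes each event as achieved iff
x\_i ≥ z\_ir (closed threshold, configurable in principle via the event
definition) and counts the Hamming distance to the prefix implied by the
assigned stage; this reconstruction of the "event imperfection" count is a
stated, testable definition.

Follow-up scans are restaged by the frozen baseline-trained model, each scan
independently (stateless in subject identity and visit order). Stability
pairs each subject's baseline with the last non-excluded follow-up; subjects
whose baseline is excluded are dropped (counted and warned). Agreement is
summarized by the confusion matrix, unweighted Cohen's κ with its asymptotic
95% CI (statsmodels), and the retention proportion with a Wald 95% CI.
Annualized stage change (k̂\_last − k̂\_first)/Δt is computed only for
subtype-stable subjects, with per-subtype one-sample t-tests (one-sided,
increase), a one-way ANOVA across subtypes, and regressed/stable/progressed
counts. Wald intervals (p̂ ± 1.96·√(p̂(1−p̂)/n), clamped, integer-rounded
percent) are the reporting default because they reproduce the printed
intervals of the reference results from their counts; Wilson can be
substituted by calling statsmodels directly.

## The synthetic cohort generator

`tausustain.simulate` provides the ground-truth cohorts all testing runs on:

* **Truth**: B regions × R thresholds (defaults 10 × 2, thresholds (2, 5),
  ceiling 10 — the 20-event reference configuration), C subtype sequences
  drawn uniformly from the valid permutations (or supplied), fractions
  uniform by default.
* **Baseline**: controls z ~ N(0, 1) per region (default n = 85); patients
  (default n = 365) draw a subtype from the fractions and a stage uniform on
  0..N, then z = g\_c(k) + N(0, σ²) with σ = 1. A small `mixed_frac` of
  patients can be generated from the average of two subtypes' trajectories
  to exercise the poor-fit exclusion. Raw-value mode maps z back through
  per-region control (mean, SD) so z-scoring itself is testable end-to-end.
* **Follow-ups**: each patient gets a latent rate ~ N(0.56, 0.70)
  stages/year (the observed progression rate) and by default one follow-up
  PET on the study's annual visit schedule — Δt ∈ {1, 2, 3} years with
  probabilities (0.45, 0.20, 0.35) plus N(0, 0.1) timing jitter, giving a
  follow-up duration of 1.90 ± 0.89 years against the observed 1.90 ± 0.94.
  The true stage advances by round(rate·Δt), clamped to [0, N] (the stage
  space is discrete; the continuous rate is kept in the truth record). A
  `switch_prob` option flips the generating subtype to exercise the
  stability metrics (default 0).

What the generator does **not** emulate: covariate structure (age, sex,
amyloid), spatial correlation between regions beyond the shared stage,
measurement drift between visits, attrition correlated with severity, and
any off-model heterogeneity beyond the two-subtype mixing option. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to the ways
real tau-PET data violate them.

## Reference experiment scales and their quirks

The packaged experiments (`tausustain.experiments`) run at: recovery —
B = 10, R = 2, C = 3, n = 300 patients, σ = 1, uniform stages, 5-fold CV
over C = 1..4; longitudinal — n = 200 patients with one scheduled follow-up
each; oracle comparison — 100 datasets at N = 6 (90 valid orderings);
EM diagnostics — 50 unstructured-noise datasets. Recovery and longitudinal
metrics are reported as means over 3 independent replicates (fresh truth,
cohort and fit per replicate), because single-replicate estimates carry
Monte-Carlo error of the same order as their recovery tolerances.
Recovery metrics are computed over the analysis population after the 50%
poor-fit exclusion, mirroring how poorly fitted scans are excluded from
post-clustering analyses; under uniform stages the excluded scans are
mostly genuine low-stage scans whose subtype is unidentifiable in
principle. Fraction error is scored against the cohort's *realized* subtype
composition rather than the nominal generating fractions — a mixture fitted
to a finite sample estimates the sample's composition, and at n = 300 the
realized composition itself strays from nominal by more than the scoring
tolerance. Two known biases of the longitudinal estimand are documented
rather than corrected: stage clamping at 0 and N shrinks the observable
mean rate below the latent 0.56, and hard MAP staging adds boundary
shrinkage; together they put the recovered mean near 0.48–0.50.

## Numerical choices

* All likelihoods in log space; stage-likelihood matrices via a single
  (n × B)(B × (N+1)) product on σ-scaled values.
* EM tolerance 1e-6 (relative), max 100 iterations; GMM tolerance 1e-10,
  max 500 iterations, variance floor 1e-6 × data variance.
* Tie-breaking everywhere: first-encountered maximum in canonical
  enumeration order (regions in table order, thresholds ascending, stages
  ascending, subtypes by index).
* One seed (`RunConfig.seed`) drives every stochastic step; derived child
  seeds come from `numpy` SeedSequence and stay below 2^31.
* Model bundles serialize to a single JSON document; floats survive the
  round trip bit-exactly (shortest-repr printing).

## Known limitations

* σ is fixed, not estimated; subjects with atypical noise levels are
  absorbed into stage/subtype uncertainty.
* The MCMC samples orderings only; positional-variance matrices understate
  total uncertainty by conditioning on the EM fractions.
* Held-out likelihood from point estimates makes CVIC slightly optimistic
  for larger C; the elbow heuristic compensates in practice but the curve
  should be inspected.
* Exhaustive subtype matching in evaluation is limited to C ≤ 8.
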