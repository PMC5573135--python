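# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `catrep` pipeline. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Category structures and stimulus sets

Two canonical four-category structures live on an abstract 2-D stimulus
space (dim1 = bar width, dim2 = orientation). The rule-based (RB) structure
has means (1.9, 0.30), (1.9, 0.67), (1.9, 1.03), (1.9, 1.40) with shared
covariance diag(0.44, 0.01): categories differ only on dim2, so a
one-dimensional criterion rule is optimal. The information-integration (II)
structure has means (0.92, 2.49), (1.50, 1.93), (2.02, 1.41), (2.59, 0.82)
with shared covariance [[0.06, 0.04], [0.04, 0.06]]: the mean axis is
diagonal and the covariance correlated, so no single-dimension rule works.
Coordinates are kept abstract: the II means are not consistent with any
fixed physical orientation range, so no unit conversion to cpd/radians is
attempted and none is needed by the analyses.

Stimulus sets are drawn per category and then **moment matched**: points are
linearly transformed (`y = m + L_t L_s^{-1} (x - x̄)`, lower-triangular
Cholesky factors of the target and ddof=1 sample covariance) so the sample
mean and covariance equal the generative parameters exactly. Any
factorization achieving exact moment equality would do; the invariant, not
the factor, is the contract. The map is idempotent and label-preserving,
and fails loudly (`DegenerateSampleError`) on singular samples.

The canonical 600-stimulus set uses per-category counts (125, 175, 175,
125). The schedule consumes 125 of each category across the five training
blocks (25 per block, so A/B and C/D questions are equally likely) and 50 B
+ 50 C in the test block; with these counts every stimulus is shown exactly
once and the training and test sets are disjoint. The counts are a design
inference from the schedule's requirements, not an external given, and are
configurable.

## Schedules and sessions

A session is 600 trials: blocks 1–5 train A-vs-B and C-vs-D with feedback,
block 6 tests B-vs-C without feedback. In the A/B (classification)
condition questions are ordered pairs and responses are category buttons;
in the Yes/No (concept) condition each trial names a single target and a
"no" implies the target's contrast partner (A↔B, C↔D in training, B↔C at
test). Yes/No target labels are crossed with the ground truth 50/50 within
each (block, category) cell, with the odd trial assigned at random — exact
rather than stochastic balance, a deliberate choice where either reading of
"equally likely" is defensible.

Timeout / wrong-key responses are representable in the log format but carry
no implied category; they are excluded from all fitting and accuracy
computations, and the simulator never emits them. Session CSVs are written
with full-precision float reprs and re-parsed with exact round-trip
semantics; reading validates every schedule invariant and reports the first
violation.

## Observer models

**Density model (within-category).** One Gaussian per response category,
estimated from the trials that reveal the participant's own labeling: in
Yes/No, the trials where the category was the named target and the answer
was "yes" (a "no" does not reveal the intended category); in A/B, the
trials where that category's button was pressed. Estimators are the sample
mean and (co)variance (maximum likelihood, ddof=0). RB fits use dim2 only —
four means and four variances, eight representational parameters; II fits
are bivariate with a full covariance per category, chosen because the
generative covariance is correlated (the II parameter count has no
canonical reference value; this is a documented package choice). Region
probability is the two-density ratio, applied identically in training and
at test.

**Boundary model (between-category).** One bound per trained pair, each a
cumulative Gaussian on a fixed unit projection axis: dim2 (0, 1) for RB,
(1, −1)/√2 for II (the normal of the linear optimal bounds; projected
category means are strictly ordered A < B < C < D on it). Keeping the axis
fixed preserves the four-parameter count (two locations, two noise SDs); a
free-slope variant is out of scope. Bound parameters are probit MLEs of the
"upper label implied" indicators, with deterministic initialization
(location at the midpoint of the per-response projected means, SD at the
pooled projected SD), L-BFGS-B within generous bounds, tolerance 1e-8. In
training `p(C_A|d) = 1 − F_AB(d)` (and the C/D analogue); at test, where no
B/C bound exists, both trained bounds are consulted:
`p(C_B|d) = F_AB(d) / (F_AB(d) + (1 − F_CD(d)))`. The test equation's
typeset source is ambiguous; the implemented grouping follows its prose
reading (numerator = B per the AB bound; denominator adds C per the CD
bound). A side effect worth knowing: inside the B/C band the expression is
flat near 0.5 and weakly *anti*-predictive near the trained bounds, which
is precisely why a pure-boundary observer cannot exceed chance at test.

**Decision rule.** Both models share the softmax
`p(R_X|d) = exp(α p_CX) / (exp(α p_CX) + exp(α p_CY))`. α is fitted after,
and conditional on, the representational parameters, by minimizing
`SSE(α) = Σ (y_i − p(R_X|d_i; α))²` over one 0/1 indicator per trial (the
two alternatives are complementary, so using both would only scale the SSE
by 2 without moving the minimum). The search is bounded scalar minimization
on [0, 50] with tolerance 1e-6; both interval endpoints are also evaluated,
so a monotone SSE returns the bound, and exact ties on saturated plateaus
(where the SSE underflows to 0) resolve to the larger α.

**Numerical conventions.** Fitted variances are floored at 1e-4 squared
units and bound SDs at 1e-3 units, preventing degenerate likelihoods on
small "yes" subsets; floors are flagged on the fitted parameters. Region
probabilities are computed in log space; the 0/0 cases (both densities
vanished, or both test-equation terms vanished) return 0.5, maximum
ignorance. Probit likelihoods clip probabilities at 1e-12.

## Cross-validated classification

Both models are fit to trials 301–500 (blocks 4–5, the last 200 training
trials, where performance is stable) and evaluated on block 6 with every
parameter frozen — test prediction is a pure function of the fitted
parameters. The verdict is *within* iff the density model's test RMSD is
strictly smaller; ties go to *between* because the boundary model is nested
with fewer parameters (parsimony). The window is positional: excluded
trials reduce the usable count rather than shifting the window.

Participants whose density model lacks three usable trials for a
test-relevant category (B or C), or with a non-identifiable bound (all
responses on one side), are excluded with the reason flagged — never
silently defaulted. Other underdetermined categories only remove the
affected trials from the α fit.

## Synthetic observers

The generator produces behavioral data with the representational structure
the analysis assumes, so every downstream stage is testable without human
data. It emulates the study conditions — the schedule above, four-category
moment-matched stimulus sets, both questioning conditions — not human
learning dynamics; no claim about learning theory is embedded.

*Within agents* keep running per-category mean/covariance estimates
(Welford updates) and respond from the density ratio (univariate on dim2
for RB, bivariate for II) through the softmax with their own noise
`alpha_agent`. *Between agents* keep one criterion per trained pair — the
midpoint of the running per-side projected means, bookkeeping only — and
respond from cumulative-Gaussian bound probabilities with a perceptual
noise SD; at test they use the two-bound test equation, which pins them
near chance. Both agents guess uniformly for the first `learn_burnin`
trials while still accumulating feedback, and both decode the true category
of every training stimulus from question + feedback (always possible in
this task).

Defaults, chosen once on a-priori grounds: `alpha_agent = 20` (responses
essentially deterministic once region probabilities separate by ≳ 0.1, the
regime the human-scale accuracies occupy), `learn_burnin = 50` (produces
early-block learning curves that rise from near chance without asserting
any acquisition model), `noise_sd = 0.03` abstract units (the scale of an
orientation discrimination threshold, roughly 2° in radians — an order of
magnitude below the RB within-category SD of 0.1). What passing recovery
tests show is that *if* a participant responds from one of these two
representations under these noise levels, the pipeline identifies which;
they do not show that humans are this clean, and real data may mix
strategies, drift over blocks, or lapse — none of which the agents emulate.

## Recovery studies and study sizes

`catrep.recovery` runs three checks, each deterministic given one seed:
model recovery over all four structure × condition cells with 30 within +
30 between agents per cell (240 sessions); density-mean recovery over 10
within-agent RB sessions, scoring categories with ≥ 20 usable trials
against the generative means; and the transfer pattern over 20 seeds per
agent type, comparing block-5 and block-6 accuracies (100 trials each).
These sizes give binomial/SEM resolution well inside the thresholds being
checked (e.g. a 90% recovery threshold against an observed rate near 100%)
while keeping the full suite in the tens of seconds on one CPU.

## Known limitations

- The importer for external raw-data archives is not implemented; the
  pipeline ingests its own documented CSV dialect (and anything converted
  to it).
- The boundary model's projection axis is fixed per structure; participants
  using tilted bounds would be approximated, not represented.
- The II density model's covariance structure (full, per category) is a
  package choice; alternatives (shared or diagonal covariance) would change
  its parameter count.
- Exemplar models, free-slope linear classifiers, and perceptual noise on
  the stimulus representation itself are out of scope.
- Standard inferential statistics beyond the pooled two-proportion z test
  (ANOVAs, t tests, corrections) are intentionally left to general-purpose
  statistics packages operating on the pipeline's outputs.
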