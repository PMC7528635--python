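# Methods

This note documents the statistical model behind `cptdetect`, the choices
made where the design was genuinely open, and what the synthetic generators
do and do not emulate.

## Session simulator

One session comprises 8 levels of 53 trials (33 targets, 20 non-targets per
level), each level lasting exactly 114.15 s, for a 15.2-minute test.  Each
stimulus is displayed for 0.5, 1 or 3 s and followed by a void period of the
same duration; a space-bar press during stimulus or void counts as a correct
(respectively timely or merely accurate) response to a target.

The mix of stimulus durations within a level is not uniquely determined by
the level's structure: 53 trials with an equal mix of 0.5/1/3-s stimuli
would occupy an expected 2 × 53 × 1.5 = 159 s of stimulus+void time, which
cannot fit a 114.15-s level while keeping the void equal to the stimulus
duration.  The simulator therefore draws durations from a categorical mix
with default weights (0.7, 0.2, 0.1) over (0.5, 1, 3) s — expected occupancy
90.1 s — rejects the (astronomically rare) draws that overflow the budget,
and distributes the residual level time as random inter-trial gaps so that
every level spans exactly 114.15 s.  Distractor windows exist in the
schedule but have no behavioural effect by default; distraction sensitivity
is not a scored index here.

Responses are governed by four latent traits, all monotone in the indices
they drive: the probability of answering a target, the conditional
probability the answer is timely, the probability of a commission error,
and a Poisson rate of redundant presses.  *Hyperactivity* is operationalized
as the count of redundant motor responses — space-bar presses beyond the
first within a trial plus presses of any other key — consistent with the
task instruction to press the space bar once and only once.  Raw indices
are integer counts; standardization (z-scoring) is offered against either
the whole sample (default) or the control group, since no external norm
tables are assumed.

## Cohort generator

The cohort generator emulates the *statistical* structure of an
observational clinical CPT cohort at its published scale (458 children,
roughly 47% with ADHD): non-uniform factor-level frequencies
(Monday-dominated DoW, morning-dominated ToD), class fractions that vary by
factor group via ordered first-match rules (weekend → controls only,
afternoon/evening → almost only controls, boys at a higher ADHD rate than
girls), standardized diagnosis effects on all four indices (defaults in the
0.5–0.8 SD band, signed so ADHD performs worse), and a negative linear ToD
trend on hyperactivity.

Index z-scores are drawn directly from this Gaussian effect model rather
than routed through the trial-level simulator.  The two generators serve
different contracts: the cohort generator must *converge to its configured
effect sizes* (checked to 3 Monte-Carlo SEs at n = 5000), which a nonlinear
trait → count → z chain cannot guarantee, while the session simulator
provides trial-level ground truth for the aggregation and schedule
arithmetic.  Consequences for interpretation: passing tests show the
pipeline recovers *known, linear-Gaussian* effects under *known* confounding
rules.  Real CPT data have correlated indices, heavier tails, floor/ceiling
effects on counts, and confounding that is not piecewise-constant in the
factors; none of that is claimed.

## Audit

Records are sorted into the cells of the 7 × 2 × 7 × 3 = 294-cell factor
cross-product (groups are the non-empty cells).  The within-group ADHD
effect is the ADHD-minus-control difference of means of a composite
performance score — the unweighted mean of the four z indices, chosen
because no canonical scalar combination is imposed — with a Welch standard
error.  Merging is greedy agglomeration: the pair of estimable groups with
the largest two-sample z-test p-value is merged while that p-value exceeds
alpha (default 0.05), the merged effect is recomputed, and ties are broken
by the lexicographic order of group keys, making the procedure order-stable.
Any two groups may merge; no factor-adjacency constraint is imposed.

Sparse cells frequently contain a single class (or a singleton class), so
their ADHD effect is unconstrained: they are compatible with any effect, and
an equality test can neither support nor reject a merge.  Leaving them
unmerged would send them — and with ~294 cells at n ≈ 458, the majority of
all records — to the degenerate filter, gutting exactly the strata whose
imbalance the method is meant to correct.  Each inestimable group is
therefore absorbed into the estimable group whose class-conditional mean
composite (for the class the sparse group contains) is nearest, in
deterministic key order.  After absorption the degenerate filter removes
any remaining groups with p_i ∈ {0, 1}; their records are excluded
downstream.

The per-factor imbalance statistic is the chi-square test of independence
of the diagnosis × factor-level table, with Yates continuity correction
applied to 2 × 2 tables (the convention matching the published gender
statistic of 10.84).

## Rebalancing

Weights combine the level factor (1 − n_i/N) and the class factor
((1 − p_i) for ADHD, p_i for controls) multiplicatively.  Multiplicative
combination is what yields the exact within-group class-mass identity
n_i p_i (1 − p_i)(1 − n_i/N) on both sides, hence an expected resampled
ADHD fraction of exactly ½ — the stated goal of balancing within and across
levels.  Group statistics (n_i, p_i) are those of the audit on the full
retained cohort, since processing precedes partitioning; weights are then
restricted to the training ids and renormalized.  When a single group spans
all records the level factor is a common zero scale and drops out by
symmetry.  An optional group-equalized normalization (uniform group masses
before class weighting) is provided but off by default: the inverse-
appearance formula alone balances classes within groups, not group masses,
and the stronger normalization is a separate modelling commitment.

Bootstrap repetition is the default oversampling mode (Ñ = 5000 by
default).  The SMOTE-style mode replaces each drawn seed record's four
index values by a convex combination with one of its k = 5 nearest
same-class neighbours *within the same factor group* (factor columns copied
from the seed); a (group, class) stratum with fewer than two members falls
back to repetition.  Undersampling reduces the majority class to the
minority size, exactly 1:1, with no synthesis.  Partitioning is simple
random (not stratified) at a 0.6 training fraction.

## Classifiers

The forest is a bagging loop over scikit-learn CART trees (default 500
trees, √p features per split, unlimited depth) with each tree's bootstrap
and out-of-bag (OOB) index sets recorded explicitly — the OOB permutation
importance needs per-tree OOB samples, which the stock ensemble class does
not expose publicly.  Categorical controls enter the forest as ordinal
integer codes (scikit-learn trees have no native categorical splits; ordinal
coding is the conventional stand-in) and the network as one-hot columns;
importances are re-aggregated per original variable.  The network is one
hidden layer of 8 logistic units trained by L-BFGS with the weight-decay
parameter chosen by k-fold cross-validation (default 100 folds,
configurable; the folds apply to the decay search, the smallest faithful
reading of "cross-validation on 100 folds" given that the CV object of that
phrase is otherwise undefined).

Classification threshold is 0.5 on the predicted probability; an exact tie
is classified as ADHD (the positive class) — fixed and documented so it is
testable.  Importance is the per-tree OOB accuracy minus the OOB accuracy
after shuffling one feature, averaged over trees, reported raw: values are
relative, not absolute.

## Evaluation

R = 100 repetitions; each repetition draws a fresh partition shared by all
arms (paired design, asserted by partition hash), applies each arm's
training manipulation to the training side only, and scores the untouched
holdout.  The benchmark arm trains on unprocessed data with CPT features
only — under uncorrected imbalance the control variables are not reliable
predictors, so giving them to the benchmark would measure the confounding,
not the correction.  Confidence intervals are mean ± 1.96 SD of the
repetition metrics, clipped to [0, 1] — the normal approximation is
consistent with symmetric reporting of wide intervals; a percentile variant
was not adopted because the interval's role here is descriptive spread, not
coverage.  Pairwise paired t-tests are reported unadjusted (an optional
Holm flag exists on the comparison output).  An exact tie across
repetitions is reported as t = 0, p = 1 rather than a division error.

Relative improvement is 100 × (model − benchmark)/benchmark on the
percentage scale, rounded to one decimal.

## Problem sizes and numerical choices

Library defaults are 500 trees and Ñ = 5000.  The repeated-holdout
property checks and the acceptance script run 100 repetitions with 60-tree
forests and Ñ = 2000 on the 458-child confounded cohort — sizes chosen so
the full property suite completes comfortably on one CPU while leaving the
directional conclusions (corrected-with-controls beats benchmark at paired
one-sided p < 0.05; undersampling trails weighted oversampling) stable
across seeds.  The weighted-bootstrap balance check keeps Ñ = 5000, where
the binomial tolerance of ±0.03 on the resampled class fraction is pinned.
Probability vectors are validated to sum to 1 within 1e-12; z-scoring
refuses zero-variance reference columns by name; the degenerate-group
filter, not the merge test, handles one-class groups.

## Known limitations

The generator's confounding rules are piecewise-constant and its effects
homogeneous across groups, so the audit typically collapses to a handful of
merged groups — the merge machinery is exercised at calibration level (rate
≈ 1 − alpha on equal-effect pairs) rather than on a rich heterogeneous
landscape.  The undersampling comparison's direction depends on genuine
global class imbalance; on a near-balanced cohort undersampling loses
little information and can tie the oversampling arm.  No ROC/AUC reporting
is included, and no attempt is made to calibrate the session simulator's
response model to any commercial CPT's norms.
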