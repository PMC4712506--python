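# Methods

## The refinement model

`subtyperefine` treats subtype labelling as a noisy-label problem: the
input labelling (in practice, PAM50 calls) is assumed to be mostly
correct, with a minority of samples mislabelled into the wrong class.
The procedure alternates two estimators that regularize each other:

* **feature re-estimation** — given the current labels, per-class
  signed CM1 signatures are recomputed, so the feature space always
  reflects the current partition;
* **label re-estimation** — given the features, a heterogeneous
  classifier ensemble re-votes every labelled sample; a sample's label
  is only retained or changed when a unique class reaches the consensus
  bar, and samples that split the ensemble are removed from the game
  entirely (marked inconsistent).

The implicit assumptions are that (i) each class is characterized by a
small set of strongly up-/down-regulated probes, (ii) correctly
labelled samples dominate each class, so class statistics computed
under noisy labels still point toward the true signature, and (iii)
disagreement across classifier families is informative — a sample no
family can place consistently is better excluded than forced.
Convergence is not guaranteed in general; in practice the loop
contracts quickly because each iteration strictly shrinks or fixes the
assigned pool, and a safety cap guarantees termination.

## The CM1 score

For probe values x over samples, class mask m:

    CM1(x, m) = (mean(x[m]) − mean(x[¬m])) / (sd(x[m]) + sd(x[¬m]))

with sample standard deviations (ddof = 1). Positive scores mean
up-regulation in the class relative to the pooled rest. The denominator
is pluggable (`sum_sd` default, `pooled_sd`, `range`) because the score
belongs to the signal-to-noise family whose variants differ only in the
spread normalisation; the refinement loop's behaviour is insensitive to
this choice and the default is the most conservative (largest
denominator under class-specific spread).

Numerical conventions: zero-detection is relative to the data scale
(1e-12 · max(1, max|x|)) so that float cancellation on near-constant
probes cannot fabricate a score; a genuinely separated probe with zero
spread gets a sign-capped score (±1e6) so it sorts to the extreme
without producing infinities; ties in the ranking are broken by probe
id for platform-independent determinism. Only strictly positive scores
qualify as "up" and strictly negative as "down", so all-constant probes
can never enter a signature.

## The ensemble

The reference method used 24 Weka classifiers whose identities are not
recoverable; the contribution is consensus over a *diverse* ensemble,
not any particular member. The default roster is therefore 24
scikit-learn estimators spanning six families (decision trees, shallow
rule-like trees/stumps, naive Bayes, linear/discriminant models,
k-nearest-neighbour, bagged/boosted meta-learners), fully declared in
configuration and echoed into every manifest so a run is auditable. An
8-member `fast_roster()` (one or two quick members per family) is
provided for desk-scale experiments and is what the acceptance script
uses.

Votes are collected out-of-fold under stratified k-fold
cross-validation for balanced-subset samples, and from members trained
once on the full subset for the remaining labelled samples — the
procedure describes cross-validation only for the training subset, and
every labelled sample must receive votes for relabelling to be
possible. A member that fails to train (e.g. a discriminant model on a
rank-deficient class) abstains for the affected samples; abstentions
shrink that sample's vote total rather than counting against any class,
because a crashed member expresses no opinion.

Consensus: class c wins iff it is the unique vote maximum and
votes(c) ≥ ceil(threshold · total). The ceiling is computed with a
1e-9 slack so that binary representation of fractions like 2/3 cannot
shift the integer bar (2/3 of 24 is 16, not 17). An exact tie at the
bar fails the uniqueness requirement and the sample becomes
inconsistent — this reconciles the "majority" and "at least 50 %"
readings of the consensus rule.

## The loop and its parameters

| parameter | default | role |
|---|---|---|
| k_up / k_down | 5 / 5 | signed signature size per class |
| folds | 10 | stratified CV folds within a balanced subset |
| runs | 10 | balanced redraws per iteration; votes pooled across runs |
| refine_threshold | 0.5 | consensus bar during refinement |
| traintest_threshold | 2/3 | stricter bar for held-out classification |
| kappa_stop | 0.92 | Fleiss' κ between consecutive labellings that ends the loop |
| max_iterations | 50 | safety cap (reported as a stop reason, not an error) |

Balancing draws the minimum class size from every class (the minimum
class contributes all its samples), because most members otherwise
overfit the majority classes; with the published cohort's class sizes
{728, 600, 234, 233, 58} this yields the 58 × 5 = 290-sample training
sets the method was designed around. The 10 redraws exist because the
subsample is interchangeable; their votes are **pooled** into a single
matrix (240 votes per sample with the default roster) rather than
reduced run-by-run — pooling uses all information and avoids
nested-tie pathologies of a majority-of-majorities.

Stopping combines three criteria, checked in this order: (1) labels
and feature set both unchanged (the stability reading that does not
stop too eagerly), (2) κ between the previous and current labelling at
or above `kappa_stop` (computed as two-rater Fleiss' κ over samples
assigned in both iterations, so the inconsistent state is never treated
as a rated category), (3) the iteration cap. A fixed-point input
reports `labels_and_features_stable` after a single iteration;
`kappa_stop = 0` degenerates to stopping after the first iteration with
`kappa_reached`.

Determinism: a single master seed deterministically derives every
sub-seed (per phase, iteration, run, and classifier) through
`numpy.random.SeedSequence`; two executions with the same inputs and
seed produce identical traces.

## Agreement statistics

Cramér's V, Fleiss' κ and the adjusted Rand index are implemented from
their defining formulas (tests cross-check them against
scipy/statsmodels/scikit-learn to 1e-12 on random instances). Choices
worth recording:

* V drops empty rows/columns before both the χ² statistic and the
  min(r, c) − 1 degrees-of-freedom term, so an unused label (e.g. an
  all-zero inconsistent row) cannot distort the statistic; no
  continuity correction is applied.
* κ returns exactly 1 for unanimous tables, including the degenerate
  single-category case where chance agreement is also 1 (logged).
* ARI's degenerate corner (both partitions trivial) returns 1 for
  identical partitions and 0 otherwise.
* κ interpretation follows the conventional six bands, with values in
  the unprinted gaps (e.g. 0.205) assigned to the lower band's side by
  ≤-comparison and κ ≤ 0 mapped to "poor agreement".

## Survival and markers

The Kaplan–Meier estimator and the K-group log-rank test are
implemented from the product-limit and hypergeometric-moment formulas
(df = K − 1, quadratic form over K − 1 groups, χ² upper tail; the
covariance matrix is solved directly and falls back to a pseudo-inverse
if singular). Censorings tied with events at the same time leave the
risk set after the events are counted (the standard convention). With
no events anywhere the statistic is 0 and p = 1, with a warning.
Proportional-hazards modelling is deliberately out of scope: the
stratification p-value the method reports comes from the log-rank test.

Marker summaries count ER/PR/HER2 +/−/unknown per class (plus the
inconsistent group when present); missing annotation is tracked as
unknown so per-class totals are conserved.

## The synthetic generator

`GeneratorSpec` defaults describe the study conditions the pipeline is
validated under: 1000 probes; five classes of sizes
{250, 200, 90, 90, 58} (imbalanced, with a small minimum class echoing
the normal-like group); 5 planted up- and 5 down-regulated probes per
class, disjoint across classes, shifted by ±2σ on a Normal(0, σ²)
log-intensity background; 10 % of labels corrupted by reassignment to a
uniformly random *different* class (a single-sample predictor always
outputs a subtype, never "inconsistent"); class-conditional marker
probabilities following the expected receptor patterns (luminal ER+,
HER2-enriched HER2+, basal triple-negative); exponential survival with
per-class hazards ordered by the usual prognosis gradient and
independent exponential censoring (≈ 1/4000 per day, giving roughly a
third censored).

What the generator does **not** emulate: probe–probe correlation
within and between signatures, batch effects, heavy-tailed intensity
noise, class overlap on a continuum (planted classes are
homogeneous blocks), and informative censoring. Passing tests
therefore demonstrate that the machinery is correct and that the loop
repairs label noise under its own assumptions — not that it would
resolve the harder ambiguities of real cohorts, where signatures
overlap and some samples are genuinely intermediate.

## Problem sizes

The bundled tests and the acceptance script run at desk scale, chosen
so the full suite completes in a few minutes: 1000 × 688 instances
with the 8-member fast roster for pipeline-level checks (one such
pipeline takes a few seconds), 200-probe instances for unit-level
checks, and 1,000 random small instances per statistic for oracle
equivalence. Cohort-scale runs (≈ 48,800 probes, ≈ 2,000 samples, the
24-member roster) use the identical code paths; only the input sizes
differ.

## Known limitations

* The classifier roster is a reconstruction by family, not a replica of
  the original 24-member suite; refined labels on real data will differ
  in detail from the reference implementation's.
* The exact CM1 spread normalisation in the companion literature could
  not be consulted; the default is one member of the plausible family
  and is pluggable (`cm1_denominator`).
* Consensus pools the 10 runs' votes; a run-level
  majority-of-majorities is a defensible alternative reading and would
  be slightly stricter near the threshold.
* Samples marked inconsistent re-enter only through the train–test
  stage; within a refinement phase their exclusion is permanent, which
  matches the described procedure but forfeits information if the
  ensemble was wrong about them.
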