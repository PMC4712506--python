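# subtyperefine

Iterative ensemble-consensus refinement of breast cancer intrinsic
subtype labels.

Single-sample predictors such as PAM50 assign each breast tumour one of
five intrinsic subtypes (luminal A, luminal B, HER2-enriched,
basal-like, normal-like) from its expression profile, but the labels
they produce are noisy: different predictors agree only moderately, and
mislabelled samples blur the clinical signatures of the groups.
`subtyperefine` implements an iterative procedure that treats the
initial labels as provisional and refines them until an ensemble of
heterogeneous classifiers agrees with itself:

1. **CM1 scoring.** For each class *c* and each probe, compute the
   signed separation score
   CM1 = (μ_in − μ_out) / (σ_in + σ_out)
   between class-*c* samples and all other labelled samples, and keep
   the 5 most positive (up-regulated) and 5 most negative
   (down-regulated) probes per class — a signed top-10 signature.
2. **Balanced ensemble voting.** Down-sample every class to the
   minimum class size, train a roster of 24 heterogeneous classifiers
   (trees, shallow rule-like trees, naive Bayes, linear/discriminant
   models, nearest neighbours, bagging/boosting) on the signature
   probes with stratified 10-fold cross-validation, and repeat the
   whole draw 10 times, pooling all votes.
3. **Consensus relabelling.** A sample keeps a class only if that class
   is the unique vote maximum with ≥ 50 % of its cast votes; otherwise
   it is marked *inconsistent* and excluded from all further scoring
   and training in the phase.
4. **Stopping.** Iterate until labels and feature set both stop
   changing, or Fleiss' κ between consecutive labellings reaches 0.92
   ("almost perfect agreement").
5. **Train–test stage.** Held-out samples (a validation cohort, plus
   anything marked inconsistent) are classified by the refined model
   under a stricter two-thirds consensus, merged, and run through the
   same refinement once more.

Label quality is evaluated with Cramér's V, Fleiss' κ (with the
conventional six interpretation bands) and the adjusted Rand index —
all implemented from their defining formulas — and clinically with
ER/PR/HER2 marker tables, Kaplan–Meier curves and the K-group log-rank
test.

Because the cohort that motivated the method is access-controlled, the
package bundles a synthetic-data generator that emulates its structure
(five imbalanced classes, planted up/down probe blocks, corrupted
initial labels, class-conditional markers and survival hazards), so the
whole pipeline is testable end to end.

## Worked example

```python
from subtyperefine import (GeneratorSpec, RefinementConfig, fast_roster,
                           generate, run_refinement, agreement_report,
                           logrank_by_label)

ds = generate(GeneratorSpec(seed=1))          # 1000 probes x 688 samples
trace = run_refinement(ds.matrix, ds.initial, fast_roster(),
                       RefinementConfig(master_seed=42))
print("iterations:", len(trace.records), "| stop:", trace.stop_reason)
report, table = agreement_report(trace.final_labelling, ds.truth)
print(f"vs planted truth: V={report.cramers_v:.3f} "
      f"kappa={report.fleiss_kappa:.3f} ({report.kappa_band}) "
      f"ARI={report.ari:.3f}")
stat, df, p = logrank_by_label(trace.final_labelling, ds.clinical)
print(f"log-rank: chi2={stat:.1f} (df={df}), p={p:.2e}")
```

prints

```
iterations: 2 | stop: kappa_reached
vs planted truth: V=1.000 kappa=1.000 (almost perfect agreement) ARI=1.000
log-rank: chi2=137.1 (df=4), p=1.19e-28
```

The generator corrupts 10 % of the initial labels; two refinement
iterations repair every one of them (perfect association, agreement and
partition concordance with the planted truth), and the five refined
groups separate the planted survival hazards sharply.

The same workflow is available from the shell:

```bash
subtyperefine simulate --seed 1 --outdir sim/
subtyperefine pipeline --expression sim/expression.tsv \
    --labels sim/labels_initial.tsv --roster fast --outdir out/
subtyperefine report --labels out/labels_final.tsv \
    --initial sim/labels_true.tsv --clinical sim/clinical.tsv --outdir rep/
```

Every output directory contains a `manifest.json` (effective config,
full roster, seed, input digests) sufficient to reproduce the run
bit-identically.

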