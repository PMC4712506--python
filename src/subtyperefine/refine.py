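"""The iterative label-refinement loop and the two-stage pipeline.

One refinement iteration, starting from the currently assigned samples:

1. score all probes with CM1 against the current labels and select the
   per-class signed top-k feature set;
2. repeat ``runs`` times (default 10): draw a class-balanced training
   subset (every class down-sampled to the minimum class size), collect
   out-of-fold votes for subset samples via stratified k-fold
   cross-validation, and votes for the remaining assigned samples from
   members trained on the whole subset;
3. pool the votes of all runs into one vote matrix and apply majority
   consensus (>= 50 % of cast votes, unique maximum); samples failing
   consensus become INCONSISTENT and leave the assigned pool for the
   rest of the phase.

Iterations stop when labels and feature set both stop changing, when
Fleiss' kappa between consecutive labellings reaches ``kappa_stop``
(default 0.92), or at the ``max_iterations`` safety cap.

The full pipeline refines the discovery set, reclassifies validation
and inconsistent samples in train-test mode (two-thirds consensus,
failures UNASSIGNED), merges the assigned samples and refines again.
All randomness derives from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementReport, agreement_report, pairwise_kappa
from .cm1 import FeatureSet, select_features
from .ensemble import (
    ClassifierRoster,
    VoteMatrix,
    consensus,
    crossval_votes,
    predict_votes,
)
from .io_core import ExpressionMatrix, INCONSISTENT, Labelling, UNASSIGNED, align

logger = logging.getLogger(__name__)

STOP_NONE = "none"
STOP_STABLE = "labels_and_features_stable"
STOP_KAPPA = "kappa_reached"
STOP_MAX = "max_iterations"


@dataclass(frozen=True)
class RefinementConfig:
    """Tunable parameters of the refinement loop."""

    k_up: int = 5
    k_down: int = 5
    folds: int = 10
    runs: int = 10
    refine_threshold: float = 0.5
    traintest_threshold: float = 2.0 / 3.0
    kappa_stop: float = 0.92
    max_iterations: int = 50
    master_seed: int = 0
    cm1_denominator: str = "sum_sd"

    def __post_init__(self) -> None:
        for name in ("refine_threshold", "traintest_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 <= self.kappa_stop <= 1.0):
            raise ValueError(f"kappa_stop must be in [0, 1], got {self.kappa_stop}")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def derive_seed(master_seed: int, *path: int) -> int:
    """Deterministic sub-seed for a position in the run hierarchy."""
    return int(np.random.SeedSequence([master_seed, *path]).generate_state(1)[0]
               % (2**31))


@dataclass
class IterationRecord:
    """What one refinement iteration did."""

    iteration: int
    features: FeatureSet
    before: Labelling
    after: Labelling
    n_label_changes: int        # assigned before and after, class changed
    n_new_inconsistent: int
    kappa_vs_previous: float
    stop_reason: str = STOP_NONE
    votes: VoteMatrix | None = None   # pooled over runs


@dataclass
class RefinementTrace:
    """Complete record of one refinement phase."""

    records: list[IterationRecord]
    final_labelling: Labelling
    final_features: FeatureSet
    provenance: dict = field(default_factory=dict)

    @property
    def stop_reason(self) -> str:
        return self.records[-1].stop_reason

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"iteration": r.iteration,
              "n_label_changes": r.n_label_changes,
              "n_new_inconsistent": r.n_new_inconsistent,
              "kappa_vs_previous": r.kappa_vs_previous,
              "n_assigned_after": len(r.after.assigned()),
              "stop_reason": r.stop_reason}
             for r in self.records])


def balance_classes(labelling: Labelling, seed: int) -> list[str]:
    """Class-balanced training subset: every class down-sampled (without
    replacement, seeded) to the minimum class size.

    The minimum class contributes all its samples, so with class sizes
    {728, 600, 234, 233, 58} the subset holds 58 x 5 = 290 samples.
    """
    assigned = labelling.assigned()
    by_class: dict[str, list[str]] = {c: [] for c in labelling.classes}
    for s, c in assigned.items():
        by_class[c].append(s)
    empty = [c for c, ids in by_class.items() if not ids]
    if empty:
        raise ValueError(f"classes with no assigned samples: {empty}")
    m = min(len(ids) for ids in by_class.values())
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for c in labelling.classes:
        ids = by_class[c]
        if len(ids) == m:
            out.extend(ids)
        else:
            pick = rng.choice(len(ids), size=m, replace=False)
            out.extend(ids[i] for i in sorted(pick))
    return out


def _check_min_class(labelling: Labelling, minimum: int = 2) -> None:
    for c, n in labelling.class_sizes().items():
        if n < minimum:
            raise ValueError(
                f"class {c!r} has {n} assigned samples (need >= {minimum})")


def refine_iteration(
    matrix: ExpressionMatrix,
    labelling: Labelling,
    roster: ClassifierRoster,
    config: RefinementConfig,
    iteration_seed: int,
) -> IterationRecord:
    """One pass of feature selection, balanced ensemble voting and consensus."""
    _check_min_class(labelling)
    features = select_features(matrix, labelling, config.k_up, config.k_down,
                               denominator=config.cm1_denominator)
    union_matrix = matrix.subset_probes(features.union)
    assigned_ids = [s for s in matrix.sample_ids if s in labelling.assigned()]
    pooled: VoteMatrix | None = None
    for run in range(config.runs):
        subset_ids = balance_classes(labelling, derive_seed(iteration_seed, run, 0))
        sub_matrix = union_matrix.subset_samples(subset_ids)
        sub_lab = labelling.subset(subset_ids)
        votes = crossval_votes(sub_matrix, sub_lab, roster, config.folds,
                               derive_seed(iteration_seed, run, 1))
        outside = [s for s in assigned_ids if s not in set(subset_ids)]
        if outside:
            out_votes = predict_votes(sub_matrix, sub_lab,
                                      union_matrix.subset_samples(outside),
                                      roster, derive_seed(iteration_seed, run, 2))
            votes = votes.add(out_votes)
        pooled = votes if pooled is None else pooled.add(votes)
    assert pooled is not None
    new_states = consensus(pooled, config.refine_threshold, mode="refine",
                           classes=labelling.classes)
    after = labelling.replace(new_states.states)
    before_assigned = labelling.assigned()
    after_assigned = after.assigned()
    n_changes = sum(1 for s, c in before_assigned.items()
                    if s in after_assigned and after_assigned[s] != c)
    n_new_inc = sum(1 for s in before_assigned if s not in after_assigned)
    if after_assigned and before_assigned:
        try:
            kappa = pairwise_kappa(labelling, after)
        except ValueError:
            kappa = float("nan")
    else:
        kappa = float("nan")
    return IterationRecord(-1, features, labelling, after,
                           n_changes, n_new_inc, kappa, votes=pooled)


def run_refinement(
    matrix: ExpressionMatrix,
    initial: Labelling,
    roster: ClassifierRoster,
    config: RefinementConfig,
    *,
    phase: int = 0,
) -> RefinementTrace:
    """Iterate :func:`refine_iteration` until a stopping criterion fires."""
    matrix, labelling = align(matrix, initial)
    records: list[IterationRecord] = []
    prev_features: FeatureSet | None = None
    for it in range(config.max_iterations):
        rec = refine_iteration(matrix, labelling, roster, config,
                               derive_seed(config.master_seed, phase, it))
        rec.iteration = it
        labels_stable = rec.after == rec.before
        features_stable = prev_features is None or rec.features == prev_features
        if labels_stable and features_stable:
            rec.stop_reason = STOP_STABLE
        elif rec.kappa_vs_previous >= config.kappa_stop:
            rec.stop_reason = STOP_KAPPA
        elif it == config.max_iterations - 1:
            rec.stop_reason = STOP_MAX
            logger.warning("refinement hit the %d-iteration safety cap",
                           config.max_iterations)
        records.append(rec)
        labelling = rec.after
        prev_features = rec.features
        if rec.stop_reason != STOP_NONE:
            break
    trace = RefinementTrace(
        records, labelling, records[-1].features,
        provenance={"config": config, "roster": roster.to_config(),
                    "phase": phase, "master_seed": config.master_seed})
    logger.info("refinement phase %d stopped after %d iteration(s): %s",
                phase, len(records), trace.stop_reason)
    return trace


def reclassify(
    discovery_matrix: ExpressionMatrix,
    refined: Labelling,
    features: FeatureSet,
    target_matrix: ExpressionMatrix,
    roster: ClassifierRoster,
    config: RefinementConfig,
    *,
    phase: int = 1,
) -> Labelling:
    """Train-test classification of held-out / previously inconsistent samples.

    Per run, members train on a balanced subset of the refined discovery
    set (restricted to the refined feature union) and vote on every
    target sample; pooled votes face the stricter two-thirds consensus,
    and failures are UNASSIGNED.
    """
    _check_min_class(refined)
    union_matrix = discovery_matrix.subset_probes(features.union)
    target_union = target_matrix.subset_probes(features.union)
    pooled: VoteMatrix | None = None
    for run in range(config.runs):
        subset_ids = balance_classes(refined,
                                     derive_seed(config.master_seed, phase, run, 0))
        votes = predict_votes(union_matrix.subset_samples(subset_ids),
                              refined.subset(subset_ids), target_union, roster,
                              derive_seed(config.master_seed, phase, run, 1))
        pooled = votes if pooled is None else pooled.add(votes)
    assert pooled is not None
    return consensus(pooled, config.traintest_threshold, mode="traintest",
                     classes=refined.classes)


@dataclass
class PipelineResult:
    """Everything the two-stage pipeline produced."""

    discovery_trace: RefinementTrace
    reclassified: Labelling | None
    final_trace: RefinementTrace
    final_labelling: Labelling       # over all input samples
    final_features: FeatureSet
    contingency: pd.DataFrame
    report: AgreementReport


def full_pipeline(
    discovery_matrix: ExpressionMatrix,
    initial: Labelling,
    validation_matrix: ExpressionMatrix | None,
    roster: ClassifierRoster,
    config: RefinementConfig,
    *,
    initial_validation: Labelling | None = None,
) -> PipelineResult:
    """Discovery refinement -> train-test reclassification -> joint refinement.

    ``initial_validation`` (optional) provides initial labels for
    validation samples for the final contingency/agreement report only;
    the pipeline itself never trains on them.
    """
    discovery_matrix, initial_aligned = align(discovery_matrix, initial)
    phase1 = run_refinement(discovery_matrix, initial_aligned, roster, config,
                            phase=0)
    inconsistent_ids = phase1.final_labelling.samples_in_state(INCONSISTENT)
    val_ids = validation_matrix.sample_ids if validation_matrix is not None else []
    target_ids = val_ids + [s for s in inconsistent_ids if s not in set(val_ids)]

    if not target_ids:
        final_trace = phase1
        reclassified = None
        final_labelling = phase1.final_labelling
    else:
        parts = []
        if validation_matrix is not None and val_ids:
            parts.append(validation_matrix.values)
        if inconsistent_ids:
            parts.append(discovery_matrix.values.loc[:, inconsistent_ids])
        target_values = pd.concat(parts, axis=1)
        target_values = target_values.loc[:, ~target_values.columns.duplicated()]
        target_matrix = ExpressionMatrix(target_values)
        reclassified = reclassify(discovery_matrix, phase1.final_labelling,
                                  phase1.final_features, target_matrix, roster,
                                  config, phase=1)
        # merge: discovery samples still assigned after phase 1 + newly
        # assigned targets; UNASSIGNED targets sit the joint phase out
        merged_states = dict(phase1.final_labelling.assigned())
        merged_states.update(reclassified.assigned())
        merged = Labelling(merged_states, initial.classes)
        full_values = discovery_matrix.values
        if validation_matrix is not None and val_ids:
            shared = [p for p in discovery_matrix.probe_ids
                      if p in set(validation_matrix.probe_ids)]
            if len(shared) < len(discovery_matrix.probe_ids):
                raise ValueError("validation matrix lacks discovery probes")
            full_values = pd.concat(
                [discovery_matrix.values,
                 validation_matrix.values.loc[discovery_matrix.probe_ids]], axis=1)
            full_values = full_values.loc[:, ~full_values.columns.duplicated()]
        merged_matrix = ExpressionMatrix(full_values).subset_samples(
            [s for s in full_values.columns if s in merged_states])
        final_trace = run_refinement(merged_matrix, merged, roster, config,
                                     phase=2)
        # assemble the final state of every input sample
        final_states = dict(final_trace.final_labelling.states)
        for s in target_ids:
            if s not in final_states:
                final_states[s] = reclassified.states[s]   # UNASSIGNED
        for s in discovery_matrix.sample_ids:
            if s not in final_states:
                final_states[s] = phase1.final_labelling.states[s]
        final_labelling = Labelling(final_states, initial.classes)

    # initial labels for reporting: discovery initials plus optional
    # validation initials
    report_initial_states = dict(initial_aligned.states)
    if initial_validation is not None:
        for s, v in initial_validation.states.items():
            report_initial_states.setdefault(s, v)
    report_initial = Labelling(report_initial_states, initial.classes)
    report, table = agreement_report(final_labelling, report_initial)
    return PipelineResult(phase1, reclassified, final_trace, final_labelling,
                          final_trace.final_features, table, report)
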