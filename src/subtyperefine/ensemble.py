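"""Heterogeneous classifier ensemble: roster, voting, consensus.

The refinement loop never trusts a single classifier.  A roster of
heterogeneous members (default: 24 scikit-learn estimators spanning
tree-based, rule-like shallow trees, naive-Bayes, linear/function-based,
nearest-neighbour and bagged/boosted meta-learner families) votes on
every sample, either out-of-fold within a stratified k-fold
cross-validation (training samples) or after training once on the full
training set (held-out samples).  Votes are reduced to a consensus label
per sample: a class wins only if it is the unique vote maximum and
reaches the required fraction of that sample's cast votes; otherwise the
sample is marked INCONSISTENT (refinement mode) or UNASSIGNED
(train-test mode).

A member that fails to train on a fold abstains for that fold's test
samples; abstentions shrink the sample's vote total rather than counting
against any class.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier

from .io_core import ExpressionMatrix, INCONSISTENT, Labelling, UNASSIGNED

logger = logging.getLogger(__name__)

ABSTAIN = "ABSTAIN"

FAMILIES = ("tree", "rule", "bayes", "linear", "knn", "meta")

# algorithm name -> (family, constructor, accepts random_state)
_ALGORITHMS: dict[str, tuple[str, type, bool]] = {
    "decision_tree": ("tree", DecisionTreeClassifier, True),
    "extra_tree": ("tree", ExtraTreeClassifier, True),
    "shallow_tree": ("rule", DecisionTreeClassifier, True),
    "gaussian_nb": ("bayes", GaussianNB, False),
    "bernoulli_nb": ("bayes", BernoulliNB, False),
    "logistic": ("linear", LogisticRegression, True),
    "ridge": ("linear", RidgeClassifier, True),
    "sgd_log": ("linear", SGDClassifier, True),
    "lda": ("linear", LinearDiscriminantAnalysis, False),
    "qda": ("linear", QuadraticDiscriminantAnalysis, False),
    "knn": ("knn", KNeighborsClassifier, False),
    "random_forest": ("meta", RandomForestClassifier, True),
    "extra_trees": ("meta", ExtraTreesClassifier, True),
    "bagging": ("meta", BaggingClassifier, True),
    "adaboost": ("meta", AdaBoostClassifier, True),
}


@dataclass(frozen=True)
class Member:
    """One roster entry: a named, fully parameterised classifier spec."""

    member_id: str
    algorithm: str
    params: tuple[tuple[str, Any], ...] = ()

    @property
    def family(self) -> str:
        return _ALGORITHMS[self.algorithm][0]

    def build(self, random_state: int | None = None):
        family, cls, takes_seed = _ALGORITHMS[self.algorithm]
        kwargs = dict(self.params)
        if self.algorithm == "bagging" and "estimator" not in kwargs:
            kwargs["estimator"] = DecisionTreeClassifier()
        if self.algorithm == "adaboost" and "estimator" not in kwargs:
            kwargs["estimator"] = DecisionTreeClassifier(max_depth=1)
        if takes_seed:
            kwargs["random_state"] = random_state
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {"member_id": self.member_id, "family": self.family,
                "algorithm": self.algorithm, "params": dict(self.params)}


@dataclass
class ClassifierRoster:
    """Ordered, uniquely named list of ensemble members."""

    members: list[Member]

    def __post_init__(self) -> None:
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            dup = next(x for x in ids if ids.count(x) > 1)
            raise ValueError(f"duplicate member_id {dup!r} in roster")

    def __len__(self) -> int:
        return len(self.members)

    def families(self) -> set[str]:
        return {m.family for m in self.members}

    def to_config(self) -> list[dict[str, Any]]:
        return [m.to_dict() for m in self.members]


_DEFAULT_SPECS: list[tuple[str, str, dict[str, Any]]] = [
    # tree family
    ("dt_gini", "decision_tree", {"criterion": "gini"}),
    ("dt_entropy", "decision_tree", {"criterion": "entropy"}),
    ("dt_depth5", "decision_tree", {"max_depth": 5}),
    ("xtree", "extra_tree", {}),
    # rule-like shallow trees (stump ~ one-rule classifier)
    ("stump", "shallow_tree", {"max_depth": 1}),
    ("rule2", "shallow_tree", {"max_depth": 2}),
    ("rule3", "shallow_tree", {"max_depth": 3, "criterion": "entropy"}),
    # naive Bayes
    ("gnb", "gaussian_nb", {}),
    ("gnb_smooth", "gaussian_nb", {"var_smoothing": 1e-3}),
    ("bnb", "bernoulli_nb", {"binarize": 0.0}),
    # linear / function-based
    ("logreg", "logistic", {"max_iter": 500}),
    ("logreg_c01", "logistic", {"max_iter": 500, "C": 0.1}),
    ("ridge", "ridge", {}),
    ("sgd_log", "sgd_log", {"loss": "log_loss", "max_iter": 300, "tol": 1e-3}),
    ("lda", "lda", {}),
    ("qda", "qda", {"reg_param": 0.1}),
    # nearest neighbour
    ("knn1", "knn", {"n_neighbors": 1}),
    ("knn3", "knn", {"n_neighbors": 3}),
    ("knn5", "knn", {"n_neighbors": 5}),
    ("knn5_dist", "knn", {"n_neighbors": 5, "weights": "distance"}),
    # bagged / boosted meta-learners
    ("rf", "random_forest", {"n_estimators": 30}),
    ("xtrees", "extra_trees", {"n_estimators": 30}),
    ("bag_dt", "bagging", {"n_estimators": 10}),
    ("ada_stump", "adaboost", {"n_estimators": 20}),
]

_FAST_IDS = ("gnb", "lda", "logreg", "ridge", "dt_gini", "xtree", "knn3", "knn5_dist")


def build_roster(config: Sequence[Mapping[str, Any]] | None = None) -> ClassifierRoster:
    """Build a roster from a config list, or the 24-member default.

    Each config entry needs ``member_id`` and ``algorithm`` (one of the
    registered algorithm names) plus optional ``params``.
    """
    if config is None:
        members = [Member(mid, algo, tuple(sorted(params.items())))
                   for mid, algo, params in _DEFAULT_SPECS]
        return ClassifierRoster(members)
    if len(config) < 2:
        raise ValueError("roster config must name at least 2 members")
    members = []
    for entry in config:
        algo = entry["algorithm"]
        if algo not in _ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {algo!r}; known: {sorted(_ALGORITHMS)}")
        members.append(Member(entry["member_id"], algo,
                              tuple(sorted(dict(entry.get("params", {})).items()))))
    return ClassifierRoster(members)


def default_roster() -> ClassifierRoster:
    """The full 24-member roster spanning all six families."""
    return build_roster(None)


def fast_roster() -> ClassifierRoster:
    """A reduced 8-member roster of quick-to-train members for desk-scale runs."""
    full = {m.member_id: m for m in default_roster().members}
    return ClassifierRoster([full[i] for i in _FAST_IDS])


@dataclass
class VoteMatrix:
    """Per-sample, per-class vote counts plus the per-member prediction log.

    ``counts`` is samples x classes (non-negative ints); ``total_votes``
    counts the votes actually cast per sample (abstentions excluded).
    The log has columns sample_id, member_id, fold, predicted_label and
    is sufficient to recompute ``counts`` exactly.
    """

    counts: pd.DataFrame
    total_votes: pd.Series
    log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "member_id", "fold", "predicted_label"])
    )

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative vote count")
        if (self.counts.sum(axis=1) > self.total_votes).any():
            raise ValueError("class votes exceed total votes for some sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def classes(self) -> list[str]:
        return list(self.counts.columns)

    def add(self, other: "VoteMatrix") -> "VoteMatrix":
        """Pool two vote matrices (union of samples, summed counts)."""
        if list(other.counts.columns) != list(self.counts.columns):
            raise ValueError("cannot pool vote matrices over different class lists")
        counts = self.counts.add(other.counts, fill_value=0).astype(int)
        totals = self.total_votes.add(other.total_votes, fill_value=0).astype(int)
        log = pd.concat([self.log, other.log], ignore_index=True)
        return VoteMatrix(counts, totals.loc[counts.index], log)

    def recompute_from_log(self) -> pd.DataFrame:
        """Rebuild the counts table from the prediction log (conservation check)."""
        cast = self.log[self.log["predicted_label"] != ABSTAIN]
        table = pd.crosstab(cast["sample_id"], cast["predicted_label"])
        return table.reindex(index=self.counts.index,
                             columns=self.counts.columns, fill_value=0).astype(int)


def _samples_by_column(matrix: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    """Return samples x features array and the sample id order."""
    return matrix.values.to_numpy().T, matrix.sample_ids


def crossval_votes(
    matrix: ExpressionMatrix,
    labelling: Labelling,
    roster: ClassifierRoster,
    folds: int = 10,
    seed: int = 0,
) -> VoteMatrix:
    """Out-of-fold votes for every training sample from every member.

    Folds are stratified by class and shuffled with ``seed``.  If the
    smallest class has fewer members than ``folds`` the fold count is
    reduced to that size (stratified k-fold requires it); every class
    must have at least 2 samples.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    assigned = labelling.assigned()
    if set(assigned) != set(labelling.sample_ids):
        raise ValueError("crossval_votes requires all samples to carry class labels")
    X, sample_ids = _samples_by_column(matrix)
    y = np.array([assigned[s] for s in sample_ids])
    class_counts = pd.Series(y).value_counts()
    if (class_counts < 2).any():
        small = class_counts[class_counts < 2].index.tolist()
        raise ValueError(f"classes with <2 training samples: {small}")
    eff_folds = min(folds, int(class_counts.min()))
    if eff_folds < folds:
        logger.warning("reducing folds from %d to %d (smallest class size)",
                       folds, eff_folds)
    skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    classes = list(labelling.classes)
    class_idx = {c: j for j, c in enumerate(classes)}
    arr = np.zeros((len(sample_ids), len(classes)), dtype=int)
    tot = np.zeros(len(sample_ids), dtype=int)
    log_rows: list[tuple[str, str, int, str]] = []
    rng_seeds = np.random.SeedSequence(seed).generate_state(len(roster)) % (2**31)
    folds_split = list(skf.split(X, y))
    n_failed_members = 0
    for m_idx, member in enumerate(roster.members):
        member_failed_everywhere = True
        for fold_idx, (train_idx, test_idx) in enumerate(folds_split):
            est = member.build(int(rng_seeds[m_idx]))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[train_idx], y[train_idx])
                    preds = est.predict(X[test_idx])
            except Exception as exc:  # member abstains on this fold
                logger.warning("member %s failed on fold %d: %s",
                               member.member_id, fold_idx, exc)
                for i in test_idx:
                    log_rows.append((sample_ids[i], member.member_id, fold_idx, ABSTAIN))
                continue
            member_failed_everywhere = False
            pred_j = np.array([class_idx[str(p)] for p in preds], dtype=int)
            np.add.at(arr, (test_idx, pred_j), 1)
            tot[test_idx] += 1
            log_rows.extend(
                (sample_ids[i], member.member_id, fold_idx, str(p))
                for i, p in zip(test_idx, preds))
        if member_failed_everywhere:
            n_failed_members += 1
    if n_failed_members == len(roster):
        raise RuntimeError("all roster members failed to train")
    counts = pd.DataFrame(arr, index=sample_ids, columns=classes)
    totals = pd.Series(tot, index=sample_ids)
    log = pd.DataFrame(log_rows,
                       columns=["sample_id", "member_id", "fold", "predicted_label"])
    return VoteMatrix(counts, totals, log)


def predict_votes(
    train_matrix: ExpressionMatrix,
    train_labelling: Labelling,
    target_matrix: ExpressionMatrix,
    roster: ClassifierRoster,
    seed: int = 0,
) -> VoteMatrix:
    """Votes for target samples from members trained once on the full training set."""
    missing = [p for p in train_matrix.probe_ids
               if p not in set(target_matrix.probe_ids)]
    if missing:
        raise ValueError(
            f"target matrix lacks {len(missing)} training features, e.g. {missing[:3]}")
    target = target_matrix.subset_probes(train_matrix.probe_ids)
    assigned = train_labelling.assigned()
    X_train, train_ids = _samples_by_column(train_matrix)
    y_train = np.array([assigned[s] for s in train_ids])
    X_target, target_ids = _samples_by_column(target)
    classes = list(train_labelling.classes)
    class_idx = {c: j for j, c in enumerate(classes)}
    arr = np.zeros((len(target_ids), len(classes)), dtype=int)
    tot = np.zeros(len(target_ids), dtype=int)
    log_rows: list[tuple[str, str, int, str]] = []
    rng_seeds = np.random.SeedSequence(seed).generate_state(len(roster)) % (2**31)
    n_failed = 0
    for m_idx, member in enumerate(roster.members):
        est = member.build(int(rng_seeds[m_idx]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X_train, y_train)
                preds = est.predict(X_target)
        except Exception as exc:
            logger.warning("member %s failed in train-test: %s", member.member_id, exc)
            for sid in target_ids:
                log_rows.append((sid, member.member_id, -1, ABSTAIN))
            n_failed += 1
            continue
        pred_j = np.array([class_idx[str(p)] for p in preds], dtype=int)
        np.add.at(arr, (np.arange(len(target_ids)), pred_j), 1)
        tot += 1
        log_rows.extend((sid, member.member_id, -1, str(p))
                        for sid, p in zip(target_ids, preds))
    if n_failed == len(roster):
        raise RuntimeError("all roster members failed to train")
    counts = pd.DataFrame(arr, index=target_ids, columns=classes)
    totals = pd.Series(tot, index=target_ids)
    log = pd.DataFrame(log_rows,
                       columns=["sample_id", "member_id", "fold", "predicted_label"])
    return VoteMatrix(counts, totals, log)


def required_votes(threshold_fraction: float, total: int) -> int:
    """ceil(threshold * total), robust to binary float representation of e.g. 2/3."""
    return int(math.ceil(threshold_fraction * total - 1e-9))


def consensus(
    votes: VoteMatrix,
    threshold_fraction: float,
    mode: str = "refine",
    classes: Sequence[str] | None = None,
) -> Labelling:
    """Reduce votes to per-sample consensus labels.

    A sample is assigned class c iff c is the unique vote maximum and
    votes[c] >= ceil(threshold_fraction * total_votes).  Failures become
    INCONSISTENT in ``"refine"`` mode, UNASSIGNED in ``"traintest"`` mode.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must be in (0, 1]")
    if mode not in ("refine", "traintest"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    if len(votes.counts) == 0:
        raise ValueError("empty vote matrix")
    fallback = INCONSISTENT if mode == "refine" else UNASSIGNED
    class_list = tuple(classes) if classes is not None else tuple(votes.classes)
    states: dict[str, str] = {}
    counts = votes.counts
    for sid in votes.sample_ids:
        row = counts.loc[sid]
        total = int(votes.total_votes.loc[sid])
        if total == 0:
            states[sid] = fallback
            continue
        top = int(row.max())
        winners = [c for c in votes.classes if row[c] == top]
        if len(winners) != 1 or top < required_votes(threshold_fraction, total):
            states[sid] = fallback
        else:
            states[sid] = winners[0]
    return Labelling(states, class_list)
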