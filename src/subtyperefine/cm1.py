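"""CM1 discriminative probe scoring and per-class feature selection.

The CM1 score is a signed one-vs-rest separation statistic computed per
probe and per class: positive scores flag probes up-regulated in the
class relative to all other assigned samples pooled, negative scores
down-regulated probes.  The default definition is

    CM1 = (mean_in - mean_out) / (sd_in + sd_out)

with sample standard deviations (ddof=1).  The denominator is pluggable
(``"sum_sd"`` default, ``"pooled_sd"``, ``"range"``) because the score
family admits several spread normalisations; the refinement loop is
insensitive to the exact choice as long as it is used consistently.

Feature selection takes, per class, the ``k_up`` highest strictly
positive scores and the ``k_down`` lowest strictly negative scores (the
conventional "top ten": five up, five down); zero scores never qualify.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, Labelling

logger = logging.getLogger(__name__)

#: Magnitude assigned when the spread term vanishes but the means differ.
ZERO_DENOM_CAP = 1e6

DENOMINATORS = ("sum_sd", "pooled_sd", "range")


class DegenerateClassError(ValueError):
    """A class (or its complement) has fewer than 2 samples."""


def cm1_score(
    values: np.ndarray,
    in_class: np.ndarray,
    *,
    denominator: str = "sum_sd",
    cap: float = ZERO_DENOM_CAP,
) -> float:
    """Signed separation score of one probe for one class-vs-rest split.

    Parameters
    ----------
    values : array of expression values over samples.
    in_class : boolean mask, True for samples in the class.
    denominator : spread normalisation, one of ``"sum_sd"`` (sd_in +
        sd_out), ``"pooled_sd"`` or ``"range"`` (max - min over all
        samples).
    cap : magnitude returned when the spread is 0 but the means differ.

    Returns 0.0 when both spread and mean difference vanish.
    """
    values = np.asarray(values, dtype=float)
    in_class = np.asarray(in_class, dtype=bool)
    if values.shape != in_class.shape:
        raise ValueError("values and mask must have the same shape")
    n_in = int(in_class.sum())
    n_out = int((~in_class).sum())
    if n_in < 2 or n_out < 2:
        raise DegenerateClassError(
            f"degenerate class: {n_in} in-class / {n_out} out-of-class samples"
        )
    x_in = values[in_class]
    x_out = values[~in_class]
    num = float(x_in.mean() - x_out.mean())
    if denominator == "sum_sd":
        den = float(x_in.std(ddof=1) + x_out.std(ddof=1))
    elif denominator == "pooled_sd":
        den = math.sqrt(
            ((n_in - 1) * x_in.var(ddof=1) + (n_out - 1) * x_out.var(ddof=1))
            / (n_in + n_out - 2)
        )
    elif denominator == "range":
        den = float(values.max() - values.min())
    else:
        raise ValueError(f"unknown denominator {denominator!r}; choose from {DENOMINATORS}")
    # zero-detection is relative to the data scale so that float
    # cancellation on (near-)constant vectors cannot fabricate a score
    eps = 1e-12 * max(1.0, float(np.abs(values).max()))
    if den <= eps:
        if abs(num) <= eps:
            return 0.0
        return math.copysign(cap, num)
    return num / den


def rank_probes(
    matrix: ExpressionMatrix,
    labelling: Labelling,
    class_label: str,
    *,
    denominator: str = "sum_sd",
) -> pd.DataFrame:
    """Score every probe for ``class_label`` vs the pooled rest.

    Only samples currently carrying a class label participate.  Returns a
    frame with columns ``probe_id``, ``class``, ``score``, ``rank``,
    ordered by descending score with ties broken by ascending probe id.
    """
    assigned = labelling.assigned()
    sample_ids = [s for s in matrix.sample_ids if s in assigned]
    mask = np.array([assigned[s] == class_label for s in sample_ids], dtype=bool)
    n_in = int(mask.sum())
    n_out = len(mask) - n_in
    if n_in < 2 or n_out < 2:
        raise DegenerateClassError(
            f"degenerate class {class_label!r}: {n_in} in / {n_out} out"
        )
    sub = matrix.values.loc[:, sample_ids].to_numpy()
    x_in = sub[:, mask]
    x_out = sub[:, ~mask]
    num = x_in.mean(axis=1) - x_out.mean(axis=1)
    if denominator == "sum_sd":
        den = x_in.std(axis=1, ddof=1) + x_out.std(axis=1, ddof=1)
    elif denominator == "pooled_sd":
        den = np.sqrt(
            ((n_in - 1) * x_in.var(axis=1, ddof=1)
             + (n_out - 1) * x_out.var(axis=1, ddof=1)) / (n_in + n_out - 2)
        )
    elif denominator == "range":
        den = sub.max(axis=1) - sub.min(axis=1)
    else:
        raise ValueError(f"unknown denominator {denominator!r}; choose from {DENOMINATORS}")
    eps = 1e-12 * np.maximum(1.0, np.abs(sub).max(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(
            den <= eps,
            np.where(np.abs(num) <= eps, 0.0, np.copysign(ZERO_DENOM_CAP, num)),
            num / den,
        )
    df = pd.DataFrame({"probe_id": matrix.probe_ids, "class": class_label,
                       "score": scores})
    df = df.sort_values(["score", "probe_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class FeatureSet:
    """Per-class signed top probes and their deduplicated union."""

    up_probes: dict[str, list[str]]
    down_probes: dict[str, list[str]]
    union: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.union:
            seen: set[str] = set()
            union: list[str] = []
            for cls in self.up_probes:
                for p in list(self.up_probes[cls]) + list(self.down_probes.get(cls, [])):
                    if p not in seen:
                        seen.add(p)
                        union.append(p)
            self.union = union

    def probes_for(self, class_label: str) -> list[str]:
        return list(self.up_probes[class_label]) + list(self.down_probes[class_label])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureSet):
            return NotImplemented
        return (self.up_probes == other.up_probes
                and self.down_probes == other.down_probes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.up_probes:
            for i, p in enumerate(self.up_probes[cls], 1):
                rows.append((cls, "up", i, p))
            for i, p in enumerate(self.down_probes[cls], 1):
                rows.append((cls, "down", i, p))
        return pd.DataFrame(rows, columns=["class", "direction", "rank", "probe_id"])


def select_features(
    matrix: ExpressionMatrix,
    labelling: Labelling,
    k_up: int = 5,
    k_down: int = 5,
    *,
    denominator: str = "sum_sd",
) -> FeatureSet:
    """Select per-class signed top-k probes over the assigned samples.

    Per class: the ``k_up`` largest strictly positive scores (up-regulated)
    and the ``k_down`` most negative strictly negative scores
    (down-regulated).  Classes with fewer qualifying probes contribute
    shorter lists (logged).  The union preserves first-selection order.
    """
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    for cls in labelling.classes:
        ranked = rank_probes(matrix, labelling, cls, denominator=denominator)
        pos = ranked[ranked["score"] > 0.0]
        neg = ranked[ranked["score"] < 0.0]
        up[cls] = pos["probe_id"].head(k_up).tolist()
        # most negative first: reverse rank order, ties by probe_id ascending
        neg_sorted = neg.sort_values(["score", "probe_id"], ascending=[True, True],
                                     kind="mergesort")
        down[cls] = neg_sorted["probe_id"].head(k_down).tolist()
        if len(up[cls]) < k_up:
            logger.warning("class %s: only %d strictly positive probes (wanted %d)",
                           cls, len(up[cls]), k_up)
        if len(down[cls]) < k_down:
            logger.warning("class %s: only %d strictly negative probes (wanted %d)",
                           cls, len(down[cls]), k_down)
    return FeatureSet(up_probes=up, down_probes=down)
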