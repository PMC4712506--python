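"""Inter-rater / inter-labelling agreement statistics.

Three statistics, each implemented from its defining formula:

* Cramér's V — chi-square-based association between two categorical
  labellings of the same samples, V = sqrt(chi2 / (N * (min(r,c) - 1)))
  over the non-empty rows/columns of their contingency table.
* Fleiss' kappa — chance-corrected multi-rater agreement,
  kappa = (P_bar - Pe_bar) / (1 - Pe_bar), for a constant number of
  raters per subject.  Also used with two "raters" to compare
  consecutive refinement labellings.
* Adjusted Rand Index — chance-adjusted pairwise partition agreement.

Kappa values are mapped onto the conventional six interpretation bands
(poor / slight / fair / moderate / substantial / almost perfect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from .io_core import INCONSISTENT, Labelling

logger = logging.getLogger(__name__)

KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "poor agreement"),
    (0.20, "slight agreement"),
    (0.40, "fair agreement"),
    (0.60, "moderate agreement"),
    (0.80, "substantial agreement"),
    (1.0, "almost perfect agreement"),
)


def contingency_table(
    rows: Mapping[str, str] | Sequence[str],
    cols: Mapping[str, str] | Sequence[str],
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate two labelings of the same samples (rows = predicted,
    columns = initial)."""
    if isinstance(rows, Mapping) and isinstance(cols, Mapping):
        common = [s for s in rows if s in cols]
        if not common:
            raise ValueError("labellings share no samples")
        a = [rows[s] for s in common]
        b = [cols[s] for s in common]
    else:
        a, b = list(rows), list(cols)
        if len(a) != len(b):
            raise ValueError("labelings must cover the same samples")
    table = pd.crosstab(pd.Series(a, name="predicted"), pd.Series(b, name="initial"))
    if row_order is not None:
        table = table.reindex(index=[r for r in row_order], fill_value=0)
    if col_order is not None:
        table = table.reindex(columns=[c for c in col_order], fill_value=0)
    return table.fillna(0).astype(int)


def cramers_v(table: pd.DataFrame | np.ndarray) -> float:
    """Cramér's V association of an r x c contingency table, in [0, 1].

    Empty rows and columns are dropped before computing both the
    chi-square statistic and the min(r, c) - 1 term, so an all-zero
    margin (e.g. an unused label) cannot deflate the statistic.  A table
    with a single non-empty row or column has no defined association.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("negative count in contingency table")
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    r, c = arr.shape
    if r < 2 or c < 2:
        raise ValueError("association undefined: single non-empty row or column")
    n = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    chi2 = float(((arr - expected) ** 2 / expected).sum())
    v = np.sqrt(chi2 / (n * (min(r, c) - 1)))
    return float(min(max(v, 0.0), 1.0))


def fleiss_kappa(ratings: pd.DataFrame | np.ndarray) -> float:
    """Fleiss' kappa for an n-subjects x q-categories rating-count table.

    Every subject must be rated by the same number (>= 2) of raters.
    Returns exactly 1.0 when all subjects are unanimous (including the
    degenerate one-category case, where chance agreement is also 1).
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("rating table must be 2-dimensional with >= 1 subject")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("rating table must hold non-negative integer counts")
    row_sums = arr.sum(axis=1)
    m = row_sums[0]
    if not np.all(row_sums == m):
        raise ValueError("raters-per-subject must be constant across subjects")
    if m < 2:
        raise ValueError("need >= 2 raters per subject")
    n = arr.shape[0]
    # per-subject observed agreement and category marginals
    p_i = (np.sum(arr * (arr - 1), axis=1)) / (m * (m - 1))
    p_bar = float(p_i.mean())
    p_j = arr.sum(axis=0) / (n * m)
    pe_bar = float(np.sum(p_j**2))
    if pe_bar >= 1.0:
        if p_bar >= 1.0:
            logger.info("all raters unanimous in a single category; kappa = 1 by convention")
            return 1.0
        raise ValueError("chance agreement is 1 but observed is not")  # unreachable
    if p_bar == 1.0:
        return 1.0
    return (p_bar - pe_bar) / (1.0 - pe_bar)


def two_labelling_ratings(
    a: Labelling | Mapping[str, str],
    b: Labelling | Mapping[str, str],
    categories: Sequence[str],
) -> pd.DataFrame:
    """Build a 2-rater rating table over the samples both labelings assign
    to one of ``categories`` (non-class states are excluded)."""
    sa = a.states if isinstance(a, Labelling) else dict(a)
    sb = b.states if isinstance(b, Labelling) else dict(b)
    cats = list(categories)
    cat_set = set(cats)
    common = [s for s in sa if s in sb and sa[s] in cat_set and sb[s] in cat_set]
    if not common:
        raise ValueError("no samples assigned to a category in both labelings")
    rows = np.zeros((len(common), len(cats)), dtype=int)
    idx = {c: j for j, c in enumerate(cats)}
    for i, s in enumerate(common):
        rows[i, idx[sa[s]]] += 1
        rows[i, idx[sb[s]]] += 1
    return pd.DataFrame(rows, index=common, columns=cats)


def pairwise_kappa(a: Labelling, b: Labelling) -> float:
    """Fleiss' kappa between two labelings treated as two raters.

    Restricted to samples that carry a class label in both labelings;
    INCONSISTENT/UNASSIGNED are not rated categories.
    """
    ratings = two_labelling_ratings(a, b, a.classes)
    return fleiss_kappa(ratings)


def ensemble_kappa(counts: pd.DataFrame, total_votes: pd.Series) -> float:
    """Fleiss' kappa of raw ensemble votes (raters = classifier votes).

    Only samples with the modal vote total are used, because the
    statistic requires a constant rater count; abstention-shrunk samples
    are dropped with a log message.
    """
    modal = int(total_votes.mode().iloc[0])
    keep = total_votes[total_votes == modal].index
    if len(keep) < len(total_votes):
        logger.info("ensemble kappa over %d/%d samples with %d votes each",
                    len(keep), len(total_votes), modal)
    return fleiss_kappa(counts.loc[keep])


def adjusted_rand_index(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Adjusted Rand Index between two partitions of the same samples.

    Chance-adjusted under the permutation model; 1 iff the partitions
    coincide up to label renaming, 0 expected for independent labelings.
    """
    a, b = list(labels_a), list(labels_b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same samples")
    if len(a) < 2:
        raise ValueError("need >= 2 samples")
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    n = len(a)
    sum_cells = comb(table, 2).sum()
    sum_rows = comb(table.sum(axis=1), 2).sum()
    sum_cols = comb(table.sum(axis=0), 2).sum()
    total_pairs = comb(n, 2)
    expected = sum_rows * sum_cols / total_pairs
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        # both partitions trivial (all-singletons or one block): identical -> 1
        return 1.0 if sum_cells == expected else 0.0
    return float((sum_cells - expected) / (max_index - expected))


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value onto the six conventional agreement bands."""
    if kappa > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if kappa <= 0.0:
        return KAPPA_BANDS[0][1]
    for upper, band in KAPPA_BANDS[1:]:
        if kappa <= upper + 1e-12:
            return band
    return KAPPA_BANDS[-1][1]


@dataclass
class AgreementReport:
    """Point estimates of association/agreement between two labelings."""

    cramers_v: float
    fleiss_kappa: float
    kappa_band: str
    ari: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"statistic": ["cramers_v", "fleiss_kappa", "kappa_band", "ari"],
             "value": [self.cramers_v, self.fleiss_kappa, self.kappa_band, self.ari]})


def agreement_report(
    predicted: Labelling,
    initial: Labelling,
    *,
    include_inconsistent_row: bool = True,
) -> tuple[AgreementReport, pd.DataFrame]:
    """Compare a refined labelling with its initial labelling.

    Returns the report plus a contingency table with refined labels as
    rows (including an Inconsistent row when present) and initial class
    labels as columns.  V is computed on the full table (with the
    Inconsistent row unless disabled); kappa and ARI compare only the
    samples assigned in both labelings, since the non-class states are
    not subtype categories.
    """
    classes = list(predicted.classes)
    rows = {s: v for s, v in predicted.states.items() if s in initial.states}
    cols = {s: initial.states[s] for s in rows}
    row_order = classes + ([INCONSISTENT] if INCONSISTENT in set(rows.values()) else [])
    table = contingency_table(rows, cols, row_order=row_order, col_order=classes)
    v_table = table if include_inconsistent_row else table.loc[classes]
    v = cramers_v(v_table)
    kappa = pairwise_kappa(predicted, initial)
    both = [s for s in rows
            if rows[s] in predicted.classes and cols[s] in predicted.classes]
    ari = adjusted_rand_index([rows[s] for s in both], [cols[s] for s in both])
    return AgreementReport(v, kappa, interpret_kappa(kappa), ari), table
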