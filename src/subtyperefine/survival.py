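"""Kaplan-Meier curves, the K-group log-rank test and clinical marker summaries.

Both survival procedures are implemented from their defining formulas:
the product-limit estimator S(t) = prod_{t_j <= t} (1 - d_j / n_j), and
the K-sample log-rank statistic (O - E)' V^{-1} (O - E) over K-1 groups
with the hypergeometric covariance of event counts at each distinct
event time, referred to a chi-square with K-1 degrees of freedom.

Ties between events and censorings at the same time follow the standard
convention: censored subjects leave the risk set *after* the events at
that time are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ClinicalTable, Labelling

logger = logging.getLogger(__name__)


@dataclass
class KmCurve:
    """A product-limit survival curve over the distinct event times."""

    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # risk-set size just before each event time
    events: np.ndarray       # deaths at each event time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "events": self.events})


def km_curve(times: Sequence[float], events: Sequence[int]) -> KmCurve:
    """Kaplan-Meier estimate from times and event flags (1 = death, 0 = censored)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    deaths = []
    s = 1.0
    for tj in event_times:
        nj = int(np.sum(t >= tj))          # censored at tj still at risk
        dj = int(np.sum((t == tj) & (e == 1)))
        s *= 1.0 - dj / nj
        at_risk.append(nj)
        deaths.append(dj)
        surv.append(s)
    return KmCurve(event_times, np.array(surv), np.array(at_risk, dtype=int),
                   np.array(deaths, dtype=int))


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]],
) -> tuple[float, int, float]:
    """K-group log-rank test.

    Parameters
    ----------
    groups : list of (times, events) pairs, one per stratum.

    Returns
    -------
    (chi2 statistic, degrees of freedom, p-value).  With no events in
    any group the statistic is 0 and p = 1 (logged as a warning).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    times_list = [np.asarray(t, dtype=float) for t, _ in groups]
    events_list = [np.asarray(e, dtype=int) for _, e in groups]
    for t in times_list:
        if t.size == 0:
            raise ValueError("empty group in log-rank test")
    all_t = np.concatenate(times_list)
    all_e = np.concatenate(events_list)
    df = k - 1
    event_times = np.unique(all_t[all_e == 1])
    if event_times.size == 0:
        logger.warning("no events in any group; log-rank statistic 0")
        return 0.0, df, 1.0
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for tj in event_times:
        n_ij = np.array([np.sum(t >= tj) for t in times_list], dtype=float)
        d_ij = np.array([np.sum((t == tj) & (e == 1))
                         for t, e in zip(times_list, events_list)], dtype=float)
        nj = n_ij.sum()
        dj = d_ij.sum()
        observed += d_ij
        expected += dj * n_ij / nj
        if nj > 1:
            # hypergeometric covariance of the event split at tj
            factor = dj * (nj - dj) / (nj - 1)
            cov += factor * (np.diag(n_ij / nj) - np.outer(n_ij, n_ij) / nj**2)
    z = (observed - expected)[:df]
    v = cov[:df, :df]
    try:
        stat = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(v) @ z)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def logrank_by_label(
    labelling: Labelling | Mapping[str, str],
    clinical: ClinicalTable,
    *,
    min_group_size: int = 1,
) -> tuple[float, int, float]:
    """Log-rank test of survival curves stratified by class label."""
    states = labelling.assigned() if isinstance(labelling, Labelling) else dict(labelling)
    surv = clinical.survival()
    groups = []
    for cls in sorted(set(states.values())):
        ids = [s for s, v in states.items() if v == cls and s in surv.index]
        if len(ids) >= min_group_size and ids:
            sub = surv.loc[ids]
            groups.append((sub["time"].to_numpy(), sub["event"].to_numpy()))
    return logrank_test(groups)


@dataclass
class MarkerSummary:
    """Per-class counts of positive/negative/unknown status for each marker."""

    table: pd.DataFrame  # index: class; columns: (marker, status)

    def to_frame(self) -> pd.DataFrame:
        flat = self.table.copy()
        flat.columns = [f"{m}{s}" for m, s in flat.columns]
        return flat


def marker_summary(
    labelling: Labelling,
    clinical: ClinicalTable,
    *,
    include_inconsistent: bool = True,
) -> MarkerSummary:
    """Count ER/PR/HER2 +/-/unknown per class (and Inconsistent when present).

    Samples without clinical annotation are ignored; a missing marker is
    counted as unknown so per-class totals are conserved.
    """
    from .io_core import INCONSISTENT

    states = dict(labelling.states)
    classes = list(labelling.classes)
    if include_inconsistent and INCONSISTENT in states.values():
        classes = classes + [INCONSISTENT]
    markers = ClinicalTable.MARKERS
    statuses = ("+", "-", "unknown")
    columns = pd.MultiIndex.from_product([markers, statuses])
    out = pd.DataFrame(0, index=classes, columns=columns, dtype=int)
    clin = clinical.table
    for sid, cls in states.items():
        if cls not in out.index or sid not in clin.index:
            continue
        for m in markers:
            out.loc[cls, (m, clin.loc[sid, m])] += 1
    return MarkerSummary(out)
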