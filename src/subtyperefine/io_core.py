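"""Tabular I/O and sample/probe alignment.

The pipeline reads three flat TSV formats:

* expression: probes as rows, samples as columns, header row of sample
  ids, first column of probe ids, body numeric (log-scale intensities);
* labels: two columns ``sample_id``, ``label``;
* clinical: columns ``sample_id``, ``er``, ``pr``, ``her2``, ``time``,
  ``event``.

All in-memory containers are thin, validated wrappers around pandas
objects so downstream modules can rely on their invariants (unique
identifiers, finite values, every sample labelled exactly once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five breast cancer intrinsic subtypes, in the conventional order.
DEFAULT_CLASSES: tuple[str, ...] = ("LumA", "LumB", "Her2", "Basal", "Normal")

#: Fixed, case-sensitive tokens for the two non-class sample states.
INCONSISTENT = "INCONSISTENT"
UNASSIGNED = "UNASSIGNED"


class DataError(ValueError):
    """Raised when an input file or container violates a format invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A probes x samples matrix of log-scale expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric frame with probe ids as the index and sample ids as the
        columns.  All values must be finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "probe")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                "non-finite expression value at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise DataError(f"unknown sample identifiers: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise DataError(f"unknown probe identifiers: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(probe_ids), :])


@dataclass
class Labelling:
    """Per-sample subtype state.

    Each sample is in exactly one state: a class label from ``classes``,
    ``INCONSISTENT`` (the ensemble failed to reach consensus) or
    ``UNASSIGNED`` (not yet classified / train-test rejection).
    """

    states: dict[str, str]
    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        _check_unique(list(self.classes), "class")
        valid = set(self.classes) | {INCONSISTENT, UNASSIGNED}
        for sid, state in self.states.items():
            if state not in valid:
                raise DataError(f"unknown label {state!r} for sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.states)

    def state_of(self, sample_id: str) -> str:
        return self.states[sample_id]

    def assigned(self) -> dict[str, str]:
        """Samples currently carrying a class label (not INCONSISTENT/UNASSIGNED)."""
        cls = set(self.classes)
        return {s: v for s, v in self.states.items() if v in cls}

    def samples_in_state(self, state: str) -> list[str]:
        return [s for s, v in self.states.items() if v == state]

    def class_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in self.classes}
        for v in self.states.values():
            if v in sizes:
                sizes[v] += 1
        return sizes

    def subset(self, sample_ids: Sequence[str]) -> "Labelling":
        return Labelling({s: self.states[s] for s in sample_ids}, self.classes)

    def replace(self, updates: Mapping[str, str]) -> "Labelling":
        new = dict(self.states)
        for s, v in updates.items():
            if s not in new:
                raise DataError(f"cannot update unknown sample {s!r}")
            new[s] = v
        return Labelling(new, self.classes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Labelling):
            return NotImplemented
        return self.states == other.states and self.classes == other.classes

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation: ER/PR/HER2 status and survival.

    Marker status is one of ``"+"``, ``"-"`` or ``"unknown"``.  Survival
    time (days) and the event flag (1 = death observed, 0 = censored)
    are present together or absent together.
    """

    table: pd.DataFrame  # index sample_id; columns er, pr, her2, time, event
    MARKERS = ("er", "pr", "her2")

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index), "sample")
        for col in ("er", "pr", "her2"):
            bad = set(self.table[col].unique()) - {"+", "-", "unknown"}
            if bad:
                raise DataError(f"invalid {col} status values: {sorted(bad)}")
        has_time = self.table["time"].notna()
        has_event = self.table["event"].notna()
        if (has_time != has_event).any():
            sid = self.table.index[(has_time != has_event)][0]
            raise DataError(
                f"sample {sid!r}: survival time and event flag must be present together"
            )
        times = self.table.loc[has_time, "time"]
        if (times < 0).any():
            raise DataError("negative survival time")
        events = set(self.table.loc[has_event, "event"].astype(int).unique())
        if events - {0, 1}:
            raise DataError(f"event flag must be 0/1, got {sorted(events)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def survival(self, sample_ids: Iterable[str] | None = None) -> pd.DataFrame:
        """Return (time, event) rows for samples with survival data."""
        t = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        t = t[t["time"].notna()]
        return pd.DataFrame(
            {"time": t["time"].astype(float), "event": t["event"].astype(int)},
            index=t.index,
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path, *, impute_missing: bool = False) -> ExpressionMatrix:
    """Read a probes x samples TSV expression matrix.

    By default any missing or non-numeric cell is a hard error reported
    with its coordinates.  With ``impute_missing=True`` missing cells are
    filled with the per-probe median (the choice is logged).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(list(df.index), "probe")
    _check_unique(list(df.columns), "sample")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric cell {df.iat[i, j]!r} at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        if not impute_missing:
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise DataError(
                f"missing expression value at probe {numeric.index[i]!r}, "
                f"sample {numeric.columns[j]!r} in {path} "
                "(pass impute_missing=True to enable per-probe median imputation)"
            )
        n_missing = int(numeric.isna().to_numpy().sum())
        medians = numeric.median(axis=1)
        numeric = numeric.apply(lambda row: row.fillna(medians[row.name]), axis=1)
        logger.warning("imputed %d missing cells with per-probe medians", n_missing)
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_labelling(path, classes: Sequence[str] = DEFAULT_CLASSES) -> Labelling:
    """Read a two-column (sample_id, label) TSV into a :class:`Labelling`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"label file {path} needs columns sample_id, label")
    sample_col, label_col = df.columns[:2]
    states: dict[str, str] = {}
    for sid, lab in zip(df[sample_col], df[label_col]):
        if sid in states:
            raise DataError(f"sample {sid!r} repeated in {path}")
        states[sid] = lab
    return Labelling(states, tuple(classes))


def write_labelling(labelling: Labelling, path) -> None:
    pd.DataFrame(
        {"sample_id": labelling.sample_ids,
         "label": [labelling.states[s] for s in labelling.sample_ids]}
    ).to_csv(path, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "er", "pr", "her2", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"clinical file {path} missing columns {missing}")
    _check_unique(list(df["sample_id"]), "sample")
    out = df.set_index("sample_id")[["er", "pr", "her2", "time", "event"]].copy()
    for col in ("er", "pr", "her2"):
        out[col] = out[col].fillna("unknown")
    out["time"] = pd.to_numeric(out["time"], errors="raise")
    out["event"] = pd.to_numeric(out["event"], errors="raise")
    return ClinicalTable(out)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id")


def align(
    matrix: ExpressionMatrix, labelling: Labelling
) -> tuple[ExpressionMatrix, Labelling]:
    """Restrict both inputs to the intersection of their sample ids.

    The intersection keeps the matrix's column order.  An empty
    intersection is a hard error; the intersection size is logged.
    """
    label_ids = set(labelling.sample_ids)
    common = [s for s in matrix.sample_ids if s in label_ids]
    if not common:
        raise DataError("expression matrix and labelling share no samples")
    logger.info(
        "aligned %d common samples (matrix %d, labelling %d)",
        len(common), len(matrix.sample_ids), len(labelling),
    )
    if len(common) == len(matrix.sample_ids) == len(labelling):
        return matrix, labelling
    return matrix.subset_samples(common), labelling.subset(common)
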