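"""Synthetic microarray-like datasets with planted subtype structure.

The generator emulates the statistical structure the refinement pipeline
assumes in real intrinsic-subtype data:

* five latent classes with imbalanced sample counts (the smallest class
  deliberately small, echoing the normal-like group);
* per-class disjoint blocks of planted up- and down-regulated probes,
  shifted by +/- delta*sigma on a Normal(0, sigma^2) log-intensity
  background;
* an initial labelling corrupted by reassigning an exact fraction of
  samples to a uniformly random *different* class (mimicking single
  sample predictor mislabelling, which always outputs a subtype);
* class-conditional ER/PR/HER2 marker probabilities;
* class-dependent exponential survival hazards with independent
  exponential censoring.

Everything is driven by a single seed and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ClinicalTable, ExpressionMatrix, Labelling

# class-conditional P(marker positive) and P(marker unknown), loosely
# following the expected receptor patterns: luminal ER+/PR+, HER2-enriched
# HER2+, basal triple-negative, normal-like mixed.
DEFAULT_MARKER_PROBS: dict[str, dict[str, float]] = {
    "LumA":   {"er": 0.95, "pr": 0.75, "her2": 0.05},
    "LumB":   {"er": 0.90, "pr": 0.60, "her2": 0.15},
    "Her2":   {"er": 0.20, "pr": 0.10, "her2": 0.80},
    "Basal":  {"er": 0.05, "pr": 0.05, "her2": 0.05},
    "Normal": {"er": 0.60, "pr": 0.45, "her2": 0.15},
}

# exponential death hazards per day; ordering reflects the usual
# prognosis gradient (luminal A best, basal-like/HER2-enriched worst)
DEFAULT_HAZARDS: dict[str, float] = {
    "LumA": 1.0 / 6000.0,
    "LumB": 1.0 / 3000.0,
    "Her2": 1.0 / 1500.0,
    "Basal": 1.0 / 1200.0,
    "Normal": 1.0 / 4000.0,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    n_probes : total probe count.
    class_sizes : samples per class; default is imbalanced with a small
        minimum class, echoing a realistic cohort.
    n_up, n_down : planted up-/down-regulated probes per class (disjoint
        across classes and directions).
    effect_size : shift of planted probes in units of the background sd.
    noise_sd : background standard deviation sigma.
    corruption_rate : exact fraction of samples whose initial label is
        reassigned to a random different class.
    marker_probs : class-conditional P(marker positive) for er/pr/her2.
    marker_unknown_prob : probability a marker status is missing.
    hazards : per-class exponential death hazard (per day).
    censoring_hazard : hazard of the independent exponential censoring time.
    seed : drives every random draw.
    """

    n_probes: int = 1000
    class_sizes: dict[str, int] = field(default_factory=lambda: {
        "LumA": 250, "LumB": 200, "Her2": 90, "Basal": 90, "Normal": 58})
    n_up: int = 5
    n_down: int = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    corruption_rate: float = 0.10
    marker_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARKER_PROBS.items()})
    marker_unknown_prob: float = 0.02
    hazards: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    censoring_hazard: float = 1.0 / 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.corruption_rate < 1.0):
            raise ValueError("corruption_rate must be in [0, 1)")
        if any(n <= 0 for n in self.class_sizes.values()):
            raise ValueError("all class sizes must be positive")
        needed = len(self.class_sizes) * (self.n_up + self.n_down)
        if needed > self.n_probes:
            raise ValueError(
                f"planted probes ({needed}) exceed n_probes ({self.n_probes})")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.class_sizes)

    @property
    def n_samples(self) -> int:
        return sum(self.class_sizes.values())


@dataclass
class SyntheticDataset:
    """One generated dataset plus its ground truth."""

    matrix: ExpressionMatrix
    truth: Labelling
    initial: Labelling           # corrupted labelling handed to the pipeline
    clinical: ClinicalTable
    planted: dict[str, dict[str, list[str]]]  # class -> {"up": [...], "down": [...]}
    spec: GeneratorSpec

    def planted_probes(self) -> list[str]:
        out: list[str] = []
        for cls in self.planted:
            out.extend(self.planted[cls]["up"])
            out.extend(self.planted[cls]["down"])
        return out


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Draw one :class:`SyntheticDataset` according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.classes)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    probe_ids = [f"P{i:05d}" for i in range(spec.n_probes)]

    # true class per sample, in class blocks
    y = np.concatenate([[c] * spec.class_sizes[c] for c in classes])

    # background + planted blocks
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_probes, n))
    planted: dict[str, dict[str, list[str]]] = {}
    cursor = 0
    shift = spec.effect_size * spec.noise_sd
    for c in classes:
        up = list(range(cursor, cursor + spec.n_up))
        cursor += spec.n_up
        down = list(range(cursor, cursor + spec.n_down))
        cursor += spec.n_down
        in_c = np.flatnonzero(y == c)
        values[np.ix_(up, in_c)] += shift
        values[np.ix_(down, in_c)] -= shift
        planted[c] = {"up": [probe_ids[i] for i in up],
                      "down": [probe_ids[i] for i in down]}

    matrix = ExpressionMatrix(pd.DataFrame(values, index=probe_ids,
                                           columns=sample_ids))
    truth = Labelling(dict(zip(sample_ids, y)), tuple(classes))

    # corrupted initial labelling: exactly round(rho * n) samples flipped
    n_corrupt = int(round(spec.corruption_rate * n))
    corrupt_idx = rng.choice(n, size=n_corrupt, replace=False)
    initial_states = dict(truth.states)
    for i in corrupt_idx:
        others = [c for c in classes if c != y[i]]
        initial_states[sample_ids[i]] = others[rng.integers(len(others))]
    initial = Labelling(initial_states, tuple(classes))

    # clinical markers and survival
    rows = []
    for sid, cls in zip(sample_ids, y):
        probs = spec.marker_probs[cls]
        status = {}
        for m in ("er", "pr", "her2"):
            if rng.random() < spec.marker_unknown_prob:
                status[m] = "unknown"
            else:
                status[m] = "+" if rng.random() < probs[m] else "-"
        death = rng.exponential(1.0 / spec.hazards[cls])
        censor = rng.exponential(1.0 / spec.censoring_hazard)
        time = min(death, censor)
        event = int(death <= censor)
        rows.append((sid, status["er"], status["pr"], status["her2"], time, event))
    clin = pd.DataFrame(rows, columns=["sample_id", "er", "pr", "her2",
                                       "time", "event"]).set_index("sample_id")
    clinical = ClinicalTable(clin)

    return SyntheticDataset(matrix, truth, initial, clinical, planted, spec)


def split_discovery_validation(
    dataset: SyntheticDataset, validation_fraction: float = 0.4, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified (by true class) split of sample ids into discovery and
    validation subsets, mirroring a two-cohort study design."""
    if not (0.0 < validation_fraction < 1.0):
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    discovery: list[str] = []
    validation: list[str] = []
    for c in dataset.truth.classes:
        ids = [s for s, v in dataset.truth.states.items() if v == c]
        k = int(round(validation_fraction * len(ids)))
        pick = set(rng.choice(len(ids), size=k, replace=False).tolist())
        for i, s in enumerate(ids):
            (validation if i in pick else discovery).append(s)
    return discovery, validation
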