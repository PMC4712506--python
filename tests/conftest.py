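"""Shared fixtures: small planted datasets and reduced rosters."""

import numpy as np
import pandas as pd
import pytest

from subtyperefine import (
    ClassifierRoster,
    ExpressionMatrix,
    GeneratorSpec,
    Labelling,
    build_roster,
    generate,
)


@pytest.fixture(scope="session")
def tiny_roster() -> ClassifierRoster:
    """Three quick, deterministic members spanning three families."""
    return build_roster([
        {"member_id": "gnb", "algorithm": "gaussian_nb"},
        {"member_id": "lda", "algorithm": "lda"},
        {"member_id": "knn3", "algorithm": "knn", "params": {"n_neighbors": 3}},
    ])


@pytest.fixture(scope="session")
def memorizer_roster() -> ClassifierRoster:
    """A 1-nearest-neighbour pair: memorizes its training set exactly."""
    return build_roster([
        {"member_id": "knn1a", "algorithm": "knn", "params": {"n_neighbors": 1}},
        {"member_id": "knn1b", "algorithm": "knn", "params": {"n_neighbors": 1}},
    ])


@pytest.fixture(scope="session")
def small_dataset():
    """A well-separated 5-class dataset, 200 probes x 75 samples."""
    spec = GeneratorSpec(
        n_probes=200,
        class_sizes={"LumA": 20, "LumB": 20, "Her2": 13, "Basal": 12, "Normal": 10},
        effect_size=3.0,
        corruption_rate=0.10,
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def clean_dataset():
    """Same structure but with uncorrupted initial labels (a fixed point)."""
    spec = GeneratorSpec(
        n_probes=200,
        class_sizes={"LumA": 12, "LumB": 12, "Her2": 12, "Basal": 12, "Normal": 12},
        effect_size=4.0,
        corruption_rate=0.0,
        seed=5,
    )
    return generate(spec)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 probes x 6 samples; P1 cleanly separates the last three samples."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 7.0, 8.0, 9.0],
         rng.normal(0, 1, 6),
         rng.normal(0, 1, 6)],
        index=["P1", "P2", "P3"],
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def toy_labelling() -> Labelling:
    return Labelling(
        {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}, classes=("A", "B")
    )
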