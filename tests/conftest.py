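import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xrrmeta.data import MetaDataset, StudyCounts

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def worked_example() -> MetaDataset:
    """The two-study unbalanced dataset used for hand-checked resampling."""
    return MetaDataset.from_studies(
        [
            StudyCounts(2, 80, 1, 50, "study1"),
            StudyCounts(1, 100, 0, 90, "study2"),
        ]
    )


@pytest.fixture
def balanced_dataset() -> MetaDataset:
    """Six balanced studies with sparse counts."""
    pairs = [(0, 2), (1, 3), (2, 1), (0, 1), (4, 2), (1, 1)]
    return MetaDataset.from_studies(
        [StudyCounts(y1, 100, y2, 100, f"s{i}") for i, (y1, y2) in enumerate(pairs)]
    )


@pytest.fixture
def unbalanced_dataset() -> MetaDataset:
    """Eight studies with mixed imbalance directions and sparse counts."""
    rows = [
        (2, 80, 1, 50),
        (1, 100, 0, 90),
        (0, 60, 2, 120),
        (3, 200, 1, 100),
        (1, 50, 1, 50),
        (0, 150, 1, 75),
        (2, 90, 2, 180),
        (1, 120, 0, 120),
    ]
    return MetaDataset.from_studies(
        [StudyCounts(*row, label=f"u{i}") for i, row in enumerate(rows)]
    )


@pytest.fixture
def symmetric_dataset() -> MetaDataset:
    """Balanced studies with y1 = y2, symmetric under arm exchange."""
    pairs = [(1, 1), (2, 2), (0, 0), (3, 3), (1, 1), (2, 2)]
    studies = []
    for i, (y1, y2) in enumerate(pairs):
        if y1 + y2 == 0:
            continue
        studies.append(StudyCounts(y1, 100, y2, 100, f"sym{i}"))
    return MetaDataset.from_studies(studies)


def random_study(rng: np.random.Generator) -> StudyCounts:
    n1 = int(rng.integers(1, 200))
    n2 = int(rng.integers(1, 200))
    y1 = int(rng.integers(0, min(n1, 12) + 1))
    y2 = int(rng.integers(0, min(n2, 12) + 1))
    if y1 + y2 == 0:
        y1 = 1
    return StudyCounts(y1, n1, y2, n2, "rand")
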