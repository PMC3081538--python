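import numpy as np
import pytest

from mitosweep import FeatureTable, PredictorProfile, ScenarioConfig


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 proteins x 2 tools, no missing cells."""
    return FeatureTable(
        protein_ids=["P1", "P2", "P3"],
        labels=np.array([1, 0, 1], dtype=np.int8),
        tool_names=["toolA", "toolB"],
        values=np.array([[1.0, 0.25], [0.0, 0.5], [1.0, 0.75]]),
    )


@pytest.fixture
def separable_table() -> FeatureTable:
    """1-D, positives at 1.0 and negatives at 0.0: trivially separable."""
    n = 40
    labels = np.array([1, 0] * (n // 2), dtype=np.int8)
    return FeatureTable(
        protein_ids=[f"P{i}" for i in range(n)],
        labels=labels,
        tool_names=["perfect"],
        values=labels.astype(float)[:, None],
    )


@pytest.fixture
def three_tool_config() -> ScenarioConfig:
    """Small scenario with a perfect, a random and a weak tool."""
    return ScenarioConfig(
        profiles=(
            PredictorProfile("perfect", tpr=1.0, fpr=0.0),
            PredictorProfile("coin", tpr=0.5, fpr=0.5),
            PredictorProfile("weak", tpr=0.3, fpr=0.1, coverage=0.8, noise_sd=0.1),
        ),
        n_pos=40,
        n_neg=160,
        seed=7,
    )
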