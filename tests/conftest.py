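import numpy as np
import pandas as pd
import pytest

from hfrisk import Expert, InfluenceAssessment, SynthConfig, generate_case


def labeled(values, labels=None):
    """Square labeled DataFrame from a nested list."""
    a = np.asarray(values)
    labels = labels or [f"ED{i + 1}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=labels, columns=labels)


@pytest.fixture
def two_experts():
    return [Expert("A", "infection", 2), Expert("B", "infection", 1)]


@pytest.fixture
def small_case():
    """Deterministic small synthetic case shared across tests."""
    return generate_case(
        SynthConfig(
            n_departments=6,
            n_infection_experts=3,
            n_managerial_experts=3,
            n_criteria=4,
            seed=42,
        )
    )


@pytest.fixture
def random_direct_relation():
    """Factory for random non-negative direct-relation matrices."""

    def make(n, seed, scale=4.0):
        rng = np.random.default_rng(seed)
        z = rng.uniform(0, scale, size=(n, n))
        np.fill_diagonal(z, 0.0)
        return labeled(z)

    return make
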