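import numpy as np
import pytest

import stressidx as sx


@pytest.fixture
def toy_trial() -> sx.TrialTable:
    """Two genotypes with hand-checkable index values (Ȳp=4, Ȳs=2)."""
    return sx.TrialTable(("A", "B"), np.array([4.0, 4.0]), np.array([1.0, 3.0]))


@pytest.fixture
def trial20() -> sx.TrialTable:
    """Seeded 20-genotype synthetic trial."""
    return sx.generate_trial(n=20, seed=42)


@pytest.fixture
def indices20(trial20) -> sx.IndexTable:
    return sx.compute_indices(trial20)
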