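import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bimodalgene.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-gene, 120-sample cohort with all planted shape classes."""
    spec = CohortSpec(
        n_genes=300,
        n_samples=120,
        frac_balanced=0.1,
        frac_unbalanced=0.1,
        frac_outlier=0.1,
        frac_heavy=0.1,
        n_prognostic=8,
        seed=42,
    )
    matrix, survival, truth = simulate_cohort(spec)
    return spec, matrix, survival, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
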