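import numpy as np
import pytest

from chromdyn import simulate_genome, simulate_timecourses

TIMES = np.array([0, 20, 60, 120, 240, 1440], dtype=float)


@pytest.fixture(scope="session")
def scaffold_small():
    return simulate_genome(
        length=2_000_000, n_fragments=300, n_genes=15, n_peaks=60, seed=1
    )


@pytest.fixture(scope="session")
def sim_small(scaffold_small):
    return simulate_timecourses(
        scaffold_small, dyn_fraction=0.5, replicates=2, seed=2
    )


@pytest.fixture
def times():
    return TIMES.copy()
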