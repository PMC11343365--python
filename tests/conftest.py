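import numpy as np
import pytest
from hypothesis import settings

import pbulk

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """20 subjects x ~10 cells x 60 genes with subject-level heterogeneity
    and NB cell noise; shared by tests that only need 'some data'."""
    cfg = pbulk.SimConfig(
        n_subjects=20,
        mean_cells_per_subject=10,
        n_genes=60,
        random_intercept_sd=0.5,
        nb_dispersion=0.3,
        seed=42,
    )
    counts, design, truth = pbulk.simulate_dataset(cfg)
    sf = pbulk.compute_cell_size_factors(counts)
    pb = pbulk.aggregate(counts, sf, design)
    return {"counts": counts, "design": design, "truth": truth, "sf": sf, "pb": pb}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
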