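import numpy as np
import pytest

from txgrad import synthetic
from txgrad.pipeline import analyze_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_spec():
    """A fast cohort: 3 donors, 10 parcels, 60 genes."""
    return synthetic.SimulationSpec(
        n_donors=3,
        samples_per_donor=40,
        n_genes=60,
        probes_per_gene=2,
        n_step=5,
        n_smooth=5,
        n_mirror=5,
        n_parcels=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort run once per session (~1 s)."""
    return analyze_cohort(synthetic.SimulationSpec(seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return analyze_cohort(small_spec)
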