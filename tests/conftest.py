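import numpy as np
import pytest

from deepeye import simulate


@pytest.fixture(scope="session")
def small_panel():
    """Structured 3-species panel, 60 samples, 2,000 sites on one 2-Mb chromosome."""
    spec = simulate.SimPanelSpec(
        seed=11,
        n_species=3,
        samples_per_species=20,
        n_sites=2000,
        chrom_lengths={"chr1": 2_000_000},
        fst=0.1,
    )
    panel, sites = simulate.simulate_structured_panel(spec)
    return panel, sites


@pytest.fixture(scope="session")
def tiny_panel():
    """Two species x 3 samples, 50 sites: small enough for file round trips."""
    spec = simulate.SimPanelSpec(
        seed=7,
        n_species=2,
        samples_per_species=3,
        n_sites=50,
        chrom_lengths={"chr1": 100_000},
        fst=0.05,
    )
    panel, sites = simulate.simulate_structured_panel(spec)
    return panel, sites


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
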