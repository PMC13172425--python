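import numpy as np
import pytest

import chemoprofiler as cp


@pytest.fixture(scope="session")
def design():
    return cp.default_design()


@pytest.fixture(scope="session")
def small_panel():
    """4 planted members + 20 background proteins."""
    return cp.default_protein_panel(n_members=4, n_background=20, seed=11)


@pytest.fixture(scope="session")
def noiseless_table(design, small_panel):
    df = cp.generate_competition_dataset(design, small_panel, noise_cv=0.0, seed=0)
    return cp.ReporterIntensityTable(df, design)


@pytest.fixture(scope="session")
def noisy_table(design, small_panel):
    df = cp.generate_competition_dataset(design, small_panel, noise_cv=0.1, seed=5)
    return cp.ReporterIntensityTable(df, design)


@pytest.fixture(scope="session")
def toy_spec():
    return cp.PlantedInterfaceSpec(
        chain_lengths=(6, 7),
        true_contact_pairs=frozenset({(3, 2), (5, 6)}),
        interface_distance=5.0,
        background_distance=20.0,
        pae_interface=5.0,
        pae_background=28.0,
        prob_interface=0.9,
        prob_background=0.0,
    )


@pytest.fixture(scope="session")
def toy(toy_spec):
    return cp.generate_toy_complex(toy_spec, seed=0)


@pytest.fixture(scope="session")
def metric_table():
    return cp.generate_af_metric_table(34, {"OGT", "WDR5"}, n_models=5, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
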