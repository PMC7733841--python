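import warnings

import numpy as np
import pytest

import axialfil as af


@pytest.fixture(scope="session")
def p3121():
    return af.get_space_group("P3121")


@pytest.fixture(scope="session")
def toy_model():
    """Default toy asymmetric unit with the planted triad."""
    return af.make_toy_crystal(af.ToyCrystalSpec(seed=1, include_triad=True))


@pytest.fixture(scope="session")
def toy_expanded(toy_model, p3121):
    return af.expand_to_p1(toy_model, p3121)


@pytest.fixture(scope="session")
def toy_hybrid(toy_expanded):
    """Toy cell packed with silica (exclusion scaled to the half-size cell)."""
    config = af.FillConfig(protein_exclusion=0.2, seed=5)
    model, report = af.pack_silica(toy_expanded, config)
    return model, report, config


@pytest.fixture(scope="session")
def toy_sim_001(toy_hybrid):
    model, _, _ = toy_hybrid
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return af.simulate_zone_axis(model, "001", af.MicroscopeParams(), 0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
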