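import numpy as np
import pytest

from pmfrich import fixture_gen
from pmfrich.units import KB

TEMPERATURE = 300.0
KT = KB * TEMPERATURE
BETA = 1.0 / KT


@pytest.fixture(scope="session")
def helix_ensemble():
    """200 backbone chains with wrapped-Gaussian torsions around the ideal
    α-helix (Φ=−57°, Ψ=−47°, σ=15°)."""
    return fixture_gen.make_torsion_ensemble(
        400, {"phi": -57.0, "psi": -47.0}, 15.0, seed=42)


@pytest.fixture(scope="session")
def double_well_chain():
    return fixture_gen.make_toy_chain(5, preset="double_well", barrier_kT=8.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
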