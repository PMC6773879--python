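import numpy as np
import pytest

from protrack.tables import build_tables, medium_by_name
from protrack.toy import generate_toy_medium


@pytest.fixture(scope="session")
def toy():
    """Single-process analytic medium with closed-form SP/IMFP/range."""
    medium, tab = generate_toy_medium()
    return medium, tab


@pytest.fixture(scope="session")
def water_tables():
    """Production-fidelity water tables, built once per session."""
    return build_tables(medium_by_name("water"), n_eta=18, n_mid=44)


@pytest.fixture(scope="session")
def dna_tables():
    """Hydrated-DNA tables, same quadrature as the water set (media
    comparisons must not carry asymmetric quadrature bias)."""
    return build_tables(medium_by_name("dna"), n_eta=18, n_mid=44)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
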