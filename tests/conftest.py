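import pytest

from homtm import (
    ExpectedPTM,
    PTMTable,
    Proteoform,
    two_site_acetylation_example,
    simulate_spectrum,
)


@pytest.fixture(scope="session")
def default_table():
    return PTMTable.default()


@pytest.fixture(scope="session")
def acetyl_k_table():
    """Single-PTM table: acetylation on lysine only."""
    return PTMTable([ExpectedPTM("Acetylation", 42.01056, frozenset("K"))])


@pytest.fixture(scope="session")
def diacetyl_example():
    """Noiseless 70:30 diacetyl mixture spectrum of GKGKLKAKE with truth."""
    cfg = two_site_acetylation_example(seed=1)
    spectrum, truth = simulate_spectrum(cfg)
    return cfg, spectrum, truth
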