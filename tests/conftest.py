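import pytest

from bonesnp.core import make_panel
from bonesnp.simulate import sample_frequencies, sample_genotype


@pytest.fixture(scope="session")
def panel():
    """Full-size identity panel: 90 autosomal + 34 Y loci."""
    return make_panel(90, 34, seed=1)


@pytest.fixture(scope="session")
def small_panel():
    return make_panel(6, 2, seed=7)


@pytest.fixture(scope="session")
def freqs(panel):
    return sample_frequencies(panel, seed=2)


@pytest.fixture(scope="session")
def small_freqs(small_panel):
    return sample_frequencies(small_panel, seed=8)


@pytest.fixture(scope="session")
def donor(panel, freqs):
    return sample_genotype(freqs, panel, seed=3, sample_id="donor")
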