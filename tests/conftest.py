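import numpy as np
import pytest

from cmlcite import synthetic as syn
from cmlcite.projection import build_reference


@pytest.fixture(scope="session")
def profiles():
    return syn.default_reference_profiles()


@pytest.fixture(scope="session")
def lsc_signature():
    return syn.default_signature()


@pytest.fixture(scope="session")
def reference_2000(profiles):
    """Full-size synthetic reference: 11 clusters, 2000 cells."""
    rna, adt, truth = syn.generate_reference(profiles, 2000, seed=1)
    return rna, adt, truth


@pytest.fixture(scope="session")
def reference_model(reference_2000):
    rna, _, truth = reference_2000
    return build_reference(rna, truth.cells["cluster"])


@pytest.fixture(scope="session")
def query_1000(profiles):
    """Query sample drawn from the same generative model as the reference."""
    rna, adt, truth = syn.generate_reference(profiles, 1000, seed=2,
                                             cell_prefix="query")
    return rna, adt, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
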