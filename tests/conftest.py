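import pytest

from mspa import example


@pytest.fixture(scope="session")
def models():
    """Gene models of the bundled two-gene worked example."""
    return example.gene_models()


@pytest.fixture(scope="session")
def pspas():
    """The four curated PSpAs (W, X, Y, Z) of the worked example."""
    return example.pspa_set()


@pytest.fixture(scope="session")
def reference(models):
    """The five-multiblock reference MSpA of the worked example."""
    return example.reference_mspa()
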