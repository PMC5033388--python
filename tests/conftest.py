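import pytest

from complexfold import load_energy_model


@pytest.fixture(scope="session")
def model():
    """Turner-04 style parameters at 37 C: the default folding model."""
    return load_energy_model("turner04", 37.0)


@pytest.fixture(scope="session")
def model_zero(model):
    """Same conformational rules, every free energy forced to zero."""
    return model.zeroed()


@pytest.fixture(scope="session")
def kissing_strands():
    """Two 12-nt hairpin formers whose 4-nt loops are complementary.

    Each strand closes a 4-bp stem around an AAAA/UUUU loop; the loops can
    kiss through an intermolecular helix, the classic dimerization motif.
    """
    return "GGCGAAAACGCC", "GCGGUUUUCCGC"
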