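import pytest

from phostime import (ModelSpec, PhysiologicalParameters, build_generator,
                      derive_rates)


@pytest.fixture(scope="session")
def phys():
    return PhysiologicalParameters()


@pytest.fixture(scope="session")
def derivation_and_rates(phys):
    return derive_rates(phys)


@pytest.fixture(scope="session")
def kin(derivation_and_rates):
    """Kinetic rates derived from the default physiological parameters."""
    return derivation_and_rates[1]


@pytest.fixture(scope="session")
def ip23(kin):
    """IP generator at the 1 pM setting (n_R=232, n_L=23)."""
    spec = ModelSpec(kind="IP", n_R=232, n_L=23)
    return build_generator(spec, kin)


@pytest.fixture(scope="session")
def dp23(kin):
    """DP generator at the 1 pM setting (n_R=232, n_L=23)."""
    spec = ModelSpec(kind="DP", n_R=232, n_L=23)
    return build_generator(spec, kin)
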