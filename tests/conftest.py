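import warnings

import pytest

from hcrforge import (
    DesignConfig,
    MIR21,
    LET7_PANEL,
    build_basic_pair,
    load_default_params,
    nupack_calibrated,
)

# printed worked-example strings (case as displayed: toehold/loop upper)
HR1 = "TCAACAtcagtctgataagctaCAAAGTtagcttatcagactga"
HR2 = "tagcttatcagactgaTGTTGAtcagtctgataagctaACTTTG"
MIR21_RNA = "uagcuuaucagacugauguuga"
MIR21_DNA = "tagcttatcagactgatgttga"


@pytest.fixture(scope="session")
def mir21():
    return MIR21


@pytest.fixture(scope="session")
def let7():
    return LET7_PANEL


@pytest.fixture(scope="session")
def cfg():
    return DesignConfig()


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture(scope="session")
def calibrated():
    return nupack_calibrated()


@pytest.fixture()
def printed_pair(mir21):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_basic_pair(mir21)
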