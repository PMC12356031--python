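import numpy as np
import pytest

import letrbe as L


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geom():
    return L.NucleusGeometry()


@pytest.fixture
def induction_params():
    return L.InductionParams()


@pytest.fixture
def kinetics():
    return L.KineticsParams()


@pytest.fixture
def wild_type():
    return L.PHENOTYPE_PRESETS["wild_type"]


@pytest.fixture
def xray():
    return L.QUALITY_PRESETS["xray"]


@pytest.fixture
def alpha_quality():
    return L.QUALITY_PRESETS["alpha"]
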