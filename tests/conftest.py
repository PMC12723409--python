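import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from axonsf import GeneratorSpec, PGSEProtocol, gen_tem_mask


@pytest.fixture(scope="session")
def protocol():
    return PGSEProtocol.diameter_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mask_with_violations():
    """Generator mask with one injected violation of each kind + truth table."""
    spec = GeneratorSpec(seed=3, n_axons=30)
    return gen_tem_mask(spec, inject={
        "border": 1, "unmyelinated": 1, "high_eccentricity": 1,
        "low_coverage": 1,
    })
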