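import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from memkappa.xds import DomainSizeModel, SmecticStackParams


@pytest.fixture(scope="session")
def rbc_stack():
    """The fitted stack of the red-blood-cell membrane measurements."""
    return SmecticStackParams(kappa=2.0, B=2e-7, q1=0.084)


@pytest.fixture(scope="session")
def rbc_domains(rbc_stack):
    """Default finite-domain geometry at the best-fit lateral size."""
    return DomainSizeModel.default(d=rbc_stack.d, Lr=500.0)
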