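import numpy as np
import pytest

from chargescape.charge_model import ResidueChargeTable
from chargescape.proteome_io import ProteinRecord


@pytest.fixture
def default_table():
    return ResidueChargeTable()


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def random_records(rng):
    """50 random 200-aa proteins over the full residue alphabet."""
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    return [
        ProteinRecord(
            id=f"R{i:03d}",
            sequence="M" + "".join(rng.choice(alphabet, size=199)),
        )
        for i in range(50)
    ]
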