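import numpy as np
import pytest

from g4kit import seqcore

#: The 24-nt hybrid-1 human-telomeric model sequence used throughout.
TEL24 = "TTGGGTTAGGGTTAGGGTTAGGGA"
#: The 22-nt parallel c-myc promoter model sequence.
MYC22 = "TGAGGGTGGGTAGGGTGGGTAA"


@pytest.fixture(scope="session")
def epsilon_table():
    return seqcore.default_epsilon_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20211)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
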