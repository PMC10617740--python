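import numpy as np
import pytest

from idrslab.forcefield import ResidueParameterTable
from idrslab.synthetic import synthetic_table


@pytest.fixture(scope="session")
def default_table() -> ResidueParameterTable:
    return ResidueParameterTable.default()


@pytest.fixture(scope="session")
def random_table() -> ResidueParameterTable:
    """A synthetic parameter table so correctness never hinges on the
    bundled hydropathy constants."""
    return synthetic_table(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def fasta_file(tmp_path):
    p = tmp_path / "toy.fasta"
    p.write_text(
        ">prot1\nMKVRDE\n"
        ">prot2\nAAAA\nGGGG\n"
        ">prot3\nWYFRKDEHSTN\n"
    )
    return p


@pytest.fixture()
def annotation_file(tmp_path):
    p = tmp_path / "yth.tsv"
    p.write_text("id\tyth_start\nprot1\t5\nprot2\t9\nprot3\t8\n")
    return p
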