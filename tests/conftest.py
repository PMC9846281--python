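import warnings

import pytest

from mitochar.model import bundled_gene_table
from mitochar.synthetic import GenomeSpec, generate_mitogenome


@pytest.fixture(scope="session")
def table1():
    """The packaged R. luxiensis gene table (coordinates only, 39 features)."""
    return bundled_gene_table()


@pytest.fixture(scope="session")
def synth_genome():
    """One deterministic synthetic mitogenome with its truth record."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genome, truth = generate_mitogenome(GenomeSpec(seed=42))
    return genome, truth
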