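import numpy as np
import pytest
from hypothesis import settings

from chlorocodon.codon_core import GENETIC_CODE, CodonCountVector
from chlorocodon.synthetic_data import SyntheticSpec, generate_genomes, write_fixture_genbank

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def one_codon_per_aa() -> CodonCountVector:
    """Extreme-bias gene: each of the 20 amino acids encoded by one codon."""
    chosen: dict[str, str] = {}
    for codon, aa in sorted(GENETIC_CODE.items()):
        chosen.setdefault(aa, codon)
    return CodonCountVector.from_dict({c: 10 for c in chosen.values()}, "extreme")


@pytest.fixture(scope="session")
def uniform_vector() -> CodonCountVector:
    """No-bias gene: every sense codon used 1000 times."""
    return CodonCountVector.from_dict({c: 1000 for c in GENETIC_CODE}, "uniform")


@pytest.fixture(scope="session")
def fixture_genomes(tmp_path_factory):
    """Three synthetic genomes written as GenBank flat files (shared names,
    a minus-strand gene and a two-segment join per genome)."""
    spec = SyntheticSpec(n_genes=10, codons_per_gene=(120, 250), seed=42)
    genomes = generate_genomes(spec, n_genomes=3)
    out = tmp_path_factory.mktemp("genbank")
    paths = write_fixture_genbank(genomes, out)
    return genomes, paths, out
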