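import pytest

import ssrkit as sk


@pytest.fixture(scope="session")
def passiflora():
    return sk.load_passiflora()


@pytest.fixture(scope="session")
def code_table():
    return sk.passiflora_code_table()


@pytest.fixture(scope="session")
def primer_order():
    return sk.passiflora_primer_order()


@pytest.fixture(scope="session")
def profiles():
    profs, species = sk.passiflora_profiles()
    return profs


@pytest.fixture(scope="session")
def two_pop_private():
    """Two fully diverged populations: each fixed for a private allele."""
    spec = sk.SimSpec(
        n_populations=2,
        samples_per_population=25,
        n_loci=10,
        alleles_per_locus=4,
        fixed_private_alleles=True,
        missing_rate=0.0,
        seed=3,
    )
    return sk.simulate_genotypes(spec)
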