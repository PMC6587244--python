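import pytest

from cazymine import synthetic_data as sd


@pytest.fixture(scope="session")
def community():
    return sd.generate_community(n_taxa=8, n_genes=60, seed=11)


@pytest.fixture(scope="session")
def unigene_set(community):
    unigenes, truth_table = sd.generate_unigenes(community, seed=12)
    return unigenes, truth_table


@pytest.fixture(scope="session")
def clean_hits(community, unigene_set):
    _, truth_table = unigene_set
    return sd.generate_hit_table(
        community, truth_table, identity_noise=0.0, decoy_rate=0.0, seed=13
    )
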