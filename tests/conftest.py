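import pytest

from plectokit import fixtures, morphology


@pytest.fixture(scope="session")
def matrix():
    """Packaged 32-row x 11-character matrix (with the two ikanensis forms)."""
    return fixtures.character_matrix()


@pytest.fixture(scope="session")
def species_matrix(matrix):
    """Species-level matrix: form rows collapsed, 31 species."""
    return morphology.collapse_forms(matrix)


@pytest.fixture(scope="session")
def key():
    return fixtures.identification_key()


@pytest.fixture(scope="session")
def descriptions():
    return fixtures.species_descriptions()


@pytest.fixture(scope="session")
def divergences():
    return fixtures.divergence_table()


@pytest.fixture(scope="session")
def records():
    return fixtures.collection_records()
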