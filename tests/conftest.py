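import os

import pytest

from venomrepevo import canonical_species_tree, paper_like_preset, read_matrix

# Optional supplementary inputs: if a user drops the study's proteome
# presence/absence matrix (families x species TSV, 0/1/?) at this path,
# the full published-value tests run against it.
SUPPLEMENTARY_MATRIX = os.path.join(
    os.path.dirname(__file__), "..", "data",
    "S5_proteome_presence_absence.tsv")
SUPPLEMENTARY_OVERRIDES = os.path.join(
    os.path.dirname(__file__), "..", "data", "published_overrides.yaml")


@pytest.fixture(scope="session")
def species_tree():
    return canonical_species_tree()


@pytest.fixture(scope="session")
def preset():
    return paper_like_preset(seed=20240901)


@pytest.fixture(scope="session")
def supplementary_matrix():
    if not os.path.exists(SUPPLEMENTARY_MATRIX):
        pytest.skip(
            "supplementary proteome matrix not available (place the "
            "families x species TSV at data/S5_proteome_presence_absence.tsv "
            "to enable the published-value checks)")
    return read_matrix(SUPPLEMENTARY_MATRIX)
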