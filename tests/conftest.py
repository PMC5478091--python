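import numpy as np
import pytest

from miaconcord import (
    ConfusionMatrix,
    DiseaseCategory,
    default_block_table,
    default_category_map,
    example_cases_path,
    read_cases,
)

# Published 5x5 category cross-tabulation (rows MIA, columns CDA) for the
# 54-case pediatric series; the reference input for the agreement statistics.
STUDY_MATRIX = np.array([
    [39, 0, 2, 1, 0],
    [0, 7, 0, 0, 0],
    [0, 0, 0, 0, 0],
    [1, 0, 0, 2, 0],
    [2, 0, 0, 0, 0],
])


@pytest.fixture(scope="session")
def block_table():
    return default_block_table()


@pytest.fixture(scope="session")
def category_map():
    return default_category_map()


@pytest.fixture(scope="session")
def study_matrix():
    return ConfusionMatrix(categories=DiseaseCategory.ordered(),
                           counts=STUDY_MATRIX)


@pytest.fixture(scope="session")
def example_cases(block_table, category_map):
    return read_cases(example_cases_path(), block_table, category_map)
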