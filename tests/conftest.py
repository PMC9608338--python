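import numpy as np
import pytest

import fittsboard as fb
from fittsboard.data import default_corpus


@pytest.fixture(scope="session")
def grid() -> fb.GridSpec:
    return fb.GridSpec()


@pytest.fixture(scope="session")
def scheme() -> fb.AngularBinScheme:
    return fb.AngularBinScheme()


@pytest.fixture(scope="session")
def corpus_flow() -> np.ndarray:
    return fb.count_digraphs(default_corpus())


@pytest.fixture(scope="session")
def spiral27(grid) -> tuple:
    return fb.candidate_positions(grid, 27)
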