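import numpy as np
import pandas as pd
import pytest

from pairscan.containers import MISSING, GenotypeMatrix, SampleTable


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    codes = np.array([
        [0, 1, 2, 1],
        [1, 1, 0, MISSING],
        [2, 0, 1, 0],
        [0, 2, 1, 1],
    ], dtype=np.int8)
    return GenotypeMatrix([f"s{i}" for i in range(4)],
                          [f"L{j}" for j in range(4)], codes)


@pytest.fixture
def tiny_samples(tiny_matrix) -> SampleTable:
    return SampleTable(pd.DataFrame({
        "sample_id": tiny_matrix.sample_ids,
        "population": ["A", "A", "B", "B"],
        "life_history": [1, 1, 0, 0],
        "sex": ["M", "F", "M", "F"],
    }))
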