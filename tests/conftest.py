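import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_meta  # noqa: E402

from pairflow import QMatrix, load_sceloporus_pairs  # noqa: E402
from pairflow.datasets import comparison3_assignments  # noqa: E402


@pytest.fixture(scope="session")
def pair_table():
    return load_sceloporus_pairs()


@pytest.fixture()
def worked_example():
    """Q-matrix and metadata for the published ten-individual comparison
    (clade 1 vs clade 12): other-clade percentages 2.7,0,0,0,0 / 7.1,5.3,5.8,4.3,3.3."""
    c1, c12 = comparison3_assignments()
    rows = [[1 - p / 100, p / 100] for p in c1] + [[p / 100, 1 - p / 100] for p in c12]
    samples = [f"ind{i}" for i in range(10)]
    q = QMatrix(samples, np.array(rows))
    meta = make_meta(samples, ["clade1"] * 5 + ["clade12"] * 5)
    return q, meta
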