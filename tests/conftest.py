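import numpy as np
import pandas as pd
import pytest

from cobreed.simulate import RESIGHTING_COLUMNS


def make_records(rows, colony="C"):
    """Build a resighting table from (individual, year, patch) triples."""
    return pd.DataFrame(
        [(i, y, colony, p) for i, y, p in rows],
        columns=list(RESIGHTING_COLUMNS),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def records_small():
    """Two groups of two individuals over three years, one floater."""
    return make_records(
        [
            ("a", 2002, "P1"), ("b", 2002, "P1"), ("c", 2002, "P2"),
            ("d", 2002, "P2"),
            ("a", 2003, "P3"), ("b", 2003, "P3"), ("c", 2003, "P4"),
            ("a", 2004, "P5"), ("c", 2004, "P5"), ("e", 2004, "P6"),
        ]
    )
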