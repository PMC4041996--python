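import numpy as np
import pandas as pd
import pytest

from funsig.study_design import Block


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_design(rng):
    """Three-feature design with two case and two control blocks."""
    snps = [f"s{i}" for i in range(10)]
    F = pd.DataFrame(rng.standard_normal((10, 3)), index=snps, columns=["a", "b", "c"])
    blocks = [
        Block("c0", "case", ("s0", "s1", "s2"), "s0", pair_id=0),
        Block("t0", "control", ("s3", "s4"), "s3", pair_id=0),
        Block("c1", "case", ("s5",), "s5", pair_id=1),
        Block("t1", "control", ("s6", "s7", "s8", "s9"), "s6", pair_id=1),
    ]
    return blocks, F
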