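import numpy as np
import pandas as pd
import pytest

from tepomics import CountMatrix, MatureMiRNA


@pytest.fixture
def tiny_ref():
    """Two hand-built reference miRNAs with known flanks.

    mir-a: flank3 starts with G (so an appended G would be a templated
    extension, not an nta#G tail); mir-b: flank3 starts with A.
    """
    return [
        MatureMiRNA("mir-a", "UGAGGUAGUAGGUUGUAUAGUU", "CCUACC", "GAAAUC"),
        MatureMiRNA("mir-b", "CAUUGCACUUGUCUCGGUCUGA", "GGCUAC", "AUUCGG"),
    ]


@pytest.fixture
def two_group_matrix():
    """Small deterministic count matrix with 3 vs 3 samples."""
    rng = np.random.default_rng(0)
    samples = ["A01", "A02", "A03", "B01", "B02", "B03"]
    counts = pd.DataFrame(
        rng.poisson(50, size=(20, 6)), columns=samples,
        index=[f"g{i:02d}" for i in range(20)],
    )
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=samples)
    return CountMatrix("mrna", counts, groups)


def make_matrix(counts, n_a, n_b, layer="mrna"):
    """CountMatrix from a 2D array with the first n_a columns in group A."""
    counts = np.asarray(counts)
    samples = [f"A{i:02d}" for i in range(n_a)] + [f"B{i:02d}" for i in range(n_b)]
    df = pd.DataFrame(counts, columns=samples,
                      index=[f"f{i:03d}" for i in range(counts.shape[0])])
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    return CountMatrix(layer, df, groups)
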