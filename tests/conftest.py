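import numpy as np
import pandas as pd
import pytest

from rair_axis import CohortSpec, generate_cohort
from rair_axis.preprocess import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_cohort():
    """2000-gene, 20+20-sample cohort with a 50-gene planted up/down module."""
    spec = CohortSpec(
        n_genes=2000, n_per_group=(20, 20),
        planted_up=frozenset(range(50)),
        planted_down=frozenset(range(50, 100)),
        effect_size=2.0, noise_sd=0.3, seed=101)
    matrix, truth = generate_cohort(spec)
    return spec, matrix, truth


@pytest.fixture
def tiny_matrix(rng):
    """10 genes x 8 samples (4 vs 4), log scale, no planted structure."""
    genes = [f"g{i}" for i in range(10)]
    samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
    vals = pd.DataFrame(rng.normal(6.0, 1.0, size=(10, 8)),
                        index=genes, columns=samples)
    return ExpressionMatrix(values=vals, scale="log2p1", sample_groups=groups)
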