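import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cernaforge import ExpressionMatrix, SyntheticConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_matrix(values, genes, samples, groups, rna_class="mRNA"):
    df = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    group = pd.Series(groups, index=samples, dtype=object)
    return ExpressionMatrix(values=df, group=group, rna_class=rna_class)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, 2v2 design."""
    return make_matrix(
        [[5.0, 5.2, 6.4, 6.6], [4.0, 4.1, 4.0, 4.2], [8.0, 7.9, 6.0, 5.9]],
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        ["control", "control", "case", "case"],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests (seed 1)."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_network():
    from cernaforge import load_table2_fixture

    return load_table2_fixture()
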