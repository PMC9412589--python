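import numpy as np
import pandas as pd
import pytest

from csfpanel.ingest import IntensityMatrix


def make_matrix(values, groups=None, fractions=None, protein_ids=None, sample_ids=None):
    """Assemble an IntensityMatrix from a 2-D array and per-sample labels."""
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    protein_ids = protein_ids or [f"P{i}" for i in range(n_prot)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n_samp)]
    groups = groups or ["control"] * (n_samp // 2) + ["MB"] * (n_samp - n_samp // 2)
    fractions = fractions or ["total"] * n_samp
    ann = pd.DataFrame({"group": groups, "fraction": fractions}, index=sample_ids)
    return IntensityMatrix(pd.DataFrame(values, index=protein_ids, columns=sample_ids), ann)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def matrix_factory():
    return make_matrix
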