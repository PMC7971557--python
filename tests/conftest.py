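import numpy as np
import pandas as pd
import pytest

from purinomics import MetaboliteMatrix, control_zscore
from purinomics.synthetic import simple_metabolome_spec, simulate_metabolome


@pytest.fixture
def tiny_matrix() -> MetaboliteMatrix:
    """3 samples x 2 metabolites, hand-written AUCs."""
    auc = pd.DataFrame(
        {"met_a": [8.0, 16.0, 32.0], "met_b": [1024.0, 2048.0, 4096.0]},
        index=["s1", "s2", "s3"],
    )
    groups = pd.Series(["saline", "saline", "ATP"], index=auc.index, name="group")
    pathways = pd.Series({"met_a": "Purines", "met_b": "Amino acids"})
    return MetaboliteMatrix(auc=auc, groups=groups, pathways=pathways)


@pytest.fixture
def small_spec():
    """10 metabolites, 8 + 8 samples, no planted effects."""
    return simple_metabolome_spec(10, seed=1)


@pytest.fixture
def small_zmat(small_spec):
    return control_zscore(simulate_metabolome(small_spec), "saline")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
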