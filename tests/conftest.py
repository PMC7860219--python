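import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import configuration, settings

from npomics import ExpressionMatrix

# keep hypothesis state out of the repository and make runs reproducible
configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hypothesis-"))
settings.register_profile("deterministic", database=None, derandomize=True)
settings.load_profile("deterministic")


def make_matrix(values, layer="mrna", scale="log2", feature_ids=None, n_per_group=None):
    """ExpressionMatrix from a 2-D array; first half IVD, second half IDD."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if n_per_group is None:
        n_per_group = n_samp // 2
    samples = [f"IVD_{i}" for i in range(1, n_per_group + 1)] + [
        f"IDD_{i}" for i in range(1, n_samp - n_per_group + 1)
    ]
    groups = {s: s.split("_")[0] for s in samples}
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(n_feat)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=samples),
        layer=layer,
        scale=scale,
        groups=groups,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
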