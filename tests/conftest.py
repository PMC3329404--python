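import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from famsurvey.config import SimConfig
from famsurvey.io import ExpressionMatrix
from famsurvey.synthetic import generate_all


@pytest.fixture(scope="session")
def dataset():
    """Full-size synthetic dataset at default study conditions."""
    return generate_all(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome for fast pipeline-level tests."""
    return SimConfig(
        n_chromosomes=6,
        genes_per_chromosome=60,
        n_family_genes=40,
        n_tandem_groups=4,
        n_segmental_pairs=4,
        n_modules=3,
        module_size=8,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_all(small_config)


def make_matrix(values, conditions, replicates, flags=None, index=None):
    """Assemble an ExpressionMatrix from a 2-D array and a condition layout."""
    values = np.asarray(values, dtype=float)
    cols, meta = [], []
    k = 0
    for cond, n_rep in zip(conditions, replicates):
        for r in range(1, n_rep + 1):
            cols.append(f"{cond}_r{r}")
            meta.append({"sample_id": f"{cond}_r{r}", "condition": cond, "replicate": r})
            k += 1
    assert k == values.shape[1]
    index = index or [f"g{i}" for i in range(values.shape[0])]
    vdf = pd.DataFrame(values, index=index, columns=cols)
    fdf = None
    if flags is not None:
        fdf = pd.DataFrame(flags, index=index, columns=cols)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ExpressionMatrix(vdf, samples, fdf)
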