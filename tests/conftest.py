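import warnings

import numpy as np
import pandas as pd
import pytest

import dmrscan as ds

# the sklearn saga solver warns about convergence on tiny CV folds; harmless here
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture
def tiny_matrix():
    """4 sites x 4 samples, full coverage, hand-set counts."""
    chroms = ["chr1", "chr1", "chr2", "chr2"]
    positions = [100, 250, 50, 900]
    coverage = np.full((4, 4), 20, dtype=int)
    meth = np.array(
        [
            [2, 4, 10, 12],
            [10, 10, 10, 10],
            [0, 0, 20, 20],
            [5, 5, 5, 5],
        ]
    )
    return ds.MethylationCallMatrix(chroms, positions, meth, coverage, ["cn1", "cn2", "ad1", "ad2"])


@pytest.fixture
def tiny_samples():
    return pd.DataFrame(
        {
            "sample_id": ["cn1", "cn2", "ad1", "ad2"],
            "group": ["CN", "CN", "AD", "AD"],
            "sex": ["male", "female", "male", "female"],
            "age": [70.0, 71.0, 72.0, 73.0],
            "apoe_e4": [0, 0, 1, 2],
            "cohort": "test",
        }
    )


def random_dmp_frame(rng, n_dmps, span_bp=50_000, chrom="chr1", delta_range=(0.1, 0.4)):
    pos = np.sort(rng.choice(np.arange(1, span_bp + 1), size=n_dmps, replace=False))
    delta = rng.uniform(*delta_range, size=n_dmps) * rng.choice([-1.0, 1.0], size=n_dmps)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "delta_beta": delta})


@pytest.fixture
def random_dmps():
    return random_dmp_frame
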