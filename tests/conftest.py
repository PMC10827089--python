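import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from centrotx import SimConfig, run_pipeline, small_config


@pytest.fixture(scope="session")
def small_run():
    """One desk-scale end-to-end pipeline run shared across tests."""
    return run_pipeline(small_config(seed=7))


@pytest.fixture(scope="session")
def full_census_run():
    """Pipeline run at the default full-census configuration."""
    return run_pipeline(SimConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_contigs(rng, n_contigs, min_len, max_len):
    """Random A/C/G/T contigs for oracle comparisons."""
    out = {}
    for i in range(n_contigs):
        n = int(rng.integers(min_len, max_len + 1))
        out[f"ctg{i}"] = "".join("ACGT"[j] for j in rng.integers(0, 4, size=n))
    return out
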