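"""Shared fixtures.

The CSV files under tests/data are *synthetic* stand-ins generated by the
package's own simulator (fixed seeds); they mimic the shape of published
worked-example datasets (20 and 10 studies) but not their values.
"""

from pathlib import Path

import numpy as np
import pytest

from mixturemeta import MetaSample, NormalLatent
from mixturemeta.simulation import PAPER_SIZE_PAIRS

DATA_DIR = Path(__file__).parent / "data"

#: One global seed for every stochastic test (derandomized on purpose).
TEST_SEED = 20260924


@pytest.fixture
def rng():
    return np.random.default_rng(TEST_SEED)


@pytest.fixture
def toy_sample():
    """Three hand-checkable studies; the raw tau2 estimate is negative."""
    return MetaSample(
        g=[0.2, 0.5, 0.8], n1=[10, 15, 20], n2=[10, 15, 20],
        study_ids=["s1", "s2", "s3"],
    )


@pytest.fixture
def latent():
    """The latent distribution of the reference simulation condition."""
    return NormalLatent(mu_delta=0.5, tau2=0.1)


@pytest.fixture
def design_pairs():
    return PAPER_SIZE_PAIRS
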