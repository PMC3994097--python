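import numpy as np
import pytest

from assoclearn import BlobSpec, make_blobs


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def separable_blobs():
    """Two classes 20 units apart at sigma=1: effectively noiseless."""
    return make_blobs(
        BlobSpec(means=[[-10.0, 0.0], [10.0, 0.0]], sigma=1.0, counts=[50, 50], seed=7)
    )


@pytest.fixture
def overlapping_blobs():
    """Two classes 1 sigma apart: heavy overlap, exercises imperfect paths."""
    return make_blobs(
        BlobSpec(means=[[0.0, 0.0], [1.0, 0.0]], sigma=1.0, counts=[30, 30], seed=11)
    )
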