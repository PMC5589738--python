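import numpy as np
import pytest

from anfiswo.anfis import ANFISModel
from anfiswo.data_model import SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_model(rng, d=3, c=2, sigma_lo=0.05, sigma_hi=1.5):
    """A random valid rule base with widths safely above the decode clamp."""
    return ANFISModel(
        centers=rng.uniform(-0.2, 1.2, size=(c, d)),
        widths=rng.uniform(sigma_lo, sigma_hi, size=(c, d)),
        coeffs=rng.uniform(-3.0, 3.0, size=(c, d)),
        bias=rng.uniform(-3.0, 3.0, size=c),
    )


def random_table(rng, n=20, d=3, m=2):
    return SampleTable(
        features=rng.random((n, d)) * 10.0,
        targets=rng.random((n, m)) * 5.0 + 1.0,
        feature_names=[f"f{j}" for j in range(d)],
        target_names=[f"t{j}" for j in range(m)],
    )
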