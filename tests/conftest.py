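import numpy as np
import pytest

from pharmscreen.clustering import FingerprintSet
from pharmscreen.pharmacophore import PharmacophoreQuery


@pytest.fixture
def four_feature_query() -> PharmacophoreQuery:
    """An aromatic/acceptor/two-hydrophobe query with well-spread centres."""
    return PharmacophoreQuery(
        name="AHHR_0",
        types=["Aro", "Acc", "Hyd", "Hyd"],
        centers=np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0],
                          [1.5, 3.0, 0.0], [3.0, 1.0, 2.5]]),
        radii=np.array([1.0, 1.0, 1.4, 1.4]),
    )


def random_fingerprint_set(rng: np.random.Generator, n: int, n_bits: int = 32,
                           density: float = 0.3) -> FingerprintSet:
    bits = (rng.random((n, n_bits)) < density).astype(np.uint8)
    return FingerprintSet(ids=[f"m{i}" for i in range(n)], bits=bits, n_bits=n_bits)
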