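import numpy as np
import pytest

from nlm3d import Volume


def max_rel_dev(a: Volume | np.ndarray, b: Volume | np.ndarray) -> float:
    """Max per-voxel relative deviation of a from reference b."""
    da = a.data if isinstance(a, Volume) else np.asarray(a)
    db = b.data if isinstance(b, Volume) else np.asarray(b)
    return float(np.max(np.abs(da - db) / np.maximum(np.abs(db), 1e-12)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240616)
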