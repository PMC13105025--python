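import numpy as np
import pytest

from cellskew.core_io import ActivitySample
from cellskew.synthetic import SyntheticSpec, generate_sample


@pytest.fixture
def lognormal_sample() -> ActivitySample:
    """10^4 lognormal draws with mu_log=2, sigma=1 (fixed seed)."""
    spec = SyntheticSpec(
        "lognormal", {"mu_log": 2.0, "sigma": 1.0}, n=10_000, seed=11, sample_id="ln_ref"
    )
    return generate_sample(spec)


@pytest.fixture
def event_csv(tmp_path):
    """Small three-sample event table on disk."""
    path = tmp_path / "events.csv"
    path.write_text(
        "sample_id,rfu,regime,bp\n"
        "s1,10,chemostat,0.5\n"
        "s1,20,chemostat,0.5\n"
        "s2,5,environmental,2.0\n"
    )
    return path


def assert_sorted_equal(a, b):
    np.testing.assert_allclose(np.sort(a), np.sort(b))
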