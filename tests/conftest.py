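import numpy as np
import pytest

from cfmulti.datatypes import FragmentProfile, LENGTH_GRID
from cfmulti.simulate import GeneratorConfig, gen_cohort


def profile_from_dict(counts: dict[int, float], sample_id: str = "toy") -> FragmentProfile:
    """Build a FragmentProfile from {length: count} (lengths on 30-700)."""
    arr = np.zeros(LENGTH_GRID.size)
    for length, c in counts.items():
        arr[length - 30] = c
    total = arr.sum()
    return FragmentProfile(sample_id=sample_id, rel_freq=arr / total, n_fragments=int(total))


@pytest.fixture(scope="session")
def small_cohort():
    """One small but complete synthetic cohort shared across tests."""
    config = GeneratorConfig(
        n_controls=10, n_lpca=10, n_apca=8, n_missing_urine=2,
        n_bins=500, n_windows=800, n_fragments=150_000, seed=11,
    )
    return gen_cohort(config)
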