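import numpy as np
import pytest

from dtwfc import SimConfig, StudySet, SubjectRecord, simulate_study

# Six-point worked example pair: the known optimal alignment has total
# absolute cost 2 (verified against exhaustive path enumeration).
EXAMPLE_A = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 1.0])
EXAMPLE_B = np.array([1.0, 1.0, 3.0, 4.0, 3.0, 1.0])


@pytest.fixture
def example_pair():
    return EXAMPLE_A.copy(), EXAMPLE_B.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_study(rng):
    """Four subjects, three regions, twelve time points; labels balanced."""
    records = [
        SubjectRecord(f"s{i}", rng.standard_normal((3, 12)), label=i % 2, dt=2.0)
        for i in range(4)
    ]
    return StudySet(records=records, roi_names=["A", "B", "C"])


@pytest.fixture(scope="session")
def lag_study():
    """Desk-scale simulated study with one lag-type informative pair."""
    config = SimConfig(
        n_per_group=10,
        n_rois=8,
        informative_pairs=((1, 4, "lag", 1),),
        seed=11,
    )
    return simulate_study(config)
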