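import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lickstruct.bout_segmentation import SegmentationParams
from lickstruct.event_io import SessionRecord
from lickstruct.synthetic_data import default_cohort_spec, simulate_cohort


@pytest.fixture
def seg_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture
def session_record() -> SessionRecord:
    return SessionRecord(
        session_id="s1",
        animal_id="a1",
        genotype="wild_type",
        sex="F",
        fluid="ethanol20",
        session_length=7200.0,
        bottle_mass_pre=45.0,
        bottle_mass_post=44.3,
        body_mass=25.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-genotype cohort shared by read-only tests."""
    return simulate_cohort(default_cohort_spec(n_per_group=4, seed=11))


def random_lick_train(rng: np.random.Generator, n_max: int = 50) -> np.ndarray:
    """Random strictly-increasing onsets with ILIs spanning 0.05-10 s.

    The interval mixture deliberately straddles both segmentation thresholds
    so every branch of the bout criteria is exercised.
    """
    n = int(rng.integers(0, n_max + 1))
    if n == 0:
        return np.empty(0)
    choices = rng.integers(0, 3, size=n)
    ilis = np.where(
        choices == 0,
        rng.uniform(0.05, 1.2, n),
        np.where(
            choices == 1,
            rng.uniform(0.8, 3.5, n),
            rng.uniform(2.5, 10.0, n),
        ),
    )
    return np.cumsum(ilis)
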