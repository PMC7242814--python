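import numpy as np
import pandas as pd
import pytest

from dediff.containers import BetaMatrix, ROISpec
from dediff.design import DesignParams, generate_design
from dediff.simulate import BehaviorParams, simulate_behavior


@pytest.fixture(scope="session")
def small_params() -> DesignParams:
    """A scaled-down design (1 cycle x 2 blocks x 12 pairs) for fast tests."""
    return DesignParams(
        n_cycles=1,
        blocks_per_cycle=2,
        critical_per_block=12,
        null_per_sublist=6,
        new_words_per_test_sublist=6,
        fillers_per_segment=1,
    )


@pytest.fixture(scope="session")
def small_cohort_events(small_params) -> pd.DataFrame:
    design = generate_design(small_params, n_participants=4, seed=11)
    return simulate_behavior(design, BehaviorParams(), seed=12)


def make_beta_matrix(
    values: np.ndarray,
    categories,
    sessions,
    memory=None,
    preferred: str = "scene",
    name: str = "testROI",
) -> BetaMatrix:
    """Assemble a BetaMatrix from explicit arrays."""
    values = np.asarray(values, dtype=float)
    meta = pd.DataFrame(
        {
            "category": list(categories),
            "session": list(sessions),
            "memory_status": list(memory) if memory is not None else "other",
        }
    )
    roi = ROISpec(name, preferred, np.arange(values.shape[1]))
    return BetaMatrix(values, meta, roi)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
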