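import numpy as np
import pytest

from kerneldeef import (
    DonorProfile,
    simulate_cytometry_cohort,
    subsample_cells,
    two_group_cohort_spec,
)
from kerneldeef.kernel_embedding import CellSample


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-group mixture cohort: 3 + 3 donors, 60 cells, p = 3."""
    spec = two_group_cohort_spec(
        n_donors_per_group=3, n_cells_per_donor=60, p=3, shift=3.0, seed=42
    )
    return simulate_cytometry_cohort(spec)


@pytest.fixture(scope="session")
def small_samples(small_cohort):
    profiles, _ = small_cohort
    return [subsample_cells(p, 40, seed=100 + i) for i, p in enumerate(profiles)]


def random_cell_sample(rng, donor_id, n, p):
    return CellSample(
        donor_id=donor_id, cells=rng.normal(size=(n, p)), seed=-1
    )


def random_profile(rng, donor_id, n=50, p=3, nonneg=False):
    x = rng.normal(size=(n, p))
    if nonneg:
        x = np.abs(x)
    return DonorProfile(
        donor_id=donor_id,
        expression=x,
        feature_names=[f"f{j}" for j in range(p)],
    )
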