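import numpy as np
import pytest

from oedrisk.cohort import CohortConfig, generate_cohort
from oedrisk.dvh import DifferentialDVH


@pytest.fixture
def rng():
    return np.random.default_rng(20251234)


@pytest.fixture
def two_bin_dvh():
    """60 cm^3 in [0,1) Gy and 40 cm^3 in [1,2) Gy."""
    return DifferentialDVH("thyroid", [0.0, 1.0, 2.0], [60.0, 40.0])


def make_uniform_dvh(dose, volume=100.0, organ="breast_contralateral", half_width=0.05):
    """Single-bin DVH whose center is exactly ``dose`` Gy."""
    return DifferentialDVH(organ, [dose - half_width, dose + half_width], [volume])


def make_random_dvh(rng, organ="thyroid", max_bins=60, max_width=0.2):
    """Random non-uniform DVH for property and oracle tests."""
    n = int(rng.integers(3, max_bins))
    widths = rng.uniform(0.05, max_width, size=n)
    edges = np.concatenate([[0.0], np.cumsum(widths)]) + rng.uniform(0, 0.5)
    vols = rng.uniform(0.0, 5.0, size=n)
    vols[int(rng.integers(n))] += 1.0  # at least one occupied bin
    return DifferentialDVH(organ, edges, vols)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(seed=11, n_per_group=4, n_voxels=1500))
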