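import numpy as np
import pytest

from cortexdti.core import default_scheme
from cortexdti.dti_fit import fit_tensor, tensor_scalars
from cortexdti.phantom import make_slab_phantom, synthesize_dwi


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def slab():
    """Small noiseless slab phantom (tilt 0) with fitted maps and table."""
    surfaces, tv = make_slab_phantom(thickness_mm=3.0, extent_mm=15.0,
                                     voxel_mm=1.5, tilt_deg=0.0)
    return surfaces, tv


@pytest.fixture(scope="session")
def slab_maps(slab, scheme):
    surfaces, tv = slab
    dwi = synthesize_dwi(tv, scheme)
    fitted = fit_tensor(dwi)
    maps, eigen = tensor_scalars(fitted)
    return surfaces, maps, eigen


def make_cohort_from_means(means: dict, sd: float, metric: str, n: int,
                           seed: int = 0):
    """Cohort with constant (age-flat) per-region means: linear b = 0."""
    from cortexdti.cohort_sim import TrajectorySpec, simulate_cohort

    specs = {(region, metric): TrajectorySpec(
        family="linear", params=(mu, 0.0), noise_sd=sd)
        for region, mu in means.items()}
    return simulate_cohort(specs, n=n, seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
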