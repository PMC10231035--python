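import numpy as np
import pytest

from fiberwalk import build_volume
from fiberwalk.phantoms import (
    PhantomSpec,
    make_brain_phantom,
    make_slab,
    make_sphere_stack,
)


@pytest.fixture(scope="session")
def slab_volume():
    """20 x 20 all-allowed slab, 2 physical sections (z_extent 24)."""
    return build_volume(make_slab(20, 20, 2))


@pytest.fixture(scope="session")
def sphere_volume():
    """Ball of radius 16, one virtual slice per grid unit."""
    return build_volume(make_sphere_stack(16), subdivisions=1)


@pytest.fixture(scope="session")
def brain():
    """Default brain-like phantom: (sections, start_region, volume)."""
    sections, start = make_brain_phantom()
    return sections, start, build_volume(sections)


@pytest.fixture(scope="session")
def small_brain():
    """Small brain-like phantom for exhaustive cell-level checks."""
    spec = PhantomSpec(nx=48, ny=40, n_sections=8,
                       ventricle_sections=(2, 4), concavity_sections=(3, 5))
    sections, start = make_brain_phantom(spec)
    return sections, start, build_volume(sections)


def bartlett_se(theory_cov, n, max_lag):
    """Standard errors of sample autocovariances of a stationary Gaussian
    series (Bartlett): Var c(t) ~ (1/n) sum_k [c(k)^2 + c(k+t) c(k-t)].

    ``theory_cov(lag_array) -> covariances`` must accept non-negative lags.
    Long-range dependence inflates these well beyond the iid 1/sqrt(n).
    """
    kmax = n - 1
    k = np.arange(-kmax, kmax + 1)
    cov_all = theory_cov(np.arange(n + max_lag))
    c = cov_all[np.abs(k)]
    cc = np.sum(c * c)
    se = np.empty(max_lag + 1)
    for t in range(max_lag + 1):
        term = np.sum(cov_all[np.abs(k + t)] * cov_all[np.abs(k - t)])
        se[t] = np.sqrt((cc + term) / n)
    return se
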