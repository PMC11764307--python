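import numpy as np
import pytest

from mmlsdm.covariates import generate_raw_fields, pca_components, standardize
from mmlsdm.pointprocess import PointPattern, Window, intensity_surface, simulate_ippp


@pytest.fixture(scope="session")
def pc_grid():
    """Standardized PC score fields on the default 1250-cell study grid."""
    raw = generate_raw_fields(25, 50, 13, smoothness=3.0, seed=11)
    return pca_components(standardize(raw), 12)


@pytest.fixture(scope="session")
def study_pattern(pc_grid):
    """One Poisson point pattern from the 4-component reference intensity."""
    theta = np.concatenate([[-3.0], 1.0 / pc_grid.sigmas[:4]])
    lam = intensity_surface(pc_grid, [0, 1, 2, 3], theta)
    return simulate_ippp(lam, pc_grid, seed=23)


@pytest.fixture()
def uniform_pattern():
    """100 uniform points on the 50x25 window (intercept-only test case)."""
    rng = np.random.default_rng(42)
    pts = rng.random((100, 2)) * [50.0, 25.0]
    return PointPattern(pts, Window(50.0, 25.0))
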