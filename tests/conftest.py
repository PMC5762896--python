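import numpy as np
import pytest

from bcsradiomics.features import extract_table
from bcsradiomics.phantom import default_cohort_spec, generate_cohort


def ball_mask(radius: int, grid: int | None = None) -> np.ndarray:
    """Voxelized ball: voxel centers within `radius` of a half-integer center.

    With the sphere center between voxels the ball spans exactly 2r voxels
    per axis, so voxel-count ratios converge to the continuous ones (e.g.
    extent -> pi/6) instead of the (2r+1)-box discretization.
    """
    g = grid or (2 * radius + 6)
    if g % 2:
        g += 1
    c = (g - 1) / 2.0  # half-integer for even g
    zz, yy, xx = np.meshgrid(*[np.arange(g)] * 3, indexing="ij")
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def ellipsoid_mask(radii, grid=None) -> np.ndarray:
    g = grid or (2 * int(max(radii)) + 5)
    c = (g - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(g)] * 3, indexing="ij")
    a, b, d = radii
    return ((zz - c) / a) ** 2 + ((yy - c) / b) ** 2 + ((xx - c) / d) ** 2 <= 1.0


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-per-class calibrated cohort, shared across tests."""
    return generate_cohort(default_cohort_spec(seed=11, n_per_class=10))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    result = extract_table(small_cohort)
    assert not result.skipped
    return result.table
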