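import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import peridose as pdx
from peridose.grid import voxel_coords_in_model_frame


@pytest.fixture(scope="session")
def recovery_grid():
    """2 cm isotropic grid spanning ±40 cm with the 8-40 cm radial fit mask."""
    n = 41
    grid = pdx.DoseGrid(np.zeros((n, n, n)), spacing=(2, 2, 2), origin=(-40, -40, -40))
    frame = pdx.IsocenterFrame()
    x, y, z = voxel_coords_in_model_frame(grid, frame)
    r = np.sqrt(x * x + y * y + z * z)
    mask = (r >= 8.0) & (r <= 40.0)
    return grid, frame, mask


@pytest.fixture(scope="session")
def noiseless_reference(recovery_grid):
    """Noiseless reference cube generated by the calibrated model itself."""
    grid, frame, mask = recovery_grid
    cube = pdx.compute_ppd_cube(grid, frame)
    return grid.like(np.nan_to_num(cube.values, nan=0.0))


@pytest.fixture(scope="session")
def noiseless_fit(recovery_grid, noiseless_reference):
    grid, frame, mask = recovery_grid
    return pdx.fit_coefficients(noiseless_reference, mask, frame=frame)


@pytest.fixture(scope="session")
def phantom_spec():
    return pdx.PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    body, labels, names = pdx.generate_phantom(phantom_spec)
    return body, labels, names
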