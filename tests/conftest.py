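import numpy as np
import pytest

from retroughness.surfaces_io import N_SURFACES, ScanGeometry, SurfaceStack
from retroughness.synthetic import default_layer_specs, generate_surface_stack


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced scan grid for fast structural tests (full pitch calibration)."""
    return ScanGeometry(n_rows=32, n_cols=64)


@pytest.fixture(scope="session")
def small_stack(small_geometry):
    """One deterministic synthetic stack on the reduced grid."""
    return generate_surface_stack(
        default_layer_specs(),
        np.full(10, 6.0),
        geometry=small_geometry,
        seed=11,
        subject_id="T001",
    )


def flat_stack(gaps, geometry=None, slope_x=0.0, slope_y=0.0, rigid=False):
    """Stack of parallel planes with prescribed vertical gaps between surfaces.

    ``gaps`` are the 10 per-layer vertical separations (um).  With
    ``rigid=True`` the gaps are inflated by sec(theta) of the plane tilt so
    each slab has true (orthogonal) thickness equal to the nominal gap.
    """
    geometry = geometry or ScanGeometry(n_rows=24, n_cols=48)
    rows, cols = geometry.shape
    xx = np.arange(cols)[None, :] * geometry.pixel_pitch_x
    yy = np.arange(rows)[:, None] * geometry.pixel_pitch_y
    plane = slope_x * xx + slope_y * yy
    sec = np.sqrt(1.0 + slope_x**2 + slope_y**2)
    surfaces = np.empty((N_SURFACES, rows, cols))
    z = np.zeros((rows, cols)) + plane
    surfaces[0] = z
    for k, gap in enumerate(gaps):
        z = z + gap * (sec if rigid else 1.0)
        surfaces[k + 1] = z
    stack = SurfaceStack(
        geometry=geometry,
        surfaces=surfaces,
        valid_mask=np.ones((rows, cols), dtype=bool),
        fovea_rc=((rows - 1) / 2, (cols - 1) / 2),
        papilla_rc=((rows - 1) / 2, cols + 40.0),
        subject_id="FLAT",
    )
    stack.validate()
    return stack
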