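import numpy as np
import pytest

import curvecage as cc
from curvecage.harmonic import rasterize_cage, solve_harmonic_weights


@pytest.fixture(scope="session")
def unit_cube_cage():
    return cc.box_lattice_cage([0, 0, 0], [1, 1, 1], (2, 2, 2))


@pytest.fixture(scope="session")
def cube_grid_fields(unit_cube_cage):
    """Cube cage rasterized + solved at resolution 32 (shared, ~0.5 s)."""
    grid = rasterize_cage(unit_cube_cage, 32)
    fields = solve_harmonic_weights(grid, unit_cube_cage)
    return grid, fields


@pytest.fixture(scope="session")
def sphere_template():
    """Icosphere (r=20 mm) bound to a 27-vertex box-lattice cage at res 32."""
    mesh = cc.icosphere(20.0, 3)
    cage = cc.box_lattice_cage([-26] * 3, [-26 + 52] * 3, (3, 3, 3))
    return cc.bind_template(mesh, cage, 32)


@pytest.fixture(scope="session")
def sphere_template_coarse():
    """Icosphere (r=20 mm) bound to the plain 8-vertex box cage at res 24."""
    mesh = cc.icosphere(20.0, 2)
    cage = cc.box_lattice_cage([-26] * 3, [26] * 3, (2, 2, 2))
    return cc.bind_template(mesh, cage, 24)


def surface_constraint_points(mesh, axes=("XY", "YZ", "ZX"), n=64, offsets=None):
    """Equal-arc samples of the mesh's cross-section loops (exact surface points)."""
    from curvecage.curves import ConstraintPointSet, CrossSectionPlane
    from curvecage.synthetic import _subsample_loop, cross_section_loops

    if offsets is None:
        offsets = [0.0] * len(axes)
    pts = []
    for ax, off in zip(axes, offsets):
        loops = cross_section_loops(mesh, CrossSectionPlane(ax, off))
        pts.append(_subsample_loop(loops[0], n))
    return ConstraintPointSet(np.concatenate(pts))
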