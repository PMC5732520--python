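import numpy as np
import pytest
import trimesh

from femstrength import Surface, tetrahedralize, uniform_materials
from femstrength.nonlinear_fea import assemble, solve_constrained


def box_surface(lx, ly, lz, z0=0.0):
    tm = trimesh.creation.box(extents=[lx, ly, lz])
    tm.apply_translation([0, 0, z0 + lz / 2.0])
    return Surface(np.asarray(tm.vertices), np.asarray(tm.faces))


def sphere_surface(radius=10.0, subdivisions=4):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return Surface(np.asarray(tm.vertices), np.asarray(tm.faces))


def cylinder_surface(radius, length, sections=64):
    tm = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
    tm.apply_translation([0, 0, length / 2.0])
    return Surface(np.asarray(tm.vertices), np.asarray(tm.faces))


def axial_bar_stiffness(mesh, materials, prescribed=0.1):
    """Reaction/displacement for a z-aligned bar with free lateral faces.

    Ends carry axial-only constraints plus minimal pins against the lateral
    rigid-body modes, so a homogeneous bar reproduces EA/L exactly.
    """
    z = mesh.nodes[:, 2]
    bot = np.where(z < z.min() + 1e-6)[0]
    top = np.where(z > z.max() - 1e-6)[0]
    k, _ = assemble(mesh, materials)
    dofs = np.concatenate(
        [3 * bot + 2, 3 * top + 2, [3 * bot[0], 3 * bot[0] + 1, 3 * bot[1] + 1]]
    )
    vals = np.concatenate(
        [np.zeros(bot.size), np.full(top.size, -prescribed), np.zeros(3)]
    )
    u = solve_constrained(k, dofs, vals)
    f = k @ u
    return float(-f[3 * top + 2].sum() / prescribed)


@pytest.fixture(scope="session")
def bar_mesh_coarse():
    """10 x 10 x 100 mm bar meshed at 3 mm edge (exact box geometry)."""
    return tetrahedralize(box_surface(10, 10, 100), target_edge=3.0)


@pytest.fixture(scope="session")
def cube_mesh():
    """20 mm cube at 1.5 mm edge."""
    return tetrahedralize(box_surface(20, 20, 20), target_edge=1.5)


@pytest.fixture(scope="session")
def bar_elastic(bar_mesh_coarse):
    return uniform_materials(bar_mesh_coarse, E=1000.0, nu=0.3)
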