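"""Shared fixtures: phantoms and their (expensive) Laplace solutions."""

import numpy as np
import pytest

from swmprof.geometry_io import TriangleMesh, make_icosphere
from swmprof.laplace_swm import solve_laplace
from swmprof.phantom import PhantomSpec, make_shell_phantom, make_slab_phantom


@pytest.fixture(scope="session")
def slab():
    return make_slab_phantom()


@pytest.fixture(scope="session")
def slab_field(slab):
    return solve_laplace(slab.seg, tolerance=1e-6, boundary_distance=slab.boundary_distance)


@pytest.fixture(scope="session")
def shell():
    return make_shell_phantom()


@pytest.fixture(scope="session")
def shell_field(shell):
    # ~1 min at 120^3 voxels; reused by solver, placement and acceptance tests
    return solve_laplace(shell.seg, tolerance=1e-6, boundary_distance=shell.boundary_distance)


@pytest.fixture(scope="session")
def icosphere3():
    return make_icosphere(subdivisions=3)


@pytest.fixture()
def torus_mesh():
    """Flat torus triangulation: every vertex has degree 6 (regular mesh)."""
    n, m = 8, 9
    verts = np.zeros((n * m, 3))
    for i in range(n):
        for j in range(m):
            theta, phi = 2 * np.pi * i / n, 2 * np.pi * j / m
            verts[i * m + j] = [
                (2 + 0.5 * np.cos(phi)) * np.cos(theta),
                (2 + 0.5 * np.cos(phi)) * np.sin(theta),
                0.5 * np.sin(phi),
            ]
    faces = []
    for i in range(n):
        for j in range(m):
            a = i * m + j
            b = ((i + 1) % n) * m + j
            c = ((i + 1) % n) * m + (j + 1) % m
            d = i * m + (j + 1) % m
            faces.append([a, b, c])
            faces.append([a, c, d])
    return TriangleMesh(vertices=verts, faces=np.array(faces))


@pytest.fixture(scope="session")
def invivo_slab_stack(slab, slab_field):
    from swmprof.laplace_swm import DepthSpec, shift_surface

    return shift_surface(slab.gm_wm_mesh, slab_field, DepthSpec.invivo())


@pytest.fixture(scope="session")
def histology_shell_stack(shell, shell_field):
    from swmprof.laplace_swm import DepthSpec, shift_surface

    return shift_surface(shell.gm_wm_mesh, shell_field, DepthSpec.histology())
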