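import math

import numpy as np
import pytest

from intcoords import (
    CartesianGeometry,
    InternalSystem,
    angle,
    dihedral,
    distance,
    make_fixture,
)


@pytest.fixture
def water():
    return make_fixture("water")


@pytest.fixture
def water_system():
    return InternalSystem(
        [distance(1, 0), distance(2, 0), angle(1, 0, 2)], completeness="complete"
    )


@pytest.fixture
def chain4():
    return make_fixture("chain4")


@pytest.fixture
def chain4_system():
    return InternalSystem(
        [
            distance(0, 1),
            distance(1, 2),
            distance(2, 3),
            angle(0, 1, 2),
            angle(1, 2, 3),
            dihedral(0, 1, 2, 3),
        ],
        completeness="complete",
    )


def random_geometry(rng, n_atoms=4, min_sep=0.7):
    """Random nondegenerate cluster: rejection-sample until well separated."""
    while True:
        pts = rng.normal(scale=1.2, size=(n_atoms, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d[np.diag_indices(n_atoms)] = np.inf
        if d.min() > min_sep:
            # also avoid near-collinear triples (degenerate angles/dihedrals)
            ok = True
            for i in range(n_atoms):
                for j in range(n_atoms):
                    for k in range(n_atoms):
                        if len({i, j, k}) < 3:
                            continue
                        a = pts[i] - pts[j]
                        b = pts[k] - pts[j]
                        sin = np.linalg.norm(np.cross(a, b)) / (
                            np.linalg.norm(a) * np.linalg.norm(b)
                        )
                        if sin < 0.2:
                            ok = False
            if ok:
                return CartesianGeometry(["C"] * n_atoms, pts)


def richardson_diff(func, x0, h=1e-4):
    """5-point central difference of an array-valued function along every
    component of ``x0``; returns an array with one leading axis per input
    component."""
    x0 = np.asarray(x0, dtype=float)
    out = None
    for i in range(x0.size):
        e = np.zeros_like(x0)
        e[i] = h
        val = (
            -func(x0 + 2 * e) + 8 * func(x0 + e) - 8 * func(x0 - e) + func(x0 - 2 * e)
        ) / (12 * h)
        if out is None:
            out = np.zeros((x0.size,) + np.shape(val))
        out[i] = val
    return out


def rotation_matrix(axis, theta):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)
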