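"""Primitive internal coordinates and their Cartesian derivative tensors.

Distances, valence angles and dihedral (torsion) angles are evaluated and
differentiated to arbitrary order.  Every coordinate is a short pipeline of
difference vectors, cross/dot products, vector norms and a final ``atan2``
(or ``arcsin`` for the planar dihedral branch), written in jet arithmetic,
so one engine covers values and all derivative orders:

* ``r_ij = |x_i - x_j|``
* ``θ_ijk = atan2(|a×b|, a·b)`` with ``a = x_i - x_j``, ``b = x_k - x_j``
* ``τ_ijkl = atan2(|u2|·(n1·u3), n1·n2)`` with ``u1 = x_j - x_i``,
  ``u2 = x_k - x_j``, ``u3 = x_l - x_k``, ``n1 = u1×u2``, ``n2 = u2×u3``

The two-argument arctangent is numerically stable near 0 and π and carries
the right-handed sign convention of the normals ``n_ijk = (x_j-x_i)×(x_k-x_j)``.
Angles are in radians, lengths in Å.

Derivative tensors live on the participating atoms' Cartesian blocks only;
they are stored densely in that reduced space and scattered into the full
3N space on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateGeometryError
from .jets import Jet, jet_atan2, jet_cross, jet_dot, jet_norm, seed_variables
from .tensor_calculus import DerivativeExpansion

__all__ = [
    "ATOMIC_MASSES",
    "CartesianGeometry",
    "CoordinateDef",
    "distance",
    "angle",
    "dihedral",
    "linear_combination",
    "scalar_function",
    "coordinate_value",
    "coordinate_derivatives",
    "planar_dihedral_derivatives",
]

# CODATA-style standard atomic weights (amu); overridable per geometry.
ATOMIC_MASSES = {
    "X": 0.0,  # dummy
    "H": 1.00782503, "D": 2.01410178, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.0,
    "N": 14.0030740, "O": 15.9949146, "F": 18.9984032, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973762, "S": 31.9720707, "Cl": 34.96885268, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Fe": 55.845, "Ni": 58.6934,
    "Cu": 63.546, "Zn": 65.38, "Br": 78.9183376, "Mo": 97.9054082,
    "I": 126.90447,
}

DEFAULT_BOND_TOL = 1e-10  # Å; shorter difference vectors are degenerate
DEFAULT_SIN_TOL = 1e-10  # |sin θ| below this flags collinear flanking atoms


@dataclass
class CartesianGeometry:
    """Atoms, masses (amu) and N×3 coordinates (Å)."""

    atoms: List[str]
    coords: np.ndarray
    masses: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atoms) != self.coords.shape[0]:
            raise ValueError("atom count does not match coordinate rows")
        if self.masses is None:
            try:
                self.masses = np.array([ATOMIC_MASSES[a] for a in self.atoms])
            except KeyError as exc:
                raise ValueError(f"no built-in mass for element {exc}; supply masses")
        else:
            self.masses = np.asarray(self.masses, dtype=float).ravel()
            if self.masses.size != len(self.atoms):
                raise ValueError("mass count does not match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses < 0):
            raise ValueError("negative masses")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_cartesian(self) -> int:
        return 3 * self.n_atoms

    def flat(self) -> np.ndarray:
        """Atom-major flattening: index = 3*atom + axis."""
        return self.coords.reshape(-1)

    def with_coords(self, coords: np.ndarray) -> "CartesianGeometry":
        return CartesianGeometry(self.atoms, np.asarray(coords, float).reshape(-1, 3), self.masses)

    def is_linear(self, tol: float = 1e-8) -> bool:
        """Moment-of-inertia test for linearity (amu·Å² eigenvalue cutoff)."""
        x = self.coords - np.average(self.coords, axis=0, weights=np.maximum(self.masses, 1e-30))
        inertia = np.einsum("i,ix,iy->xy", self.masses, x, x)
        full = np.trace(inertia) * np.eye(3) - inertia
        return bool(np.linalg.eigvalsh(full)[0] < tol)


@dataclass(frozen=True)
class CoordinateDef:
    """One internal coordinate.

    ``kind`` is one of ``distance | angle | dihedral | linear_combination |
    scalar_function``.  Primitives carry 2/3/4 distinct 0-based atom
    indices; a linear combination carries ``terms`` of (CoordinateDef,
    coefficient) pairs; a scalar function carries argument CoordinateDefs
    plus a jet-differentiable callable.
    """

    kind: str
    atom_indices: Tuple[int, ...] = ()
    terms: Tuple[Tuple["CoordinateDef", float], ...] = ()
    args: Tuple["CoordinateDef", ...] = ()
    func: Optional[Callable] = None
    label: str = ""

    _N_ATOMS = {"distance": 2, "angle": 3, "dihedral": 4}

    def __post_init__(self):
        if self.kind in self._N_ATOMS:
            n = self._N_ATOMS[self.kind]
            if len(self.atom_indices) != n:
                raise ValueError(f"{self.kind} needs {n} atom indices")
            if len(set(self.atom_indices)) != n:
                raise ValueError(f"{self.kind} atom indices must be distinct")
            if any(i < 0 for i in self.atom_indices):
                raise ValueError("atom indices must be non-negative")
        elif self.kind == "linear_combination":
            if not self.terms:
                raise ValueError("linear_combination needs terms")
            if not all(np.isfinite(c) for _, c in self.terms):
                raise ValueError("non-finite coefficient")
        elif self.kind == "scalar_function":
            if self.func is None or not self.args:
                raise ValueError("scalar_function needs args and a callable")
        else:
            raise ValueError(f"unknown coordinate kind {self.kind!r}")

    def involved_atoms(self) -> Tuple[int, ...]:
        if self.kind in self._N_ATOMS:
            return self.atom_indices
        seen: List[int] = []
        children = [t[0] for t in self.terms] if self.kind == "linear_combination" else list(self.args)
        for child in children:
            for a in child.involved_atoms():
                if a not in seen:
                    seen.append(a)
        return tuple(seen)

    def describe(self) -> str:
        if self.label:
            return self.label
        if self.kind in self._N_ATOMS:
            short = {"distance": "r", "angle": "theta", "dihedral": "tau"}[self.kind]
            return f"{short}({','.join(map(str, self.atom_indices))})"
        return self.kind


def distance(i: int, j: int, label: str = "") -> CoordinateDef:
    return CoordinateDef("distance", (i, j), label=label)


def angle(i: int, j: int, k: int, label: str = "") -> CoordinateDef:
    """Valence angle at the central atom ``j``."""
    return CoordinateDef("angle", (i, j, k), label=label)


def dihedral(i: int, j: int, k: int, l: int, label: str = "") -> CoordinateDef:
    return CoordinateDef("dihedral", (i, j, k, l), label=label)


def linear_combination(
    terms: Sequence[Tuple[CoordinateDef, float]], label: str = ""
) -> CoordinateDef:
    return CoordinateDef("linear_combination", terms=tuple((d, float(c)) for d, c in terms), label=label)


def scalar_function(
    args: Sequence[CoordinateDef], func: Callable, label: str = ""
) -> CoordinateDef:
    """A differentiable scalar function of other coordinates.

    ``func`` receives one :class:`~intcoords.jets.Jet` per argument
    coordinate and must return a Jet built from jet arithmetic; its own
    derivative rules then propagate exactly to every order.
    """
    return CoordinateDef("scalar_function", args=tuple(args), func=func, label=label)


# ---------------------------------------------------------------------------
# jet pipelines for the primitives
# ---------------------------------------------------------------------------

def _atom_jets(points: np.ndarray, K: int) -> List[List[Jet]]:
    jets = seed_variables(points.reshape(-1), K)
    return [jets[3 * i : 3 * i + 3] for i in range(points.shape[0])]


def _diff(a: Sequence[Jet], b: Sequence[Jet]) -> List[Jet]:
    return [x - y for x, y in zip(a, b)]


def _check_vector(v: np.ndarray, what: str, tol: float = DEFAULT_BOND_TOL) -> None:
    if np.linalg.norm(v) < tol:
        raise DegenerateGeometryError(f"zero-length {what} vector {np.round(v, 12)}")


def _distance_jet(points: np.ndarray, K: int) -> Jet:
    _check_vector(points[0] - points[1], "bond (x_i - x_j)")
    xi, xj = _atom_jets(points, K)
    return jet_norm(_diff(xi, xj))


def _angle_jet(points: np.ndarray, K: int) -> Jet:
    av = points[0] - points[1]
    bv = points[2] - points[1]
    _check_vector(av, "arm (x_i - x_j)")
    _check_vector(bv, "arm (x_k - x_j)")
    xi, xj, xk = _atom_jets(points, K)
    a = _diff(xi, xj)
    b = _diff(xk, xj)
    u = jet_cross(a, b)
    if K >= 1 and np.linalg.norm(np.cross(av, bv)) < DEFAULT_SIN_TOL * np.linalg.norm(av) * np.linalg.norm(bv):
        # |a×b| is not differentiable at collinearity
        raise DegenerateGeometryError("angle at 0 or π: arms are collinear")
    return jet_atan2(jet_norm(u), jet_dot(a, b))


def _dihedral_chain(points: np.ndarray, K: int, sin_tol: float):
    u1v = points[1] - points[0]
    u2v = points[2] - points[1]
    u3v = points[3] - points[2]
    for v, name in ((u1v, "x_j - x_i"), (u2v, "x_k - x_j"), (u3v, "x_l - x_k")):
        _check_vector(v, name)
    n1v = np.cross(u1v, u2v)
    n2v = np.cross(u2v, u3v)
    for nv, pair in ((n1v, "i-j-k"), (n2v, "j-k-l")):
        if np.linalg.norm(nv) < sin_tol * np.prod([np.linalg.norm(x) for x in (u1v, u2v)]):
            raise DegenerateGeometryError(
                f"dihedral flanking angle {pair} within tolerance of 0 or π (|sin| < {sin_tol})"
            )
    xi, xj, xk, xl = _atom_jets(points, K)
    u1 = _diff(xj, xi)
    u2 = _diff(xk, xj)
    u3 = _diff(xl, xk)
    n1 = jet_cross(u1, u2)
    n2 = jet_cross(u2, u3)
    s = jet_norm(u2) * jet_dot(n1, u3)  # |u2| · det[u1,u2,u3]
    c = jet_dot(n1, n2)
    return s, c, n1, n2


def _dihedral_jet(points: np.ndarray, K: int, sin_tol: float = DEFAULT_SIN_TOL) -> Jet:
    s, c, _, _ = _dihedral_chain(points, K, sin_tol)
    return jet_atan2(s, c)


def _planar_dihedral_jet(points: np.ndarray, K: int, sin_tol: float = DEFAULT_SIN_TOL) -> Jet:
    """Arcsin-of-sine branch, finite at exactly planar configurations.

    ``sin τ = S / (|n1||n2|)`` is smooth through τ = 0 and τ = ±π where the
    arctan expression's sine part has a cusp-free zero; near trans the
    branch value ``π − arcsin(sin τ)`` continues smoothly past π.
    """
    s, c, n1, n2 = _dihedral_chain(points, K, sin_tol)
    sin_tau = s * (jet_norm(n1) * jet_norm(n2)).reciprocal()
    asin_jet = sin_tau.asin()
    if c.value >= 0.0:  # cis-like branch, τ near 0
        return asin_jet
    return math.pi - asin_jet  # trans-like branch, τ near ±π


_PRIMITIVE_JETS = {
    "distance": _distance_jet,
    "angle": _angle_jet,
    "dihedral": _dihedral_jet,
}


def _coordinate_jet(defn: CoordinateDef, geom: CartesianGeometry, K: int) -> Tuple[Jet, Tuple[int, ...]]:
    """Jet of the coordinate in the reduced space of its involved atoms."""
    atoms = defn.involved_atoms()
    sub = geom.coords[list(atoms)]
    if defn.kind in _PRIMITIVE_JETS:
        return _PRIMITIVE_JETS[defn.kind](sub, K), atoms
    if defn.kind == "linear_combination":
        acc: Optional[Jet] = None
        for child, coeff in defn.terms:
            child_jet = _embed_child_jet(child, geom, K, atoms)
            acc = child_jet * coeff if acc is None else acc + child_jet * coeff
        return acc, atoms
    if defn.kind == "scalar_function":
        arg_jets = [_embed_child_jet(arg, geom, K, atoms) for arg in defn.args]
        return defn.func(*arg_jets), atoms
    raise ValueError(defn.kind)


def _embed_child_jet(child: CoordinateDef, geom: CartesianGeometry, K: int, atoms: Tuple[int, ...]) -> Jet:
    """Re-express a child coordinate's jet in the parent's reduced space."""
    cjet, catoms = _coordinate_jet(child, geom, K)
    d = 3 * len(atoms)
    pos = {a: i for i, a in enumerate(atoms)}
    idx = np.concatenate([[3 * pos[a], 3 * pos[a] + 1, 3 * pos[a] + 2] for a in catoms]).astype(int)
    derivs = []
    for k in range(1, K + 1):
        t = np.zeros((d,) * k)
        t[np.ix_(*([idx] * k))] = cjet.derivs[k - 1]
        derivs.append(t)
    return Jet(cjet.value, derivs, d, K)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def coordinate_value(defn: CoordinateDef, geom: CartesianGeometry) -> float:
    """Value of the coordinate (Å or radians)."""
    if defn.kind == "distance":
        i, j = defn.atom_indices
        v = geom.coords[i] - geom.coords[j]
        _check_vector(v, "bond (x_i - x_j)")
        return float(np.linalg.norm(v))
    if defn.kind == "angle":
        i, j, k = defn.atom_indices
        a = geom.coords[i] - geom.coords[j]
        b = geom.coords[k] - geom.coords[j]
        _check_vector(a, "arm (x_i - x_j)")
        _check_vector(b, "arm (x_k - x_j)")
        return float(math.atan2(np.linalg.norm(np.cross(a, b)), float(a @ b)))
    if defn.kind == "dihedral":
        i, j, k, l = defn.atom_indices
        u1 = geom.coords[j] - geom.coords[i]
        u2 = geom.coords[k] - geom.coords[j]
        u3 = geom.coords[l] - geom.coords[k]
        for v, name in ((u1, "x_j - x_i"), (u2, "x_k - x_j"), (u3, "x_l - x_k")):
            _check_vector(v, name)
        n1 = np.cross(u1, u2)
        n2 = np.cross(u2, u3)
        if min(np.linalg.norm(n1), np.linalg.norm(n2)) < DEFAULT_SIN_TOL:
            raise DegenerateGeometryError("dihedral with collinear flanking atoms")
        s = np.linalg.norm(u2) * float(n1 @ u3)
        return float(math.atan2(s, float(n1 @ n2)))
    if defn.kind == "linear_combination":
        return float(sum(c * coordinate_value(d, geom) for d, c in defn.terms))
    if defn.kind == "scalar_function":
        jet, _ = _coordinate_jet(defn, geom, 1)
        return jet.value
    raise ValueError(defn.kind)


@dataclass
class SparseCoordinateExpansion:
    """Per-coordinate derivative tensors on the involved-atom block.

    ``tensors[k]`` has shape ``(3n,)*k`` with ``n = len(atoms)``; the full
    3N-space tensor is sparse outside these blocks and is densified on
    demand.
    """

    value: float
    atoms: Tuple[int, ...]
    tensors: List[np.ndarray] = field(default_factory=list)

    def cartesian_indices(self) -> np.ndarray:
        return np.concatenate([[3 * a, 3 * a + 1, 3 * a + 2] for a in self.atoms]).astype(int)

    def densify(self, n_cartesian: int, order: int) -> np.ndarray:
        idx = self.cartesian_indices()
        t = np.zeros((n_cartesian,) * order)
        t[np.ix_(*([idx] * order))] = self.tensors[order - 1]
        return t


def coordinate_derivatives(
    defn: CoordinateDef, geom: CartesianGeometry, order: int, dense: bool = True
):
    """Cartesian derivative tensors of one coordinate, orders ``1..order``.

    With ``dense=True`` returns a :class:`DerivativeExpansion` over the full
    3N Cartesian space (target_dim 1, trailing axis kept); otherwise the
    sparse per-atom-block form.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    jet, atoms = _coordinate_jet(defn, geom, order)
    sparse = SparseCoordinateExpansion(jet.value, atoms, jet.derivs)
    if not dense:
        return sparse
    n = geom.n_cartesian
    tensors = {k: sparse.densify(n, k)[..., None] for k in range(1, order + 1)}
    return DerivativeExpansion(
        "forward", n, 1, tensors, reference=geom.flat(), validate=False
    )


def planar_dihedral_derivatives(
    defn: CoordinateDef,
    geom: CartesianGeometry,
    order: int,
    dense: bool = True,
    window: float = 1e-2,
):
    """Dihedral derivatives on the arcsin branch, for use near τ = 0 or ±π.

    ``window`` (radians) is the configurable half-width around planarity in
    which this branch is intended; outside it the arctan branch is
    preferred, but the two agree wherever both are defined.
    """
    if defn.kind != "dihedral":
        raise ValueError("planar branch applies to dihedral coordinates")
    if order < 1:
        raise ValueError("order must be >= 1")
    atoms = defn.atom_indices
    sub = geom.coords[list(atoms)]
    jet = _planar_dihedral_jet(sub, order)
    sparse = SparseCoordinateExpansion(jet.value, atoms, jet.derivs)
    if not dense:
        return sparse
    n = geom.n_cartesian
    tensors = {k: sparse.densify(n, k)[..., None] for k in range(1, order + 1)}
    return DerivativeExpansion("forward", n, 1, tensors, reference=geom.flat(), validate=False)
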