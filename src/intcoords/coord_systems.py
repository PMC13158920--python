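"""Whole-system forward transformations, conversions between internal
coordinate systems, and constructed coordinates.

A complete nonredundant system has 3N-6 coordinates (3N-5 for a linear
molecule) whose first-derivative stack — the Wilson B matrix, here stored
transposed as a (3N, m) array — has full column rank at the reference
geometry.  Conversions between systems chain triangle (side-angle-side →
side-side-side) and four-atom-chain closures over the shared atom graph,
with derivatives carried by jet arithmetic so the conversion itself is
differentiable to any order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ConversionGraphError, IncompleteSystemError
from .jets import Jet, seed_variables
from .primitives import (
    CartesianGeometry,
    CoordinateDef,
    SparseCoordinateExpansion,
    coordinate_derivatives,
    coordinate_value,
    linear_combination,
)
from .tensor_calculus import DerivativeExpansion

__all__ = [
    "InternalSystem",
    "system_values",
    "system_derivatives",
    "triangle_complete",
    "dihedral_complete",
    "convert_systems",
    "symmetric_combination",
    "delocalize",
    "relocalize",
    "direct_mode_coordinate",
]

DEFAULT_RANK_CUTOFF = 1e-8  # relative singular-value cutoff for rank decisions


@dataclass
class InternalSystem:
    """Ordered set of internal coordinates (an R, Q or S system)."""

    coords: List[CoordinateDef]
    label: str = ""
    completeness: str = "unknown"  # complete | redundant | partial | unknown

    def __post_init__(self):
        keys = [_canonical_key(c) for c in self.coords if c.kind in ("distance", "angle", "dihedral")]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate coordinate definitions in system")

    def __len__(self) -> int:
        return len(self.coords)

    def __iter__(self):
        return iter(self.coords)

    def labels(self) -> List[str]:
        return [c.describe() for c in self.coords]


def system_values(sys: InternalSystem, geom: CartesianGeometry) -> np.ndarray:
    return np.array([coordinate_value(c, geom) for c in sys.coords])


def system_derivatives(
    sys: InternalSystem, geom: CartesianGeometry, order: int
) -> DerivativeExpansion:
    """Forward expansion X→R: order-k tensor of shape (3N,)*k × m.

    The trailing axis indexes coordinates in system order; each slice equals
    the per-coordinate tensors.
    """
    n = geom.n_cartesian
    m = len(sys.coords)
    tensors = {k: np.zeros((n,) * k + (m,)) for k in range(1, order + 1)}
    for q, defn in enumerate(sys.coords):
        try:
            sparse: SparseCoordinateExpansion = coordinate_derivatives(defn, geom, order, dense=False)
        except Exception as exc:
            raise type(exc)(f"coordinate {q} ({defn.describe()}): {exc}") from exc
        idx = sparse.cartesian_indices()
        for k in range(1, order + 1):
            block = tensors[k][..., q]
            block[np.ix_(*([idx] * k))] = sparse.tensors[k - 1]
    return DerivativeExpansion("forward", n, m, tensors, reference=geom.flat(), validate=False)


def b_matrix(sys: InternalSystem, geom: CartesianGeometry) -> np.ndarray:
    """Wilson B matrix stack, shape (3N, m): column q is ∇_X of coordinate q."""
    return system_derivatives(sys, geom, 1)[1]


def check_complete(
    sys: InternalSystem, geom: CartesianGeometry, cutoff: float = DEFAULT_RANK_CUTOFF
) -> int:
    """Rank of the order-1 stack; raises if below 3N-6 (3N-5 linear)."""
    B = b_matrix(sys, geom)
    sv = np.linalg.svd(B, compute_uv=False)
    rank = int(np.sum(sv > cutoff * sv[0]))
    need = geom.n_cartesian - (5 if geom.is_linear() else 6)
    if rank < need:
        raise IncompleteSystemError(f"system rank {rank} < required {need}")
    return rank


# ---------------------------------------------------------------------------
# completions: triangle and four-atom chain closure
# ---------------------------------------------------------------------------

def _law_of_cosines_jet(r_ij: Jet, r_jk: Jet, theta: Jet) -> Jet:
    return (r_ij * r_ij + r_jk * r_jk - 2.0 * r_ij * r_jk * theta.cos()).sqrt()


def triangle_complete(
    r_ij: float, r_jk: float, theta_ijk: float, order: int = 1
) -> Tuple[float, List[np.ndarray]]:
    """Third triangle side from side-angle-side, with derivatives.

    ``r_ik = sqrt(r_ij² + r_jk² − 2 r_ij r_jk cos θ)``; derivative tensors
    of orders ``1..order`` w.r.t. the inputs ``(r_ij, r_jk, θ_ijk)``.
    """
    if r_ij <= 0 or r_jk <= 0:
        raise ValueError("triangle sides must be positive")
    if not (0.0 < theta_ijk <= math.pi):
        raise ValueError("angle must lie in (0, π]")
    jr1, jr2, jth = seed_variables([r_ij, r_jk, theta_ijk], order)
    out = _law_of_cosines_jet(jr1, jr2, jth)
    return out.value, out.derivs


def _angle_from_sides_jet(r_ij: Jet, r_jk: Jet, r_ik: Jet) -> Jet:
    cos_th = (r_ij * r_ij + r_jk * r_jk - r_ik * r_ik) * (2.0 * r_ij * r_jk).reciprocal()
    return cos_th.acos()


def _chain_embedding_jets(
    r_ij: Jet, r_jk: Jet, r_kl: Jet, th_ijk: Jet, th_jkl: Jet, tau: Jet
) -> List[List[Jet]]:
    """Canonical Cartesian embedding of the 4-atom chain i-j-k-l as jets.

    j at origin, k on +x, i in the xy-plane with positive y; l placed from
    (r_kl, θ_jkl, τ) in the frame at k.  The construction is chosen so the
    dihedral of the embedded chain equals ``tau`` with the right-handed
    sign convention of the primitives.
    """
    K, d = r_ij.K, r_ij.d
    zero = Jet.constant(0.0, d, K)
    j = [zero, zero, zero]
    k = [r_jk, zero, zero]
    i = [r_ij * th_ijk.cos(), r_ij * th_ijk.sin(), zero]
    # frame at k: e1 = towards j = (-1,0,0); e2 = (0,1,0); e3 = e1×e2 = (0,0,-1)
    lx = r_jk - r_kl * th_jkl.cos()
    ly = r_kl * th_jkl.sin() * tau.cos()
    lz = r_kl * th_jkl.sin() * tau.sin()
    l = [lx, ly, lz]
    return [i, j, k, l]


def dihedral_complete(
    r_ij: float,
    r_jk: float,
    r_kl: float,
    theta_ijk: float,
    theta_jkl: float,
    tau_ijkl: float,
    order: int = 1,
) -> Tuple[float, List[np.ndarray]]:
    """Chain-closure distance ``r_il`` of the 4-atom chain, with derivatives.

    Computed from the exact Cartesian embedding of the chain (place j, k, i,
    l canonically and take |x_i − x_l|), differentiated w.r.t. the six
    inputs in the order given.
    """
    for r, name in ((r_ij, "r_ij"), (r_jk, "r_jk"), (r_kl, "r_kl")):
        if r <= 0:
            raise ValueError(f"{name} must be positive")
    for th, name in ((theta_ijk, "theta_ijk"), (theta_jkl, "theta_jkl")):
        if not (0.0 < th < math.pi):
            raise ValueError(f"{name} must lie in (0, π)")
    jets = seed_variables([r_ij, r_jk, r_kl, theta_ijk, theta_jkl, tau_ijkl], order)
    i, j, k, l = _chain_embedding_jets(*jets)
    diff = [a - b for a, b in zip(i, l)]
    out = (diff[0] * diff[0] + diff[1] * diff[1] + diff[2] * diff[2]).sqrt()
    return out.value, out.derivs


# ---------------------------------------------------------------------------
# conversion between systems
# ---------------------------------------------------------------------------

def _canonical_key(c: CoordinateDef):
    a = c.atom_indices
    if c.kind == "distance":
        return ("distance", tuple(sorted(a)))
    if c.kind == "angle":
        (i, j, k) = a
        return ("angle", (min(i, k), j, max(i, k)))
    if c.kind == "dihedral":
        # τ is invariant under chain reversal; orient the middle bond upward
        (i, j, k, l) = a
        return ("dihedral", (l, k, j, i) if j > k else (i, j, k, l))
    raise ValueError(f"cannot canonicalize {c.kind}")


def convert_systems(
    source_vals: Sequence[float],
    source: InternalSystem,
    target: InternalSystem,
    order: int = 1,
) -> Tuple[np.ndarray, DerivativeExpansion]:
    """Values and derivatives of ``target`` coordinates w.r.t. ``source`` ones.

    Propagates jets seeded on the source values through a breadth-first
    closure of completion rules (law-of-cosines distance, angle-from-sides,
    chain-closure distance, dihedral-from-distances) until every target
    coordinate is known.  Deterministic: rules applied in fixed priority
    order, candidates in lexicographic atom order.

    A dihedral recovered from distances carries the sign of the matching
    source dihedral when one exists, else it is taken positive (a mirror
    image cannot be distinguished by distances alone).
    """
    source_vals = np.asarray(source_vals, dtype=float)
    if source_vals.size != len(source.coords):
        raise ValueError("source value count mismatch")
    m = len(source.coords)
    jets = seed_variables(source_vals, order)
    known: Dict[tuple, Jet] = {}
    sign_hints: Dict[tuple, float] = {}
    for c, j in zip(source.coords, jets):
        if c.kind not in ("distance", "angle", "dihedral"):
            raise ConversionGraphError("conversion handles primitive coordinates only")
        key = _canonical_key(c)
        known[key] = j
        if c.kind == "dihedral":
            sign_hints[key] = 1.0 if j.value >= 0 else -1.0

    def get(kind, atoms):
        return known.get((kind, atoms))

    def have_angle(i, j, k):
        return get("angle", (min(i, k), j, max(i, k)))

    def have_dist(i, j):
        return get("distance", tuple(sorted((i, j))))

    changed = True
    while changed:
        changed = False
        atoms_seen = sorted({a for (kind, at) in known for a in at})
        # rule 1: SAS triangle -> third distance
        for (kind, at) in sorted(known):
            if kind != "angle":
                continue
            i, j, k = at
            if have_dist(i, j) and have_dist(j, k) and not have_dist(i, k):
                known[("distance", tuple(sorted((i, k))))] = _law_of_cosines_jet(
                    have_dist(i, j), have_dist(j, k), known[(kind, at)]
                )
                changed = True
        # rule 2: SSS -> angle
        for j in atoms_seen:
            for i in atoms_seen:
                for k in atoms_seen:
                    if len({i, j, k}) < 3 or i > k:
                        continue
                    if have_angle(i, j, k):
                        continue
                    if have_dist(i, j) and have_dist(j, k) and have_dist(i, k):
                        known[("angle", (min(i, k), j, max(i, k)))] = _angle_from_sides_jet(
                            have_dist(i, j), have_dist(j, k), have_dist(i, k)
                        )
                        changed = True
        # rule 3: chain closure -> distance r_il
        for (kind, at) in sorted(known):
            if kind != "dihedral":
                continue
            i, j, k, l = at
            if have_dist(i, l):
                continue
            needed = (
                have_dist(i, j),
                have_dist(j, k),
                have_dist(k, l),
                have_angle(i, j, k),
                have_angle(j, k, l),
            )
            if all(x is not None for x in needed):
                rij, rjk, rkl, th1, th2 = needed
                tau = known[(kind, at)]
                ijets = _chain_embedding_jets(rij, rjk, rkl, th1, th2, tau)
                diff = [a - b for a, b in zip(ijets[0], ijets[3])]
                known[("distance", tuple(sorted((i, l))))] = (
                    diff[0] * diff[0] + diff[1] * diff[1] + diff[2] * diff[2]
                ).sqrt()
                changed = True
        # rule 4: dihedral from distances (|τ| via the closure, sign from hints)
        for tc in target.coords:
            if tc.kind != "dihedral":
                continue
            key = _canonical_key(tc)
            if key in known:
                continue
            i, j, k, l = key[1]
            needed = (
                have_dist(i, j),
                have_dist(j, k),
                have_dist(k, l),
                have_angle(i, j, k),
                have_angle(j, k, l),
                have_dist(i, l),
            )
            if all(x is not None for x in needed):
                rij, rjk, rkl, th1, th2, ril = needed
                # r_il² = A − B cos τ  with A from the τ=π/2 embedding
                d = rij.d
                half_pi = Jet.constant(math.pi / 2.0, d, rij.K)
                emb = _chain_embedding_jets(rij, rjk, rkl, th1, th2, half_pi)
                diff = [a - b for a, b in zip(emb[0], emb[3])]
                A = diff[0] * diff[0] + diff[1] * diff[1] + diff[2] * diff[2]
                B = 2.0 * rij * th1.sin() * rkl * th2.sin()
                cos_tau = (A - ril * ril) * B.reciprocal()
                sign = sign_hints.get(key, 1.0)
                known[key] = cos_tau.acos() * sign
                changed = True

    values = np.empty(len(target.coords))
    tensors = {k: np.zeros((m,) * k + (len(target.coords),)) for k in range(1, order + 1)}
    missing = []
    for q, tc in enumerate(target.coords):
        key = _canonical_key(tc)
        jet = known.get(key)
        if jet is None:
            missing.append(tc.describe())
            continue
        values[q] = jet.value
        for k in range(1, order + 1):
            tensors[k][..., q] = jet.derivs[k - 1]
    if missing:
        raise ConversionGraphError(
            f"target coordinates unreachable from source via completions: {missing}"
        )
    expansion = DerivativeExpansion(
        "convert", m, len(target.coords), tensors, reference=source_vals, validate=False
    )
    return values, expansion


# ---------------------------------------------------------------------------
# constructed coordinates
# ---------------------------------------------------------------------------

def symmetric_combination(
    defs: Sequence[CoordinateDef], coefficients: Sequence[float], label: str = ""
) -> CoordinateDef:
    """Linear combination ``S = Σ c_i q_i`` of existing coordinates.

    Being linear, its derivatives w.r.t. the underlying coordinates vanish
    beyond first order; Cartesian derivatives follow by reexpansion (or
    directly through :func:`coordinate_derivatives`).
    """
    coefficients = [float(c) for c in coefficients]
    if len(defs) != len(coefficients):
        raise ValueError("defs/coefficients length mismatch")
    return linear_combination(list(zip(defs, coefficients)), label=label)


def delocalize(
    sys: InternalSystem,
    geom: CartesianGeometry,
    cutoff: float = DEFAULT_RANK_CUTOFF,
) -> Tuple[InternalSystem, np.ndarray]:
    """Delocalized internal coordinates from a redundant primitive set.

    The left singular vectors of the B-matrix stack with nonzero singular
    value give 3N-6 (3N-5 linear) orthonormal coefficient vectors spanning
    the row space of the stack.  Returns the new system (each coordinate a
    linear combination of the primitives) and the (k × m) coefficient
    matrix.
    """
    B = b_matrix(sys, geom)  # (3N, m)
    U, sv, Vt = np.linalg.svd(B.T, full_matrices=False)  # rows of B.T = coordinate gradients
    rank = int(np.sum(sv > cutoff * sv[0]))
    need = geom.n_cartesian - (5 if geom.is_linear() else 6)
    if rank < need:
        raise IncompleteSystemError(
            f"redundant set spans only rank {rank} < {need}"
        )
    C = U[:, :rank].T  # (rank, m) orthonormal rows
    # deterministic sign convention: largest-magnitude entry positive
    for row in C:
        pivot = np.argmax(np.abs(row))
        if row[pivot] < 0:
            row *= -1.0
    combos = [
        symmetric_combination(sys.coords, C[i], label=f"deloc_{i}") for i in range(rank)
    ]
    return InternalSystem(combos, label=f"deloc({sys.label})", completeness="complete"), C


def _combo_matrix(deloc: InternalSystem, primitives: List[CoordinateDef]) -> np.ndarray:
    index = {id(p): i for i, p in enumerate(primitives)}
    C = np.zeros((len(deloc.coords), len(primitives)))
    for r, c in enumerate(deloc.coords):
        if c.kind != "linear_combination":
            raise ValueError("relocalize expects linear-combination coordinates")
        for child, coeff in c.terms:
            if id(child) not in index:
                raise ValueError("delocalized coordinates must share one primitive set")
            C[r, index[id(child)]] = coeff
    return C


def relocalize(
    deloc: InternalSystem,
    protected: Sequence[CoordinateDef] = (),
    tol: float = 1e-10,
) -> Tuple[InternalSystem, np.ndarray]:
    """Orthogonal Procrustes relocalization of a delocalized set.

    Finds the orthogonal transformation U of the delocalized coefficient
    matrix C minimizing ``‖U·C − I‖_F`` so the transformation looks
    maximally like the identity, while any ``protected`` coordinates
    (linear combinations of the same primitives, e.g. a symmetric stretch)
    appear as pure rows with no mixing into the others.
    """
    first = deloc.coords[0]
    primitives = [t[0] for t in first.terms]
    C = _combo_matrix(deloc, primitives)
    k, m = C.shape

    prot_rows = []
    for p in protected:
        if p.kind == "linear_combination":
            vec = np.zeros(m)
            idx = {id(q): i for i, q in enumerate(primitives)}
            for child, coeff in p.terms:
                if id(child) not in idx:
                    raise ValueError("protected coordinate uses foreign primitives")
                vec[idx[id(child)]] = coeff
        else:
            vec = np.zeros(m)
            matched = [i for i, q in enumerate(primitives) if q is p or (
                q.kind == p.kind and q.atom_indices == p.atom_indices)]
            if not matched:
                raise ValueError("protected coordinate not among the primitives")
            vec[matched[0]] = 1.0
        # must lie in the delocalized span
        proj = C.T @ (C @ vec)
        if np.linalg.norm(proj - vec) > 1e-6 * max(1.0, np.linalg.norm(vec)):
            raise IncompleteSystemError("protected coordinate outside the delocalized span")
        prot_rows.append(vec / np.linalg.norm(vec))

    # orthonormalize protected rows (within span)
    P = np.array(prot_rows).reshape(len(prot_rows), m)
    if len(prot_rows):
        Q, _ = np.linalg.qr(P.T)
        P = Q.T[: len(prot_rows)]
        for r, orig in enumerate(prot_rows):  # keep the user's sign
            if P[r] @ orig < 0:
                P[r] *= -1.0

    # orthonormal basis of the unprotected subspace of the delocalized span
    comp = C - (C @ P.T) @ P if len(prot_rows) else C
    _, sv, Vt_c = np.linalg.svd(comp, full_matrices=False)
    n_rest = k - len(prot_rows)
    M = Vt_c[:n_rest]  # (n_rest, m), orthonormal rows

    # Orthogonal Procrustes: rotate M to look maximally like identity rows.
    # Target rows E are the unit axes the subspace covers best (projector
    # diagonal); R = argmin ‖R·M − E‖_F over orthogonal R via SVD of E·Mᵀ.
    proj_diag = np.einsum("rm,rm->m", M, M)
    axes = np.argsort(-proj_diag)[:n_rest]
    E = np.zeros_like(M)
    for r, ax in enumerate(sorted(axes)):
        E[r, ax] = 1.0
    Zu, _, Wv = np.linalg.svd(E @ M.T)
    new_rest = (Zu @ Wv) @ M

    newC = np.vstack([P, new_rest]) if len(prot_rows) else new_rest
    combos = []
    for i in range(k):
        lbl = f"protected_{i}" if i < len(prot_rows) else f"reloc_{i}"
        combos.append(symmetric_combination(primitives, newC[i], label=lbl))
    out = InternalSystem(combos, label=f"reloc({deloc.label})", completeness=deloc.completeness)
    # verify no-mixing contract for protected coordinates
    for i in range(len(prot_rows)):
        overlaps = np.abs(new_rest @ P[i])
        if overlaps.size and overlaps.max() > tol:
            raise RuntimeError("protected coordinate mixing above tolerance")
    return out, newC


def direct_mode_coordinate(
    sys: InternalSystem,
    geom: CartesianGeometry,
    displacement: np.ndarray,
    inverse_first_order: np.ndarray,
    mass_weighted: bool = True,
) -> Tuple[CoordinateDef, np.ndarray, float]:
    """Internal-coordinate combination maximally matching a displacement.

    Least-squares fit of the rows of ``∇_R X`` (``inverse_first_order``,
    shape (m, 3N)) to the target 3N displacement, optionally in
    mass-weighted coordinates.  Returns the combination, its coefficients
    and the residual norm of the fit.
    """
    d = np.asarray(displacement, dtype=float).ravel()
    A = np.asarray(inverse_first_order, dtype=float)
    if A.shape != (len(sys.coords), geom.n_cartesian):
        raise ValueError("inverse_first_order has wrong shape")
    if mass_weighted:
        w = np.sqrt(np.repeat(geom.masses, 3))
        A = A * w[None, :]
        d = d * w
    coeffs, *_ = np.linalg.lstsq(A.T, d, rcond=None)
    residual = float(np.linalg.norm(A.T @ coeffs - d))
    combo = symmetric_combination(sys.coords, coeffs, label="direct_mode")
    return combo, coeffs, residual
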