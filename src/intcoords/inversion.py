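"""Implicit construction of inverse derivative expansions.

For an invertible map between systems Q and R, differentiating the identity
``∇_R Q · ∇_Q R = I`` shows every higher derivative of the composite must
vanish; isolating the highest inverse derivative turns this into a
recursion that delivers ``∇_R^(k)Q`` from the forward tensors and the
first-order inverse alone — the same partition machinery as the forward
chain rule, term by term.

Cartesian ↔ internal transformations are not invertible as written (six
rigid-body directions are lost) but become invertible once the Cartesians
are confined to an Eckart frame: removing the components of ``∇_X^(k)R``
along the generators of translation and rotation and taking the
Moore–Penrose pseudoinverse of the projected first-order stack yields
``∇_R X`` for the Eckart-embedded structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .coord_systems import DEFAULT_RANK_CUTOFF, InternalSystem, system_derivatives
from .errors import IncompleteSystemError
from .primitives import CartesianGeometry
from .tensor_calculus import (
    DerivativeExpansion,
    _partition_term,
    _symmetrize_term,
    integer_partitions,
)

__all__ = [
    "EckartFrame",
    "invert_expansion",
    "eckart_project",
    "cartesian_by_internal",
    "given_cartesian_expansion",
    "eckart_embed",
]


@dataclass
class EckartFrame:
    """Orthonormalized translation/rotation generators of a reference structure.

    ``generators`` is a (g, 3N) array, g = 6 (5 for a linear reference),
    each row an orthonormal mass-weighted infinitesimal rigid-body
    displacement field.  With ``mass_weighted=False`` all masses are
    treated as equal, reducing to the geometric embedding.
    """

    reference: CartesianGeometry
    mass_weighted: bool = True
    generators: np.ndarray = None  # set in __post_init__

    def __post_init__(self):
        geom = self.reference
        n = geom.n_atoms
        masses = geom.masses if self.mass_weighted else np.ones(n)
        w = np.sqrt(masses)
        com = np.average(geom.coords, axis=0, weights=masses)
        x = geom.coords - com
        gens = []
        for ax in range(3):  # translations
            t = np.zeros((n, 3))
            t[:, ax] = w
            gens.append(t.reshape(-1))
        for ax in range(3):  # rotations about the principal axes origin
            e = np.zeros(3)
            e[ax] = 1.0
            r = np.cross(np.broadcast_to(e, (n, 3)), x) * w[:, None]
            gens.append(r.reshape(-1))
        G = np.array(gens)
        # orthonormalize; a linear molecule loses one rotation
        U, sv, Vt = np.linalg.svd(G, full_matrices=False)
        keep = sv > 1e-10 * sv[0]
        self.generators = Vt[: int(keep.sum())]
        expected = 5 if geom.is_linear() else 6
        if self.generators.shape[0] != expected:
            raise ValueError(
                f"found {self.generators.shape[0]} rigid-body generators, expected {expected}"
            )

    @property
    def projector(self) -> np.ndarray:
        """Projector onto the complement of the rigid-body span, (3N, 3N).

        Orthogonal in mass-weighted coordinates, where the generators live.
        """
        G = self.generators
        return np.eye(G.shape[1]) - G.T @ G

    @property
    def weights(self) -> np.ndarray:
        """Per-Cartesian-component √m factors mapping raw to mass-weighted axes."""
        masses = self.reference.masses if self.mass_weighted else np.ones(self.reference.n_atoms)
        return np.sqrt(np.repeat(masses, 3))


def invert_expansion(
    forward: DerivativeExpansion,
    first_inverse: Optional[np.ndarray] = None,
) -> DerivativeExpansion:
    """Derivative tensors of the inverse map from the forward expansion.

    ``forward`` holds ``∇_Q^(k)R`` for orders 1..K; ``first_inverse`` is
    ``∇_R Q`` (shape target×source).  If omitted the order-1 tensor must be
    square and invertible.  Order m of the inverse is minus the sum over
    the partitions of m other than (m) of the symmetrized mixed terms,
    contracted on the trailing axis with the first-order inverse — e.g.
    order 2 is ``−[R¹R¹R¹Q²]`` and order 3 adds the (ijk+ikj+kij)
    symmetrized cross term.
    """
    K = forward.order
    nq, nr = forward.source_dim, forward.target_dim
    F1 = forward[1]
    if first_inverse is None:
        if nq != nr:
            raise ValueError("non-square order-1 tensor requires an explicit first inverse")
        R1 = np.linalg.inv(F1)
    else:
        R1 = np.asarray(first_inverse, dtype=float)
        if R1.shape != (nr, nq):
            raise ValueError(f"first_inverse must have shape {(nr, nq)}")
    inv_tensors = {1: R1}
    for m in range(2, K + 1):
        acc = np.zeros((nr,) * m + (nr,))
        for p in integer_partitions(m):
            if p == (m,):
                continue
            term = _partition_term(p, inv_tensors, forward[len(p)], True)
            acc += _symmetrize_term(term, p, True)
        inv_tensors[m] = -np.einsum("...r,rq->...q", acc, R1)
    ref = None
    return DerivativeExpansion("inverse", nr, nq, inv_tensors, reference=ref, validate=False)


def _scale_leading_axes(t: np.ndarray, k: int, factors: np.ndarray) -> np.ndarray:
    out = t
    for axis in range(k):
        shape = [1] * t.ndim
        shape[axis] = factors.size
        out = out * factors.reshape(shape)
    return out


def eckart_project(
    expansion: DerivativeExpansion, frame: EckartFrame
) -> DerivativeExpansion:
    """Remove rigid-body components from every Cartesian axis of every tensor.

    The Eckart conditions (Σmᵢdxᵢ = 0, Σmᵢxᵢ×dxᵢ = 0) are orthogonality
    constraints in mass-weighted coordinates, so each Cartesian gradient
    axis is transported there, projected onto the complement of the
    generator span, and transported back — an oblique but idempotent
    projection on the raw axes.  Gradients of genuine internal coordinates
    already satisfy the conditions and pass through unchanged.
    """
    P = frame.projector
    if expansion.source_dim != P.shape[0]:
        raise ValueError("frame dimension does not match expansion")
    w = frame.weights
    tensors = {}
    for k, t in expansion.tensors.items():
        out = _scale_leading_axes(t, k, 1.0 / w)  # ∂/∂x → ∂/∂y axes
        for axis in range(k):
            out = np.moveaxis(np.tensordot(P, out, axes=(1, axis)), 0, axis)
        tensors[k] = _scale_leading_axes(out, k, w)  # back to raw axes
    return DerivativeExpansion(
        expansion.direction,
        expansion.source_dim,
        expansion.target_dim,
        tensors,
        reference=expansion.reference,
        validate=False,
    )


def cartesian_by_internal(
    sys: InternalSystem,
    geom: CartesianGeometry,
    order: int,
    frame: Optional[EckartFrame] = None,
    cutoff: float = DEFAULT_RANK_CUTOFF,
) -> DerivativeExpansion:
    """``∇_R^(k)X`` for Eckart-embedded Cartesians of a complete system.

    The first order is the Moore–Penrose pseudoinverse of the projected
    forward stack; higher orders follow from the implicit inversion
    recursion.  ``∇_R X · ∇_X R`` is the identity on the internal block.
    """
    if frame is None:
        frame = EckartFrame(geom)
    w = frame.weights
    P = frame.projector
    raw = system_derivatives(sys, geom, order)
    # transport to mass-weighted Cartesians y = √m·x and project there
    tensors = {}
    for k, t in raw.tensors.items():
        out = _scale_leading_axes(t, k, 1.0 / w)
        for axis in range(k):
            out = np.moveaxis(np.tensordot(P, out, axes=(1, axis)), 0, axis)
        tensors[k] = out
    forward = DerivativeExpansion(
        "forward", raw.source_dim, raw.target_dim, tensors, raw.reference, validate=False
    )
    B = forward[1]  # (3N, m) in y-axes
    sv = np.linalg.svd(B, compute_uv=False)
    m = len(sys.coords)
    if sv[-1] <= cutoff * sv[0]:
        raise IncompleteSystemError(
            "system is rank-deficient after Eckart projection; a complete "
            f"nonredundant set is required (singular values {np.round(sv, 10)})"
        )
    need = geom.n_cartesian - frame.generators.shape[0]
    if m != need:
        raise IncompleteSystemError(f"complete system must have {need} coordinates, got {m}")
    pinv = np.linalg.pinv(B)  # (m, 3N) = ∇_R Y
    inverse = invert_expansion(forward, first_inverse=pinv)
    # trailing axis back to raw Cartesians: x = y/√m
    tensors = {k: t / w for k, t in inverse.tensors.items()}
    out = DerivativeExpansion("inverse", m, geom.n_cartesian, tensors, geom.flat(), validate=False)
    return out


def given_cartesian_expansion(
    displacements: DerivativeExpansion,
) -> DerivativeExpansion:
    """Forward expansion ``∇_X R`` recovered from supplied ``∇_R X`` tensors.

    The mirrored use of the implicit recursion: when a specific set of
    Cartesian displacement fields with expansions is given (e.g. rotation
    of a fragment about a fixed axis), the same procedure expresses the
    internal coordinates' dependence on those Cartesians.
    """
    A1 = displacements[1]  # (m, 3N)
    pinv = np.linalg.pinv(A1)
    return invert_expansion(displacements, first_inverse=pinv)


# ---------------------------------------------------------------------------
# Eckart embedding of displaced geometries (oracle support and interpolation)
# ---------------------------------------------------------------------------

def eckart_embed(
    geom: CartesianGeometry,
    reference: CartesianGeometry,
    mass_weighted: bool = True,
) -> CartesianGeometry:
    """Superpose ``geom`` onto ``reference`` in the Eckart sense.

    Centers both at the (mass-weighted) centroid and applies the Kabsch
    rotation minimizing the mass-weighted RMSD — the standard realization
    of the Eckart conditions.
    """
    masses = geom.masses if mass_weighted else np.ones(geom.n_atoms)
    x = geom.coords - np.average(geom.coords, axis=0, weights=masses)
    y = reference.coords - np.average(reference.coords, axis=0, weights=masses)
    H = (x * masses[:, None]).T @ y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    Rrot = (U @ D @ Vt)
    aligned = x @ Rrot + np.average(reference.coords, axis=0, weights=masses)
    return geom.with_coords(aligned)
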