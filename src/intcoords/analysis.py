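"""Curvilinear vibrational analysis: property reexpansion, Wilson G matrix,
GF frequencies, local modes and mode-space projections.

Units: Cartesian force constants in hartree/Å^k, masses in amu, lengths in
Å, angles in radians.  The GF eigenvalues then carry hartree/(amu·Å²) and
are converted to wavenumbers through one centralized constant.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

from .coord_systems import DEFAULT_RANK_CUTOFF, InternalSystem, b_matrix
from .primitives import CartesianGeometry
from .tensor_calculus import DerivativeExpansion, reexpand

__all__ = [
    "PropertySurfaceExpansion",
    "property_to_internals",
    "g_matrix",
    "gf_frequencies",
    "pure_scaling_transform",
    "project_out_coordinate",
    "WAVENUMBER_CONVERSION",
]

# sqrt(hartree / (amu Å²)) → cm⁻¹:  ν̃ = C·sqrt(λ), C = sqrt(E_h/(u·Å²))/(2πc)
_HARTREE_J = 4.3597447222071e-18
_AMU_KG = 1.66053906660e-27
_C_CM_S = 2.99792458e10
WAVENUMBER_CONVERSION = math.sqrt(_HARTREE_J / (_AMU_KG * 1e-20)) / (2 * math.pi * _C_CM_S)


class PropertySurfaceExpansion(DerivativeExpansion):
    """Derivative tensors of a scalar property V (energy, dipole component...).

    A :class:`DerivativeExpansion` with ``target_dim None`` plus units
    metadata; in Cartesian space the order-k tensor is in (units)/Å^k.
    """

    def __init__(self, source_dim, tensors, reference=None, units="hartree", validate=True):
        super().__init__("property", source_dim, None, tensors, reference, validate=validate)
        self.units = units


def property_to_internals(
    V: DerivativeExpansion, inverse: DerivativeExpansion
) -> PropertySurfaceExpansion:
    """Reexpand Cartesian property derivatives into internal coordinates.

    ``inverse`` is the ∇_R^(k)X expansion; the result holds ∇_R^(k)V.  At a
    stationary point the order-2 result reduces to the congruence
    ``(∇_R X) ∇_X²V (∇_R X)ᵀ``.
    """
    if V.target_dim is not None:
        raise ValueError("V must be a scalar property expansion")
    res = reexpand(inverse, V)
    units = getattr(V, "units", "hartree")
    return PropertySurfaceExpansion(
        res.source_dim, res.tensors, reference=inverse.reference, units=units, validate=False
    )


def g_matrix(sys: InternalSystem, geom: CartesianGeometry) -> np.ndarray:
    """Wilson G matrix ``B M⁻¹ Bᵀ`` (m×m), the internal kinetic metric.

    Symmetric positive semidefinite with rank equal to the rank of the
    first-derivative stack; for a single bond it reduces to the inverse
    reduced mass ``1/m₁ + 1/m₂``.
    """
    B = b_matrix(sys, geom)  # (3N, m); column q = ∇_X R_q
    minv = np.repeat(1.0 / geom.masses, 3)
    return B.T @ (minv[:, None] * B)


def gf_frequencies(
    G: np.ndarray,
    F_internal: np.ndarray,
    cutoff: float = DEFAULT_RANK_CUTOFF,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Harmonic frequencies and modes from the GF eigenproblem.

    Solves ``G F L = L Λ`` through the symmetric similarity
    ``G^{1/2} F G^{1/2}`` (pseudo-square-root for redundant G).  Returns

    * frequencies (cm⁻¹, ascending; magnitudes of sqrt(λ), negative for
      imaginary modes),
    * normal vectors in the internal representation (columns, ``L = G^{1/2}W``),
    * local frequencies ``sign·sqrt(|G_ii F_ii|)`` in cm⁻¹ — the 1×1
      diagonal GF blocks before any mode mixing,
    * bilinear couplings: the off-diagonal elements of the frequency-scaled
      symmetric representation (cm⁻¹; see :func:`pure_scaling_transform`
      for the normal-mode-consistent scaling).
    """
    G = np.asarray(G, dtype=float)
    F = np.asarray(F_internal, dtype=float)
    if G.shape != F.shape or G.shape[0] != G.shape[1]:
        raise ValueError("G and F must be square and congruent")
    if np.abs(G - G.T).max() > 1e-10 * max(1.0, np.abs(G).max()):
        raise ValueError("G must be symmetric")
    evals, evecs = np.linalg.eigh((G + G.T) / 2)
    if evals[0] < -1e-10 * max(evals[-1], 1.0):
        raise ValueError("G is not positive semidefinite within tolerance")
    keep = evals > cutoff * max(evals[-1], 0.0)
    Ghalf = evecs[:, keep] * np.sqrt(evals[keep])
    H = Ghalf.T @ F @ Ghalf  # (r, r) symmetric
    lam, W = np.linalg.eigh((H + H.T) / 2)
    freqs = np.sign(lam) * WAVENUMBER_CONVERSION * np.sqrt(np.abs(lam))
    modes = Ghalf @ W  # columns: internal-representation normal vectors
    gf_diag = np.diag(G) * np.diag(F)
    local = np.sign(gf_diag) * WAVENUMBER_CONVERSION * np.sqrt(np.abs(gf_diag))
    # couplings in the locally frequency-scaled representation
    scale = np.sqrt(np.sqrt(np.abs(np.diag(G) / np.maximum(np.abs(np.diag(F)), 1e-300))))
    Fs = F * np.outer(scale, scale) * WAVENUMBER_CONVERSION
    couplings = Fs - np.diag(np.diag(Fs))
    return freqs, modes, local, couplings


def pure_scaling_transform(
    local_modes: np.ndarray, G: np.ndarray, F: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Diagonal rescaling making local modes normal-mode-equivalent.

    Normal modes ``Q`` satisfy ``Qᵀ G⁻¹ Q = I``; a set of local-mode
    vectors (columns of ``local_modes`` in the internal representation)
    differs from them by an orthogonal transformation exactly when it is
    orthonormal in the same ``G⁻¹`` metric.  The pure scaling
    ``D_ii = (LᵀG⁻¹L)_ii^{-1/2}`` normalizes each column; the returned
    defect measures how far ``(LD)ᵀG⁻¹(LD)`` is from the identity (zero
    when the local modes were already G⁻¹-orthogonal).

    Returns (scaled_modes, D, local_frequencies_cm, coupling_matrix_cm):
    the scaled representation's force matrix ``F̃ = (LD)ᵀ F (LD)`` has
    kinetic metric ≈ identity, so ``sqrt`` of its diagonal gives the local
    frequencies and the off-diagonal of its matrix square root the
    bilinear couplings, both in cm⁻¹.
    """
    L = np.asarray(local_modes, dtype=float)
    Ginv = np.linalg.pinv(np.asarray(G, dtype=float))
    M = L.T @ Ginv @ L
    d = np.diag(M)
    if np.any(d <= 0):
        raise ValueError("local modes must be independent directions")
    D = np.diag(1.0 / np.sqrt(d))
    scaled = L @ D
    Ft = scaled.T @ F @ scaled
    Ft = (Ft + Ft.T) / 2
    lam, W = np.linalg.eigh(Ft)
    nu_matrix = (W * (np.sign(lam) * np.sqrt(np.abs(lam)))) @ W.T * WAVENUMBER_CONVERSION
    local_cm = np.diag(nu_matrix).copy()
    couplings_cm = nu_matrix - np.diag(local_cm)
    return scaled, D, local_cm, couplings_cm


def orthogonality_defect(scaled_modes: np.ndarray, G: np.ndarray) -> float:
    """Max deviation of ``(LD)ᵀ G⁻¹ (LD)`` from the identity."""
    Ginv = np.linalg.pinv(np.asarray(G, dtype=float))
    M = scaled_modes.T @ Ginv @ scaled_modes
    return float(np.abs(M - np.eye(M.shape[0])).max())


def project_out_coordinate(
    mode_space: np.ndarray,
    coord_index: int,
    cutoff: float = DEFAULT_RANK_CUTOFF,
) -> np.ndarray:
    """Remove one internal coordinate's direction from a mode space.

    ``mode_space`` has modes as columns in the internal representation.
    The returned orthonormal columns have exactly zero component on the
    named coordinate and span the intersection of the original span with
    that coordinate's complement; the dimension drops by one when the
    coordinate direction lay inside the span (e.g. torsion-projected
    reaction-path modes).
    """
    M = np.asarray(mode_space, dtype=float)
    m, ncols = M.shape
    if not (0 <= coord_index < m):
        raise ValueError("coordinate index out of range")
    reduced = M.copy()
    reduced[coord_index, :] = 0.0
    U, sv, _ = np.linalg.svd(reduced, full_matrices=False)
    if sv.size == 0 or sv[0] == 0:
        return np.zeros((m, 0))
    rank = int(np.sum(sv > cutoff * sv[0]))
    out = U[:, :rank]
    out[coord_index, :] = 0.0  # exact zeros against rounding
    return out
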