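"""Differentiable interpolation between conformers in internal coordinates.

Two minima of the same molecule often have different natural coordinate
systems.  Each frame of the path linearly interpolates the internal values
in system A and in system B, reconstructs Cartesians from each (warm-started
Gauss-Newton on the forward map, Eckart-embedded against the previous
frame) and blends the two reconstructions with a switching weight w(t):
w(0)=0 reproduces geometry A exactly in system A's coordinates and w(1)=1
geometry B in system B's.  A sigmoidal weight matches each coordinate
regime exactly at its own minimum; an exponential weight transforms more
gradually between the regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .coord_systems import InternalSystem, system_derivatives, system_values
from .errors import ReconstructionError
from .inversion import eckart_embed
from .primitives import CartesianGeometry

__all__ = [
    "SwitchingFunction",
    "interpolate",
    "single_system_interpolate",
    "reconstruct_cartesian",
]


@dataclass
class SwitchingFunction:
    """Monotone smooth weight w: [0,1] → [0,1] with w(0)=0, w(1)=1.

    ``form='sigmoidal'``: a logistic in t (parameters ``steepness``,
    ``center``), affinely normalized to hit 0 and 1 at the endpoints.
    ``form='exponential'``: ``w(t) = (1 − e^{−rate·t})/(1 − e^{−rate})``,
    which departs from 0 faster but approaches the far regime more slowly.
    """

    form: str = "sigmoidal"
    steepness: float = 10.0
    center: float = 0.5
    rate: float = 2.0

    def __post_init__(self):
        if self.form not in ("sigmoidal", "exponential"):
            raise ValueError(f"unknown switching form {self.form!r}")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.form == "sigmoidal":
            raw = 1.0 / (1.0 + np.exp(-self.steepness * (t - self.center)))
            w0 = 1.0 / (1.0 + math.exp(self.steepness * self.center))
            w1 = 1.0 / (1.0 + math.exp(-self.steepness * (1.0 - self.center)))
            out = (raw - w0) / (w1 - w0)
        else:
            out = (1.0 - np.exp(-self.rate * t)) / (1.0 - math.exp(-self.rate))
        return float(out) if out.ndim == 0 else out


def _wrap_residual(resid: np.ndarray, sys: InternalSystem) -> np.ndarray:
    """Wrap dihedral residuals onto (−π, π] so Newton takes the short way."""
    out = resid.copy()
    for q, c in enumerate(sys.coords):
        if c.kind == "dihedral":
            out[q] = (out[q] + math.pi) % (2 * math.pi) - math.pi
    return out


def reconstruct_cartesian(
    sys: InternalSystem,
    target_values: np.ndarray,
    start: CartesianGeometry,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> CartesianGeometry:
    """Cartesian geometry whose internals match ``target_values``.

    Gauss-Newton on the forward map with the min-norm (pseudoinverse) step,
    warm-started from ``start``; for redundant systems this converges to
    the least-squares internal match.  Convergence is measured on the step
    norm (Å).
    """
    target_values = np.asarray(target_values, dtype=float)
    geom = start
    for _ in range(maxiter):
        resid = _wrap_residual(target_values - system_values(sys, geom), sys)
        B = system_derivatives(sys, geom, 1)[1]  # (3N, m)
        dx = np.linalg.pinv(B.T) @ resid
        geom = geom.with_coords(geom.flat() + dx)
        if np.linalg.norm(dx) < tol:
            return geom
    raise ReconstructionError(
        f"no convergence in {maxiter} Gauss-Newton iterations "
        f"(last step {np.linalg.norm(dx):.2e} Å)"
    )


def _lerp_internals(vA: np.ndarray, vB: np.ndarray, t: float, sys: InternalSystem) -> np.ndarray:
    """Linear interpolation, dihedrals along the shorter arc."""
    out = (1.0 - t) * vA + t * vB
    for q, c in enumerate(sys.coords):
        if c.kind == "dihedral":
            delta = (vB[q] - vA[q] + math.pi) % (2 * math.pi) - math.pi
            out[q] = vA[q] + t * delta
    return out


def single_system_interpolate(
    geom_A: CartesianGeometry,
    geom_B: CartesianGeometry,
    sys: InternalSystem,
    n_frames: int = 11,
) -> List[CartesianGeometry]:
    """Linear path in one internal coordinate system.

    Endpoint frames reproduce the endpoint internals exactly; midpoint
    internals are arithmetic means (dihedrals on the short arc).  Redundant
    distance-only systems are supported through the least-squares
    reconstruction.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    geom_B = eckart_embed(geom_B, geom_A)
    vA = system_values(sys, geom_A)
    vB = system_values(sys, geom_B)
    frames: List[CartesianGeometry] = []
    prev = geom_A
    for i in range(n_frames):
        t = i / (n_frames - 1)
        vals = _lerp_internals(vA, vB, t, sys)
        frame = reconstruct_cartesian(sys, vals, prev)
        frame = eckart_embed(frame, prev)
        frames.append(frame)
        prev = frame
    return frames


def interpolate(
    geom_A: CartesianGeometry,
    geom_B: CartesianGeometry,
    sys_A: InternalSystem,
    sys_B: InternalSystem,
    switch: Optional[SwitchingFunction] = None,
    n_frames: int = 11,
) -> List[CartesianGeometry]:
    """Blended interpolation between two coordinate-system regimes.

    Frame t reconstructs Cartesians from the linearly interpolated
    internals of system A and of system B separately and blends them with
    weight ``switch(t)`` on the B-side reconstruction.  t=0 equals
    ``geom_A`` in every system-A coordinate and t=1 equals ``geom_B`` in
    every system-B coordinate, both to reconstruction tolerance.
    """
    if switch is None:
        switch = SwitchingFunction()
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if geom_A.atoms != geom_B.atoms:
        raise ValueError("endpoint geometries must share atom ordering")
    geom_B = eckart_embed(geom_B, geom_A)
    vA_A = system_values(sys_A, geom_A)
    vA_B = system_values(sys_A, geom_B)
    vB_A = system_values(sys_B, geom_A)
    vB_B = system_values(sys_B, geom_B)
    frames: List[CartesianGeometry] = []
    prevA = geom_A
    prevB = geom_A
    prev = geom_A
    for i in range(n_frames):
        t = i / (n_frames - 1)
        w = float(switch(t))
        try:
            fA = reconstruct_cartesian(sys_A, _lerp_internals(vA_A, vA_B, t, sys_A), prevA)
            fB = reconstruct_cartesian(sys_B, _lerp_internals(vB_A, vB_B, t, sys_B), prevB)
        except ReconstructionError as exc:
            raise ReconstructionError(f"frame {i} (t={t:.3f}): {exc}") from exc
        fA = eckart_embed(fA, prev)
        fB = eckart_embed(fB, prev)
        blended = geom_A.with_coords((1.0 - w) * fA.coords + w * fB.coords)
        blended = eckart_embed(blended, prev)
        frames.append(blended)
        prevA, prevB, prev = fA, fB, blended
    return frames
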