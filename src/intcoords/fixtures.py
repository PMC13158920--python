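"""Seeded geometry generator for testing and examples.

Base geometries are built from ideal bond lengths and angles (documented
inline, Å and degrees); an optional perturbation draws one normal deviate
per Cartesian component from a seeded generator, so every fixture is
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .primitives import CartesianGeometry

__all__ = ["make_fixture", "FIXTURE_NAMES"]


def _water() -> CartesianGeometry:
    # r(OH) = 0.9572 Å, HOH = 104.52°
    r, th = 0.9572, math.radians(104.52)
    return CartesianGeometry(
        ["O", "H", "H"],
        [
            [0.0, 0.0, 0.0],
            [r * math.sin(th / 2), 0.0, r * math.cos(th / 2)],
            [-r * math.sin(th / 2), 0.0, r * math.cos(th / 2)],
        ],
    )


def _ammonia() -> CartesianGeometry:
    # r(NH) = 1.012 Å, HNH = 106.7° (pyramidal C3v)
    r, hnh = 1.012, math.radians(106.7)
    # ring radius/height from the HNH angle
    s = r * math.sqrt(2 - 2 * math.cos(hnh)) / math.sqrt(3)  # H ring circumradius
    h = math.sqrt(max(r * r - s * s, 0.0))
    coords = [[0.0, 0.0, 0.0]]
    for i in range(3):
        phi = 2 * math.pi * i / 3
        coords.append([s * math.cos(phi), s * math.sin(phi), -h])
    return CartesianGeometry(["N", "H", "H", "H"], coords)


def _acetylene() -> CartesianGeometry:
    # linear H-C≡C-H: r(CH) = 1.062 Å, r(CC) = 1.203 Å
    rch, rcc = 1.062, 1.203
    return CartesianGeometry(
        ["H", "C", "C", "H"],
        [[0.0, 0.0, -rch], [0.0, 0.0, 0.0], [0.0, 0.0, rcc], [0.0, 0.0, rcc + rch]],
    )


def _chain4() -> CartesianGeometry:
    # HOOH-like skew chain: r(OH) = 0.95, r(OO) = 1.45 Å, OOH = 100°, τ = 112°
    r1, r2, t1, tau = 0.95, 1.45, math.radians(100.0), math.radians(112.0)
    j = np.zeros(3)
    k = np.array([r2, 0.0, 0.0])
    i = np.array([r1 * math.cos(t1), r1 * math.sin(t1), 0.0])
    l = k + np.array(
        [-r1 * math.cos(t1), r1 * math.sin(t1) * math.cos(tau), r1 * math.sin(t1) * math.sin(tau)]
    )
    return CartesianGeometry(["H", "O", "O", "H"], np.array([i, j, k, l]))


def _methanol_like() -> CartesianGeometry:
    # CH3OH skeleton: r(CO) = 1.43, r(OH) = 0.96, r(CH) = 1.09 Å,
    # COH = 108.5°, OCH = 109.5°, staggered methyl
    rco, roh, rch = 1.43, 0.96, 1.09
    coh, och = math.radians(108.5), math.radians(109.5)
    c = np.zeros(3)
    o = np.array([rco, 0.0, 0.0])
    h_o = o + roh * np.array([math.cos(math.pi - coh), math.sin(math.pi - coh), 0.0])
    hs = []
    for i, phi in enumerate((math.pi, math.pi / 3, -math.pi / 3)):  # staggered w.r.t. OH
        hs.append(
            c
            + rch
            * np.array(
                [
                    math.cos(math.pi - och),
                    math.sin(math.pi - och) * math.cos(phi),
                    math.sin(math.pi - och) * math.sin(phi),
                ]
            )
        )
    return CartesianGeometry(
        ["C", "O", "H", "H", "H", "H"], np.array([c, o, h_o] + hs)
    )


def _ring5_metal_toy() -> CartesianGeometry:
    # idealized Cp-metal toy: regular C5 ring (circumradius 1.21 Å) with a
    # heavy atom 2.0 Å above the centroid
    rring, height = 1.21, 2.0
    coords = []
    for i in range(5):
        phi = 2 * math.pi * i / 5
        coords.append([rring * math.cos(phi), rring * math.sin(phi), 0.0])
    coords.append([0.0, 0.0, height])
    return CartesianGeometry(["C"] * 5 + ["Mo"], coords)


_BUILDERS = {
    "water": _water,
    "ammonia": _ammonia,
    "acetylene": _acetylene,
    "chain4": _chain4,
    "methanol_like": _methanol_like,
    "ring5_metal_toy": _ring5_metal_toy,
}

FIXTURE_NAMES = tuple(sorted(_BUILDERS))


def make_fixture(
    name: str, perturbation: float = 0.0, seed: Optional[int] = None
) -> CartesianGeometry:
    """Deterministic test geometry, optionally with seeded Gaussian noise.

    ``perturbation`` is the per-component standard deviation in Å; scales
    up to ~0.05 Å keep every fixture nondegenerate for all coordinates.
    """
    if name not in _BUILDERS:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    geom = _BUILDERS[name]()
    if perturbation:
        rng = np.random.default_rng(seed)
        noise = rng.normal(scale=perturbation, size=geom.coords.shape)
        geom = geom.with_coords(geom.coords + noise)
    return geom
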