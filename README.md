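# intcoords

Arbitrary-order internal coordinate transformations for molecular
modelling: derivative tensors of bond lengths, valence angles, dihedrals
and composite coordinates with respect to Cartesians to any order, the
implicit inverse transformation to Eckart-embedded Cartesians, chain-rule
reexpansion of property surfaces (potential, dipole, ...) between
coordinate systems, differentiable conversions and interpolations between
internal coordinate systems, and Wilson GF local-mode analysis.

It is aimed at vibrational spectroscopists and method developers who need
curvilinear expansions — for VPT2-style perturbation theory, potential
surface analysis, reaction-path mode projections or conformer
interpolation — without hand-deriving coordinate-specific formulas or
resorting to numerical differentiation.

## The machinery

**Higher-order chain rule over integer partitions.** For a scalar V and
coordinate systems R(X), the order-m derivative is

```
∇_R^(m) V = Σ_{p ∈ P(m)} [ ∇_R^(p₁)X ⋯ ∇_R^(p_j)X · ∇_X^(j)V ]_(T(p))
```

where P(m) is the set of integer partitions of m and T(p) the minimal set
of axis transpositions restoring total symmetry — one transposition per
distinct block arrangement, m!/(∏ pᵢ!·∏ multⱼ!) in all. Transposition and
addition replace redundant contractions.

**Coordinate primitives.** r = |xᵢ−xⱼ|; θ and τ through the two-argument
arctangent of their (sin, cos) pair, which is stable near 0 and π and
carries the dihedral sign without extra logic. Every primitive is a short
pipeline of difference vectors, cross/dot products, vector norms and
atan2, each with exact derivatives at every order (the norm through the
partition recursion applied to √(a·a), atan2 through the closed form of
its mixed partials), so the same engine produces values, B matrices and
arbitrary-order tensors. Exactly planar dihedrals switch to an
arcsin-of-sine branch that stays finite at the planar point.

**Implicit inversion.** Differentiating ∇_R Q · ∇_Q R = I shows all
higher derivatives of the composite vanish; isolating the top inverse
derivative yields a recursion giving ∇_R^(k)Q from the forward tensors
and the first-order inverse alone. Cartesian ↔ internal transformations
become invertible after projecting out the translation/rotation
generators in mass-weighted coordinates (the Eckart conditions) and
pseudoinverting the projected first-order stack.

**Analysis.** Wilson G = B M⁻¹ Bᵀ; harmonic frequencies from the
symmetric form G^{1/2} F G^{1/2}; local-mode frequencies and bilinear
couplings in a pure-scaling representation consistent with the normal
modes; mode-space projections (e.g. torsion-projected 3N−7 spaces).

## Worked example

```python
import numpy as np
from intcoords import *

geom = make_fixture("water")                      # r(OH)=0.9572 Å, 104.52°
sysw = InternalSystem([distance(1, 0), distance(2, 0), angle(1, 0, 2)])

# forward tensors X→R to third order; order-1 slice is the Wilson B matrix
exp = system_derivatives(sysw, geom, order=3)
print(np.round(exp[1], 4))

# inverse tensors R→X for Eckart-embedded Cartesians, and the identity check
inv = cartesian_by_internal(sysw, geom, order=2)
comp = compose_expansions(inv, eckart_project(exp, EckartFrame(geom)))
print(float(np.abs(comp[1] - np.eye(3)).max()))

# GF frequencies from a quadratic internal force field (hartree/Å², rad)
G = g_matrix(sysw, geom)
F = np.array([[0.53, 0.025, 0.015], [0.025, 0.53, 0.015], [0.015, 0.015, 0.17]])
freqs, modes, local, coup = gf_frequencies(G, F)
print(np.round(np.sort(freqs), 1), np.round(local, 1))
```

prints

```
[[-0.7908  0.7908  0.    ]
 [ 0.      0.      0.    ]
 [-0.6121 -0.6121  1.6523]
 [ 0.7908  0.      0.6394]
 [ 0.      0.      0.    ]
 [ 0.6121  0.     -0.8262]
 [ 0.     -0.7908 -0.6394]
 [ 0.      0.      0.    ]
 [ 0.      0.6121 -0.8262]]
4.440892098500626e-16
[1710.3 2000.  2062.3] [2033.9 2033.9 1714.4]
```

The 9×3 stack holds each coordinate's Cartesian gradient (both OH
gradients point along their bonds, the angle column is the standard
bending field); the composite ∇_R X · ∇_X R is the identity to machine
precision; and the three GF frequencies are the harmonic modes of the
synthetic force field, with the diagonal "local" frequencies showing the
two equivalent uncoupled OH stretches before mode mixing.

A command-line interface mirrors the library:

```
intcoords derivs --geom water.xyz --coords sys.json --order 3 --out tensors.npz
intcoords gmatrix --geom water.xyz --coords sys.json --hessian F.txt
intcoords interpolate --a a.xyz --b b.xyz --coords-a ca.json --coords-b cb.json \
    --frames 51 --switch sigmoidal --out path.xyz
```

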