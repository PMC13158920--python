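"""Forward-mode tensor Taylor arithmetic.

A :class:`Jet` carries the value of a scalar quantity together with its
totally symmetric derivative tensors of orders ``1..K`` with respect to a
``d``-dimensional seed space.  Products follow the multivariate Leibniz
rule (a sum over distinct axis splits) and compositions with univariate or
bivariate elementary functions reuse the partition-based chain rule, so the
whole engine is exact to machine precision at every order.

This is an internal helper: the coordinate primitives are each a short
pipeline of difference vectors, cross/dot products, norms and ``atan2``
written in jet arithmetic.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, List, Sequence

import numpy as np

from .tensor_calculus import DerivativeExpansion, compose_expansions

__all__ = ["Jet", "seed_variables", "jet_cross", "jet_dot", "jet_norm", "jet_atan2"]


class Jet:
    """Scalar value plus derivative tensors of orders ``1..K`` in ``d`` dims."""

    __slots__ = ("value", "derivs", "d", "K")

    def __init__(self, value: float, derivs: List[np.ndarray], d: int, K: int):
        self.value = float(value)
        self.derivs = derivs  # derivs[k-1] has shape (d,)*k
        self.d = d
        self.K = K

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, value: float, d: int, K: int) -> "Jet":
        return cls(value, [np.zeros((d,) * k) for k in range(1, K + 1)], d, K)

    @classmethod
    def variable(cls, value: float, index: int, d: int, K: int) -> "Jet":
        derivs = [np.zeros((d,) * k) for k in range(1, K + 1)]
        derivs[0][index] = 1.0
        return cls(value, derivs, d, K)

    # -- ring operations ---------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Jet):
            return Jet(
                self.value + other.value,
                [a + b for a, b in zip(self.derivs, other.derivs)],
                self.d,
                self.K,
            )
        return Jet(self.value + float(other), [a.copy() for a in self.derivs], self.d, self.K)

    __radd__ = __add__

    def __neg__(self):
        return Jet(-self.value, [-a for a in self.derivs], self.d, self.K)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Jet) else -float(other))

    def __rsub__(self, other):
        return (-self) + float(other)

    def __mul__(self, other):
        if not isinstance(other, Jet):
            c = float(other)
            return Jet(c * self.value, [c * a for a in self.derivs], self.d, self.K)
        out: List[np.ndarray] = []
        for m in range(1, self.K + 1):
            acc = self.value * other.derivs[m - 1] + other.value * self.derivs[m - 1]
            for k in range(1, m):
                fk = self.derivs[k - 1]
                gmk = other.derivs[m - k - 1]
                prod = np.multiply.outer(fk, gmk)
                for subset in itertools.combinations(range(m), k):
                    # axes `subset` receive the f-factor, the rest the g-factor
                    rest = [ax for ax in range(m) if ax not in subset]
                    order = list(subset) + rest
                    inv = np.argsort(order)
                    acc = acc + prod.transpose(tuple(inv))
                # note: subset enumeration covers each distinct split once
            out.append(acc)
        return Jet(self.value * other.value, out, self.d, self.K)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Jet):
            return self * other.reciprocal()
        return self * (1.0 / float(other))

    def __rtruediv__(self, other):
        return self.reciprocal() * float(other)

    # -- compositions ------------------------------------------------------
    def compose(self, f_derivs: Sequence[float], f_value: float) -> "Jet":
        """Apply a univariate function given its derivative values at ``self.value``."""
        inner = DerivativeExpansion(
            "jet",
            self.d,
            1,
            {k: self.derivs[k - 1][..., None] for k in range(1, self.K + 1)},
            validate=False,
        )
        outer = DerivativeExpansion(
            "f",
            1,
            None,
            {j: np.full((1,) * j, f_derivs[j - 1]) for j in range(1, self.K + 1)},
            validate=False,
        )
        res = compose_expansions(inner, outer)
        return Jet(f_value, [res[k] for k in range(1, self.K + 1)], self.d, self.K)

    def sqrt(self) -> "Jet":
        u = self.value
        if u <= 0:
            from .errors import DegenerateGeometryError

            raise DegenerateGeometryError("sqrt of a non-positive jet value")
        ders, coeff, power = [], 1.0, 0.5
        for k in range(1, self.K + 1):
            coeff *= power
            power -= 1.0
            ders.append(coeff * u ** (0.5 - k))
        return self.compose(ders, math.sqrt(u))

    def reciprocal(self) -> "Jet":
        u = self.value
        ders = [(-1.0) ** k * math.factorial(k) * u ** (-k - 1) for k in range(1, self.K + 1)]
        return self.compose(ders, 1.0 / u)

    def cos(self) -> "Jet":
        cycle = [-math.sin(self.value), -math.cos(self.value), math.sin(self.value), math.cos(self.value)]
        return self.compose([cycle[(k - 1) % 4] for k in range(1, self.K + 1)], math.cos(self.value))

    def sin(self) -> "Jet":
        cycle = [math.cos(self.value), -math.sin(self.value), -math.cos(self.value), math.sin(self.value)]
        return self.compose([cycle[(k - 1) % 4] for k in range(1, self.K + 1)], math.sin(self.value))

    def power(self, n: float) -> "Jet":
        u = self.value
        ders, coeff, p = [], 1.0, float(n)
        for k in range(1, self.K + 1):
            coeff *= p
            p -= 1.0
            ders.append(coeff * u ** (n - k))
        return self.compose(ders, u ** n)

    def asin(self) -> "Jet":
        # asin(x) = atan2(x, sqrt(1 - x^2)); valid for |x| < 1 and exact at 0
        return jet_atan2(self, (1.0 - self * self).sqrt())

    def acos(self) -> "Jet":
        return jet_atan2((1.0 - self * self).sqrt(), self)

    def apply_expr(self, fn: Callable, *args) -> "Jet":  # pragma: no cover - convenience
        return fn(self, *args)


# ---------------------------------------------------------------------------
# helpers on vectors of jets
# ---------------------------------------------------------------------------

def seed_variables(values: np.ndarray, K: int) -> List[Jet]:
    """One seed :class:`Jet` per component of ``values``."""
    values = np.asarray(values, dtype=float).ravel()
    d = values.size
    return [Jet.variable(v, i, d, K) for i, v in enumerate(values)]


def jet_cross(a: Sequence[Jet], b: Sequence[Jet]) -> List[Jet]:
    return [
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    ]


def jet_dot(a: Sequence[Jet], b: Sequence[Jet]) -> Jet:
    acc = a[0] * b[0]
    for i in (1, 2):
        acc = acc + a[i] * b[i]
    return acc


def jet_norm(a: Sequence[Jet]) -> Jet:
    return jet_dot(a, a).sqrt()


def jet_atan2(s: Jet, c: Jet) -> Jet:
    """``atan2`` of two jets via the exact arbitrary-order partials.

    ``θ = atan2(s, c) = Im log(c + i s)`` away from the origin, so the mixed
    partial with ``b`` derivatives in ``s`` and ``a`` in ``c`` (``k = a+b``)
    is ``Im(i^b (-1)^(k-1) (k-1)! / z^k)`` with ``z = c + i s``.  Combined
    with the derivatives of ``(s, c)`` through the partition chain rule this
    realizes the identity ``dθ = cosθ d(sinθ) − sinθ d(cosθ)`` and its
    higher-order analogues without branch logic.
    """
    K, d = s.K, s.d
    z = complex(c.value, s.value)
    if z == 0:
        from .errors import DegenerateGeometryError

        raise DegenerateGeometryError("atan2 jet at the origin")
    inner = DerivativeExpansion(
        "jet",
        d,
        2,
        {
            k: np.stack([s.derivs[k - 1], c.derivs[k - 1]], axis=-1)
            for k in range(1, K + 1)
        },
        validate=False,
    )
    outer_tensors = {}
    for k in range(1, K + 1):
        t = np.empty((2,) * k)
        base = (-1.0) ** (k - 1) * math.factorial(k - 1) / z**k
        for idx in itertools.product((0, 1), repeat=k):
            b = sum(1 for i in idx if i == 0)  # s-axis derivatives
            t[idx] = ((1j**b) * base).imag
        outer_tensors[k] = t
    outer = DerivativeExpansion("atan2", 2, None, outer_tensors, validate=False)
    res = compose_expansions(inner, outer)
    return Jet(math.atan2(s.value, c.value), [res[k] for k in range(1, K + 1)], d, K)
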