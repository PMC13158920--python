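"""Partition-based machinery for transforming derivative tensors between
coordinate systems.

The higher-order chain rule (Faà di Bruno's formula) for a composite
``V(R(X))`` is organized as a sum over the integer partitions ``p`` of the
derivative order ``m``: each partition contributes one product of inner
derivative tensors of orders ``p_1..p_j`` contracted with the order-``j``
outer tensor, followed by the minimal set of axis transpositions ``T(p)``
needed to make the term totally symmetric.  Because all the factors are
themselves symmetric tensors, summing over the ``m!/(∏ p_i! ∏ mult_j!)``
distinct block arrangements reproduces the full multinomial weight of the
classical formula with additions in place of redundant contractions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "integer_partitions",
    "symmetrizing_transpositions",
    "PartitionScheme",
    "DerivativeExpansion",
    "compose_expansions",
    "reexpand",
    "norm_derivative_sequence",
]


# ---------------------------------------------------------------------------
# integer partitions and symmetrizing transpositions
# ---------------------------------------------------------------------------

def integer_partitions(m: int) -> List[Tuple[int, ...]]:
    """All integer partitions of ``m`` as non-increasing tuples.

    Ordered lexicographically descending, so ``(m,)`` comes first and
    ``(1,)*m`` last; the order is deterministic.
    """
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError(f"partition order must be a positive integer, got {m!r}")
    return _partitions_cached(int(m))


@lru_cache(maxsize=None)
def _partitions_cached(m: int) -> List[Tuple[int, ...]]:
    result: List[Tuple[int, ...]] = []

    def rec(remaining: int, maxpart: int, prefix: Tuple[int, ...]) -> None:
        if remaining == 0:
            result.append(prefix)
            return
        for part in range(min(maxpart, remaining), 0, -1):
            rec(remaining - part, part, prefix + (part,))

    rec(m, m, ())
    return result


def symmetrizing_transpositions(p: Sequence[int]) -> List[Tuple[int, ...]]:
    """The minimal set ``T(p)`` of axis permutations that symmetrizes a
    partition-``p`` product of symmetric factors.

    A term built from symmetric factors of orders ``p_1 ≥ ... ≥ p_j`` is
    already invariant under permutations inside each block of axes and under
    exchange of equal-size blocks.  One permutation per distinct assignment
    of the ``m`` axes to blocks therefore suffices; there are
    ``m!/(∏ p_i! · ∏ mult_j!)`` of them.  Permutations are returned as axis
    orders suitable for ``ndarray.transpose``.
    """
    p = tuple(int(x) for x in p)
    if not p or any(x < 1 for x in p) or any(a < b for a, b in zip(p, p[1:])):
        raise ValueError(f"not a valid (non-increasing, positive) partition: {p!r}")
    return _transpositions_cached(p)


@lru_cache(maxsize=None)
def _transpositions_cached(p: Tuple[int, ...]) -> List[Tuple[int, ...]]:
    m = sum(p)
    perms: List[Tuple[int, ...]] = []
    # block i occupies raw axes [offsets[i], offsets[i]+p[i])
    offsets = np.concatenate([[0], np.cumsum(p)]).astype(int)

    def rec(available: Tuple[int, ...], blocks: List[Tuple[int, ...]]) -> None:
        if not available:
            perm = [0] * m
            for i, blk in enumerate(blocks):
                for t, target_axis in enumerate(sorted(blk)):
                    perm[target_axis] = int(offsets[i] + t)
            perms.append(tuple(perm))
            return
        i = len(blocks)
        size = p[i]
        for blk in itertools.combinations(available, size):
            # equal-size blocks are interchangeable: require their anchors
            # (smallest members) to increase, so each unordered arrangement
            # is emitted exactly once
            if i > 0 and p[i - 1] == size and blk[0] < blocks[-1][0]:
                continue
            remaining = tuple(a for a in available if a not in blk)
            rec(remaining, blocks + [blk])

    rec(tuple(range(m)), [])
    return perms


@dataclass(frozen=True)
class PartitionScheme:
    """Integer partitions of ``order`` with their symmetrizing transpositions."""

    order: int
    partitions: List[Tuple[int, ...]] = field(init=False)
    transpositions: Dict[Tuple[int, ...], List[Tuple[int, ...]]] = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "partitions", integer_partitions(self.order))
        object.__setattr__(
            self,
            "transpositions",
            {p: symmetrizing_transpositions(p) for p in self.partitions},
        )


# ---------------------------------------------------------------------------
# derivative expansions
# ---------------------------------------------------------------------------

class DerivativeExpansion:
    """Reference point plus derivative tensors of orders ``1..K``.

    For a map between coordinate systems (``direction`` "forward" X→R,
    "inverse" R→X, or any labelled map) the order-``k`` tensor has ``k``
    leading axes of dimension ``source_dim`` and one trailing axis of
    dimension ``target_dim``.  For a scalar property (``target_dim is
    None``) the trailing axis is absent.  Tensors are totally symmetric in
    their leading axes.
    """

    def __init__(
        self,
        direction: str,
        source_dim: int,
        target_dim: Optional[int],
        tensors: Dict[int, np.ndarray],
        reference: Optional[np.ndarray] = None,
        validate: bool = True,
    ):
        self.direction = direction
        self.source_dim = int(source_dim)
        self.target_dim = None if target_dim is None else int(target_dim)
        self.tensors = {int(k): np.asarray(v, dtype=float) for k, v in tensors.items()}
        self.reference = None if reference is None else np.asarray(reference, dtype=float)
        if validate:
            self._validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def order(self) -> int:
        return max(self.tensors) if self.tensors else 0

    def __getitem__(self, k: int) -> np.ndarray:
        return self.tensors[k]

    def __contains__(self, k: int) -> bool:
        return k in self.tensors

    def orders(self) -> List[int]:
        return sorted(self.tensors)

    def _validate(self) -> None:
        ks = self.orders()
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError(f"orders must be contiguous from 1, got {ks}")
        for k, t in self.tensors.items():
            expected = (self.source_dim,) * k
            if self.target_dim is not None:
                expected = expected + (self.target_dim,)
            if t.shape != expected:
                raise ValueError(
                    f"order-{k} tensor has shape {t.shape}, expected {expected}"
                )

    def max_asymmetry(self) -> float:
        """Largest relative deviation from total symmetry of the leading axes."""
        worst = 0.0
        for k, t in self.tensors.items():
            if k < 2:
                continue
            scale = max(np.abs(t).max(), 1e-300)
            for perm in itertools.permutations(range(k)):
                axes = perm + ((k,) if self.target_dim is not None else ())
                worst = max(worst, float(np.abs(t - t.transpose(axes)).max()) / scale)
        return worst

    def copy(self) -> "DerivativeExpansion":
        return DerivativeExpansion(
            self.direction,
            self.source_dim,
            self.target_dim,
            {k: t.copy() for k, t in self.tensors.items()},
            None if self.reference is None else self.reference.copy(),
            validate=False,
        )


# ---------------------------------------------------------------------------
# the generalized chain rule
# ---------------------------------------------------------------------------

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _partition_term(
    p: Tuple[int, ...],
    inner_tensors: Dict[int, np.ndarray],
    outer_tensor: np.ndarray,
    outer_has_target: bool,
) -> np.ndarray:
    """Raw (unsymmetrized) contraction for one partition.

    ``inner_tensors[k]`` has ``k`` leading source axes and one trailing
    intermediate axis; ``outer_tensor`` has ``j = len(p)`` leading
    intermediate axes (plus an optional trailing target axis).  Result has
    ``m = sum(p)`` leading source axes assigned block-wise in partition
    order (plus the trailing target axis when present).
    """
    m = sum(p)
    j = len(p)
    n_letters = m + j + (1 if outer_has_target else 0)
    if n_letters > len(_LETTERS):
        raise ValueError(f"derivative order {m} too high for the einsum planner")
    src = _LETTERS[:m]
    mid = _LETTERS[m : m + j]
    tgt = _LETTERS[m + j] if outer_has_target else ""

    specs = []
    operands = []
    off = 0
    for i, k in enumerate(p):
        specs.append(src[off : off + k] + mid[i])
        operands.append(inner_tensors[k])
        off += k
    specs.append(mid + tgt)
    operands.append(outer_tensor)
    out = src + tgt
    return np.einsum(",".join(specs) + "->" + out, *operands, optimize=True)


def _symmetrize_term(term: np.ndarray, p: Tuple[int, ...], has_target: bool) -> np.ndarray:
    m = sum(p)
    total = np.zeros_like(term)
    extra = (m,) if has_target else ()
    for perm in symmetrizing_transpositions(p):
        total += term.transpose(perm + extra)
    return total


def compose_expansions(
    inner: DerivativeExpansion, outer: DerivativeExpansion, order: Optional[int] = None
) -> DerivativeExpansion:
    """Derivative expansion of the composite ``outer ∘ inner``.

    ``inner`` maps a source system into an intermediate system and ``outer``
    maps the intermediate system onward (to a target system or, when its
    ``target_dim`` is ``None``, to a scalar property).  Order ``m`` of the
    result is the partition sum over products of inner tensors contracted
    with outer tensors, symmetrized by ``T(p)``.
    """
    if inner.target_dim is None:
        raise ValueError("inner expansion must be a coordinate map (target_dim set)")
    if inner.target_dim != outer.source_dim:
        raise ValueError(
            f"dimension mismatch: inner target {inner.target_dim} vs outer source {outer.source_dim}"
        )
    K = min(inner.order, outer.order) if order is None else order
    if inner.order < K or outer.order < K:
        raise ValueError(f"need orders 1..{K} in both expansions")
    has_tgt = outer.target_dim is not None
    tensors: Dict[int, np.ndarray] = {}
    for m in range(1, K + 1):
        shape = (inner.source_dim,) * m + ((outer.target_dim,) if has_tgt else ())
        acc = np.zeros(shape)
        for p in integer_partitions(m):
            term = _partition_term(p, inner.tensors, outer.tensors[len(p)], has_tgt)
            acc += _symmetrize_term(term, p, has_tgt)
        tensors[m] = acc
    direction = f"({outer.direction})∘({inner.direction})"
    return DerivativeExpansion(
        direction,
        inner.source_dim,
        outer.target_dim,
        tensors,
        reference=inner.reference,
        validate=False,
    )


def reexpand(inner: DerivativeExpansion, outer: DerivativeExpansion) -> DerivativeExpansion:
    """Transform property derivatives ``∇_R^(k)V`` into ``∇_X^(k)V``.

    ``inner`` is the forward coordinate expansion X→R (``∇_X^(k)R``) and
    ``outer`` holds the property derivatives in the R system.  At first
    order this is the plain chain rule ``∇_X V = ∇_X R · ∇_R V``.
    """
    return compose_expansions(inner, outer)


# ---------------------------------------------------------------------------
# norm derivative sequence
# ---------------------------------------------------------------------------

def norm_derivative_sequence(a: np.ndarray, k: int) -> List[np.ndarray]:
    """Derivative tensors of ``|a|`` w.r.t. the components of ``a``, orders 1..k.

    Generated by the partition recursion applied to ``|a| = sqrt(a·a)``: the
    squared norm has only first and second derivatives (``2a`` and ``2I``),
    so every order is a partition sum of tensor products capped at second
    order, scaled by the univariate derivatives of the square root.
    """
    a = np.asarray(a, dtype=float).ravel()
    n = a.size
    s = float(a @ a)
    if s <= 0.0:
        from .errors import DegenerateGeometryError

        raise DegenerateGeometryError("norm derivative of a zero vector")
    if k < 1:
        raise ValueError("order must be >= 1")
    # inner: expansion of s = a·a w.r.t. a  (orders 1..k)
    inner_tensors = {1: (2.0 * a)[:, None]}
    if k >= 2:
        inner_tensors[2] = (2.0 * np.eye(n))[:, :, None]
    for m in range(3, k + 1):
        inner_tensors[m] = np.zeros((n,) * m + (1,))
    inner = DerivativeExpansion("a->s", n, 1, inner_tensors, validate=False)
    # outer: univariate derivatives of sqrt at s
    outer_tensors = {}
    coeff = 1.0
    power = 0.5
    for j in range(1, k + 1):
        coeff *= power
        power -= 1.0
        outer_tensors[j] = np.full((1,) * j, coeff * s ** (0.5 - j))
    outer = DerivativeExpansion("sqrt", 1, None, outer_tensors, validate=False)
    result = compose_expansions(inner, outer)
    return [result[m] for m in range(1, k + 1)]
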