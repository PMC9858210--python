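"""Decorated permutations and the maps that produce them.

A decorated permutation on n elements is an injective map
sigma: {1..n} -> {1..2n} with a <= sigma(a) <= a+n whose mod-n reduction is an
ordinary permutation.  Fixed points of the underlying permutation carry one
extra bit: sigma(a) = a (a "white" fixed point) or sigma(a) = a+n ("black").
These objects label cells of the positive Grassmannian and, via the maps in
this module, summarize the asymptotic structure of Markov chains and directed
graphs:

* :func:`from_markov` -- transient states map to themselves; a recurrent state
  a maps to the first b > a whose mod-n residue lies in a's communicating
  class and whose cyclic window {a,...,b} covers that whole class.  Absorbing
  states therefore map to a+n.
* :func:`from_graph` -- the same rule driven by strongly connected components.
* :func:`from_grassmannian` -- the column-span rule on a full-rank k x n
  matrix with its columns repeated once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import networkx as nx
import numpy as np

from .kernels import Kernel, communicating_classes

__all__ = [
    "DecoratedPermutation",
    "DecoratedPermutationError",
    "validate",
    "underlying_permutation",
    "decorations_of",
    "from_markov",
    "from_graph",
    "from_grassmannian",
]


class DecoratedPermutationError(ValueError):
    """Violation of the decorated-permutation axioms."""


def _residue(v: int, n: int) -> int:
    """Mod-n reduction into {1..n} (1-based labels throughout)."""
    return (v - 1) % n + 1


@dataclass(frozen=True)
class DecoratedPermutation:
    """An injective map {1..n} -> {1..2n} that is a bijection mod n."""

    n: int
    images: tuple

    def __post_init__(self):
        object.__setattr__(self, "images", tuple(int(v) for v in self.images))

    def __call__(self, a: int) -> int:
        return self.images[a - 1]

    def __str__(self) -> str:
        return "[" + ",".join(str(v) for v in self.images) + "]"

    def residues(self) -> tuple:
        return tuple(_residue(v, self.n) for v in self.images)

    def fixed_points(self) -> tuple:
        """Positions a with sigma(a) = a or a+n (decorated fixed points)."""
        return tuple(
            a for a in range(1, self.n + 1)
            if self.images[a - 1] in (a, a + self.n)
        )

    def is_identity_decoration(self) -> bool:
        return len(self.fixed_points()) == self.n


def validate(images: Sequence[int], n: int | None = None) -> DecoratedPermutation:
    """Validate an image list as a decorated permutation.

    Raises :class:`DecoratedPermutationError` naming the violated axiom:
    the range condition a <= sigma(a) <= a+n, or mod-n bijectivity.
    """
    images = tuple(int(v) for v in images)
    if n is None:
        n = len(images)
    if len(images) != n:
        raise DecoratedPermutationError(
            f"expected {n} images, got {len(images)}"
        )
    for a, v in enumerate(images, start=1):
        if not (a <= v <= a + n):
            raise DecoratedPermutationError(
                f"range violation: sigma({a})={v} outside [{a}, {a + n}]"
            )
    residues = [_residue(v, n) for v in images]
    if len(set(residues)) != n:
        seen: dict[int, int] = {}
        for a, r in enumerate(residues, start=1):
            if r in seen:
                raise DecoratedPermutationError(
                    f"mod-{n} collision: sigma({seen[r]}) and sigma({a}) "
                    f"both reduce to {r}; reduction must be a bijection"
                )
            seen[r] = a
    return DecoratedPermutation(n, images)


def underlying_permutation(sigma: DecoratedPermutation) -> tuple:
    """The ordinary permutation sigma(a) mod n, 1-based."""
    return sigma.residues()


def decorations_of(s: Sequence[int]) -> list[DecoratedPermutation]:
    """All decorated permutations over an ordinary permutation s.

    Non-fixed points are forced (add n exactly when s(a) < a); each of the k
    fixed points independently takes a or a+n, giving 2^k decorations.
    """
    s = tuple(int(v) for v in s)
    n = len(s)
    if sorted(s) != list(range(1, n + 1)):
        raise DecoratedPermutationError(f"{s} is not a permutation of 1..{n}")
    fixed = [a for a in range(1, n + 1) if s[a - 1] == a]
    base = []
    for a in range(1, n + 1):
        v = s[a - 1]
        base.append(v if v >= a else v + n)
    out = []
    for choice in itertools.product((0, 1), repeat=len(fixed)):
        images = list(base)
        for bit, a in zip(choice, fixed):
            images[a - 1] = a + n if bit else a
        out.append(DecoratedPermutation(n, tuple(images)))
    return out


# ---------------------------------------------------------------------------
# the window rule
# ---------------------------------------------------------------------------

def _window_image(a: int, cls: set, n: int) -> int:
    """First b > a whose residue lies in cls and whose inclusive cyclic window
    {a, a+1, ..., b} (taken mod n) covers cls.

    This single rule subsumes the separate recurrent and absorbing clauses:
    for an absorbing singleton {a} the first admissible b is a+n.
    """
    covered = {a}
    for b in range(a + 1, a + n + 1):
        covered.add(_residue(b, n))
        if _residue(b, n) in cls and cls <= covered:
            return b
    raise AssertionError("window rule must terminate by b = a+n")  # pragma: no cover


def from_markov(q: Kernel, tol_zero: float = 0.0) -> DecoratedPermutation:
    """The decorated permutation of a Markov chain.

    States are numbered 1..n in the kernel's label order.  Transient states
    map to themselves; recurrent states follow the window rule over their
    communicating class.  The result depends only on the support pattern of
    the kernel (entries > ``tol_zero``).
    """
    cs = communicating_classes(q, tol_zero)
    n = q.n
    pos = {a: i + 1 for i, a in enumerate(q.row_labels)}
    images = [0] * n
    for cls, rec in zip(cs.classes, cs.recurrent):
        members = {pos[s] for s in cls}
        for a in members:
            images[a - 1] = _window_image(a, members, n) if rec else a
    return validate(images, n)


def from_graph(g: nx.DiGraph) -> DecoratedPermutation:
    """The decorated permutation of a directed graph.

    Nodes are numbered 1..n in sorted node order.  A strongly connected
    component with no internal edge (an isolated or purely feed-through node)
    or with any edge leaving it is treated as transient: sigma(a) = a for its
    members.  Every other component follows the window rule, so a node whose
    only link is a self-loop gets sigma(a) = a+n.  On the support digraph of a
    kernel this reproduces :func:`from_markov` exactly.
    """
    nodes = sorted(g.nodes())
    n = len(nodes)
    pos = {v: i + 1 for i, v in enumerate(nodes)}
    images = [0] * n
    for scc in nx.strongly_connected_components(g):
        members = {pos[v] for v in scc}
        internal = any(g.has_edge(u, v) for u in scc for v in scc)
        leaky = any(w not in scc for u in scc for w in g.successors(u))
        if internal and not leaky:
            for a in members:
                images[a - 1] = _window_image(a, members, n)
        else:
            for a in members:
                images[a - 1] = a
    return validate(images, n)


# ---------------------------------------------------------------------------
# Grassmannian labeling
# ---------------------------------------------------------------------------

def _rank(mat: np.ndarray, tol: float) -> int:
    if mat.shape[1] == 0:
        return 0
    if mat.dtype == object:
        return _rank_exact(mat)
    return int(np.linalg.matrix_rank(mat, tol=tol * max(1.0, float(np.abs(mat).max()))))


def _rank_exact(mat: np.ndarray) -> int:
    rows = [[Fraction(x) for x in row] for row in mat.tolist()]
    rank = 0
    ncols = len(rows[0]) if rows else 0
    r = 0
    for c in range(ncols):
        sel = next((i for i in range(r, len(rows)) if rows[i][c] != 0), None)
        if sel is None:
            continue
        rows[r], rows[sel] = rows[sel], rows[r]
        pv = rows[r][c]
        rows[r] = [v / pv for v in rows[r]]
        for i in range(len(rows)):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        r += 1
        rank += 1
    return rank


def from_grassmannian(c: np.ndarray, tol: float = 1e-9) -> DecoratedPermutation:
    """Decorated permutation of a full-rank k x n matrix.

    Repeat the n columns once to form a k x 2n matrix.  A zero column a maps
    to itself; otherwise sigma(a) is the first b > a such that column a lies
    in the span of columns a+1..b of the expanded matrix (span membership by
    rank comparison, relative tolerance ``tol``; exact over Fractions for
    object-dtype input).
    """
    c = np.asarray(c)
    if c.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    k, n = c.shape
    if _rank(c, tol) != k:
        raise ValueError(f"matrix must have full row rank {k}")
    doubled = np.concatenate([c, c], axis=1)
    zero_tol = 0 if c.dtype == object else tol * max(1.0, float(np.abs(c).max()))
    images = [0] * n
    for a in range(1, n + 1):
        col_a = doubled[:, a - 1 : a]
        if c.dtype == object:
            is_zero = all(v == 0 for v in col_a.ravel())
        else:
            is_zero = bool(np.all(np.abs(col_a) <= zero_tol))
        if is_zero:
            images[a - 1] = a
            continue
        for b in range(a + 1, 2 * n + 1):
            span = doubled[:, a : b]
            if _rank(span, tol) == _rank(np.concatenate([span, col_a], axis=1), tol):
                images[a - 1] = b
                break
        else:  # pragma: no cover - full span reached by b = a + n
            raise AssertionError("span rule must terminate")
    return validate(images, n)
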