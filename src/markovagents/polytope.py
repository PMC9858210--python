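"""The Markov polytope Mn and the fusion simplex Fn.

Mn is the set of all n x n row-stochastic matrices: a product of n unit
(n-1)-simplices, hence an n(n-1)-dimensional polytope whose n^n vertices are
the deterministic (0/1) kernels.  Its cells are labeled by decorated
permutations: the cell of a kernel depends only on its support pattern, so
the full cell census is a finite enumeration over row supports.

Fn, the fusion simplex, is the (n-1)-simplex of rank-1 idempotent kernels --
all rows equal to a single probability vector mu.  Reaching Fn under the
kernel flow "fuses" the n qualia into one mixture quale with weights mu.  On
M2 (coordinates x = Q(1,2), y = Q(2,1)) the fusion simplex is the
anti-diagonal x + y = 1, the sink line of the flow field
(dx/dtau, dy/dtau) = (x(1-x-y), y(1-x-y)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import networkx as nx
import numpy as np

from .decorated import DecoratedPermutation, from_markov
from .kernels import Kernel, is_idempotent, validate_kernel

__all__ = [
    "FusionPoint",
    "FlowFieldM2",
    "NotFusedError",
    "m2_kernel",
    "polytope_summary",
    "polytope_vertices",
    "vertex_adjacency",
    "cell_of",
    "enumerate_support_cells",
    "fusion_kernel",
    "fuse",
    "invariant_line_slope",
    "flow_field_m2",
    "qualia_mix",
]


class NotFusedError(ValueError):
    """Raised by :func:`fuse` on kernels outside the fusion simplex."""


@dataclass(frozen=True)
class FusionPoint:
    """A point of Fn: the mixture weights of a fused quale (an invariant
    probability vector over the constituent qualia labels)."""

    labels: tuple
    weights: tuple

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        w = tuple(self.weights)
        if len(w) != len(self.labels):
            raise ValueError("one weight per label required")
        if any(v < 0 for v in w):
            raise ValueError(f"negative weight in {w}")
        if abs(sum(w) - 1) > 1e-12:
            raise ValueError(f"weights {w} do not sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class FlowFieldM2:
    """Kernel-derivative vectors sampled on a grid over the unit square M2."""

    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray


def m2_kernel(x, y, labels: Sequence = (1, 2)) -> Kernel:
    """The two-state kernel [[1-x, x], [y, 1-y]] at the point (x, y) of M2."""
    if isinstance(x, Fraction) or isinstance(y, Fraction):
        x, y = Fraction(x), Fraction(y)
        m = np.empty((2, 2), dtype=object)
        m[0, 0], m[0, 1] = 1 - x, x
        m[1, 0], m[1, 1] = y, 1 - y
    else:
        m = np.array([[1 - x, x], [y, 1 - y]], dtype=float)
    return validate_kernel(m, labels, labels)


def polytope_summary(n: int) -> dict:
    """Dimension n(n-1) and vertex count n^n of the Markov polytope Mn."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    return {"dimension": n * (n - 1), "vertex_count": n ** n}


def _vertex_kernel(f: tuple[int, ...], n: int) -> Kernel:
    m = np.zeros((n, n))
    for i, j in enumerate(f):
        m[i, j] = 1.0
    labels = tuple(range(1, n + 1))
    return Kernel(labels, labels, m)


def polytope_vertices(n: int, guard: int = 6) -> list[Kernel]:
    """All n^n deterministic kernels, enumerated in row-major function order
    (the vertex for f maps state i+1 to state f(i)+1)."""
    polytope_summary(n)
    if n > guard:
        raise ValueError(f"n={n} exceeds the enumeration guard {guard} ({n**n} vertices)")
    return [
        _vertex_kernel(f, n) for f in itertools.product(range(n), repeat=n)
    ]


def vertex_adjacency(n: int, guard: int = 5) -> nx.Graph:
    """Edge graph of Mn on the deterministic vertices: two vertices are
    adjacent iff they differ in exactly one row (the edge rule of a product
    of simplices).  The graph is regular of degree n(n-1)."""
    polytope_summary(n)
    if n > guard:
        raise ValueError(f"n={n} exceeds the adjacency guard {guard}")
    g = nx.Graph()
    verts = list(itertools.product(range(n), repeat=n))
    g.add_nodes_from(verts)
    for f in verts:
        for i in range(n):
            for j in range(n):
                if j != f[i]:
                    h = f[:i] + (j,) + f[i + 1 :]
                    g.add_edge(f, h)
    return g


def cell_of(q: Kernel, tol_zero: float = 0.0) -> DecoratedPermutation:
    """The decorated permutation labeling the cell of Mn containing Q."""
    return from_markov(q, tol_zero)


def enumerate_support_cells(n: int, guard: int = 3) -> set[DecoratedPermutation]:
    """All cell labels of Mn, by exhausting row-support patterns.

    A cell's decorated permutation depends only on which entries are positive,
    so enumerating the (2^n - 1)^n support patterns (each row a non-empty
    subset of states, represented by a kernel uniform on its support) yields
    the complete, exact census of cells.
    """
    polytope_summary(n)
    if n > guard:
        raise ValueError(f"n={n} exceeds the support-enumeration guard {guard}")
    labels = tuple(range(1, n + 1))
    subsets = [s for r in range(1, n + 1) for s in itertools.combinations(range(n), r)]
    cells: set[DecoratedPermutation] = set()
    for rows in itertools.product(subsets, repeat=n):
        m = np.zeros((n, n))
        for i, sup in enumerate(rows):
            m[i, list(sup)] = 1.0 / len(sup)
        cells.add(from_markov(Kernel(labels, labels, m)))
    return cells


def fusion_kernel(point: FusionPoint) -> Kernel:
    """The rank-1 idempotent kernel with every row equal to the fusion
    weights; its unique invariant measure is the fusion point itself."""
    n = point.n
    w = point.weights
    if any(isinstance(v, Fraction) for v in w):
        m = np.empty((n, n), dtype=object)
        for i in range(n):
            m[i, :] = [Fraction(v) for v in w]
    else:
        m = np.tile(np.asarray(w, dtype=float), (n, 1))
    return validate_kernel(m, point.labels, point.labels)


def fuse(q: Kernel, tol: float = 1e-9) -> FusionPoint:
    """Read the fused quale off a kernel on the fusion simplex.

    Requires Q idempotent and of rank 1 (all rows equal) within ``tol``;
    otherwise raises :class:`NotFusedError` naming which condition failed.
    """
    if not q.is_square:
        raise NotFusedError("fusion requires a square kernel")
    if not is_idempotent(q, tol):
        raise NotFusedError("not fused: kernel is not idempotent (Q^2 != Q)")
    m = q.matrix
    spread = float(np.max(np.abs((m - m[0:1, :]).astype(float))))
    if spread > tol:
        raise NotFusedError(
            f"not fused: kernel has rank > 1 (rows differ by up to {spread:.3g})"
        )
    row = m[0, :]
    if q.exact:
        weights = tuple(row.tolist())
    else:
        weights = tuple(float(v) for v in row / row.sum())
    return FusionPoint(labels=q.row_labels, weights=weights)


def invariant_line_slope(alpha: float):
    """Slope alpha/(1-alpha) of the M2 line of kernels sharing the invariant
    measure (alpha, 1-alpha): the locus y = alpha/(1-alpha) x."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha}")
    return alpha / (1 - alpha)


def flow_field_m2(grid_resolution: int) -> FlowFieldM2:
    """The kernel-derivative vector field on a regular grid over M2.

    At (x, y) the off-diagonal derivative of Q^2 - Q is
    (x(1-x-y), y(1-x-y)); it vanishes exactly at the identity corner (0,0)
    and on the fusion line x + y = 1.
    """
    if grid_resolution < 2:
        raise ValueError("grid resolution must be at least 2")
    t = np.linspace(0.0, 1.0, grid_resolution)
    x, y = np.meshgrid(t, t, indexing="ij")
    s = 1.0 - x - y
    return FlowFieldM2(x=x, y=y, dx=x * s, dy=y * s)


def qualia_mix(point: FusionPoint, palette: dict) -> tuple:
    """Convex combination of palette RGB colors with the fusion weights."""
    missing = [l for l in point.labels if l not in palette]
    if missing:
        raise KeyError(f"palette missing entries for labels {missing}")
    rgb = np.zeros(3)
    for label, w in zip(point.labels, point.weights):
        rgb += float(w) * np.asarray(palette[label], dtype=float)
    return tuple(rgb)
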