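"""Row-stochastic (Markovian) kernel algebra.

A finite Markovian kernel is a labeled matrix with non-negative entries whose
rows each sum to one.  Square kernels are Markov chains on their label set and
admit the usual structural analysis: communicating classes, recurrence,
periods, invariant measures, and the long-run limit ("flow") of the kernel
powers.  Rectangular kernels arise as the perception/decision/action channels
of agents and only support composition.

Two numeric regimes are supported transparently.  Matrices of Python
``fractions.Fraction`` entries (held in an object-dtype array) are processed
with exact rational arithmetic; ordinary float matrices use numpy linear
algebra.  Exactness matters for bit-exact round trips and for certifying
idempotence on polytope boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Kernel",
    "ClassStructure",
    "PeriodicityReport",
    "KernelValidationError",
    "ShapeError",
    "TOL_ROW",
    "TOL_IDEMPOTENT",
    "validate_kernel",
    "compose",
    "power",
    "communicating_classes",
    "invariant_measures",
    "kernel_derivative",
    "flow",
    "is_idempotent",
]

#: default tolerance on row sums
TOL_ROW = 1e-9
#: default tolerance for the idempotence test max|Q^2 - Q|
TOL_IDEMPOTENT = 1e-9


class KernelValidationError(ValueError):
    """A matrix failed the Markovian-kernel axioms."""


class ShapeError(ValueError):
    """Kernel shapes/labels do not chain for the requested operation."""


def _is_exact(matrix: np.ndarray) -> bool:
    return matrix.dtype == object


def _as_array(matrix) -> np.ndarray:
    arr = np.asarray(matrix)
    if arr.dtype == object:
        return arr
    return arr.astype(float)


@dataclass(frozen=True)
class Kernel:
    """A labeled row-stochastic matrix.

    Parameters
    ----------
    row_labels, col_labels
        Ordered label tuples.  A kernel is *square* (a Markov chain) iff the
        two tuples are equal.
    matrix
        2-D array, float or ``Fraction`` (object dtype) entries.

    Construct through :func:`validate_kernel` unless the matrix is already
    known to be valid.
    """

    row_labels: tuple
    col_labels: tuple
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        object.__setattr__(self, "matrix", _as_array(self.matrix))

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels

    @property
    def n(self) -> int:
        """State count; only meaningful for square kernels."""
        return len(self.row_labels)

    @property
    def exact(self) -> bool:
        """True when entries are exact rationals (Fraction, object dtype)."""
        return _is_exact(self.matrix)

    def __eq__(self, other):
        if not isinstance(other, Kernel):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and self.matrix.shape == other.matrix.shape
            and bool(np.all(self.matrix == other.matrix))
        )

    def __matmul__(self, other: "Kernel") -> "Kernel":
        return compose(self, other)

    def allclose(self, other: "Kernel", tol: float = 1e-12) -> bool:
        if self.row_labels != other.row_labels or self.col_labels != other.col_labels:
            return False
        return float(np.max(np.abs(self.matrix - other.matrix))) <= tol

    def to_float(self) -> "Kernel":
        return Kernel(self.row_labels, self.col_labels, self.matrix.astype(float))

    def support_graph(self, tol_zero: float = 0.0) -> nx.DiGraph:
        """Digraph on the states with an edge where Q(a,b) > tol_zero.

        Square kernels only.  Entries at or below ``tol_zero`` are treated as
        structural zeros (renormalization dust).
        """
        _require_square(self)
        g = nx.DiGraph()
        g.add_nodes_from(self.row_labels)
        m = self.matrix
        for i, a in enumerate(self.row_labels):
            for j, b in enumerate(self.col_labels):
                if m[i, j] > tol_zero:
                    g.add_edge(a, b)
        return g


@dataclass(frozen=True)
class ClassStructure:
    """Partition of a chain's states into communicating classes.

    ``classes`` is a tuple of frozensets ordered by smallest state (label
    order); ``recurrent`` flags each class; ``absorbing`` is the set of
    absorbing states (singleton recurrent with self-probability one);
    ``periods`` holds the period of each recurrent class (None for transient).
    """

    states: tuple
    classes: tuple
    recurrent: tuple
    absorbing: frozenset
    periods: tuple

    def class_of(self, state) -> frozenset:
        for c in self.classes:
            if state in c:
                return c
        raise KeyError(state)

    def is_recurrent(self, state) -> bool:
        for c, r in zip(self.classes, self.recurrent):
            if state in c:
                return r
        raise KeyError(state)

    @property
    def recurrent_classes(self) -> tuple:
        return tuple(c for c, r in zip(self.classes, self.recurrent) if r)

    @property
    def transient_states(self) -> frozenset:
        out = set()
        for c, r in zip(self.classes, self.recurrent):
            if not r:
                out |= c
        return frozenset(out)


@dataclass(frozen=True)
class PeriodicityReport:
    """Returned by :func:`flow` in power mode when the limit does not exist."""

    periodic_classes: tuple  # (frozenset, period) pairs

    def __str__(self):
        parts = ", ".join(
            f"{{{', '.join(map(str, sorted(c)))}}} period {p}"
            for c, p in self.periodic_classes
        )
        return f"power limit undefined; periodic classes: {parts}"


# ---------------------------------------------------------------------------
# construction / validation
# ---------------------------------------------------------------------------

def validate_kernel(
    matrix,
    row_labels: Sequence | None = None,
    col_labels: Sequence | None = None,
    tol_row: float = TOL_ROW,
) -> Kernel:
    """Validate a matrix as a Markovian kernel.

    Rows within ``tol_row`` of summing to one are renormalized exactly to one;
    anything further off is rejected.  Negative entries are rejected with the
    offending cell named; bad row sums are rejected with the row named.
    """
    arr = _as_array(matrix)
    if arr.ndim != 2 or arr.size == 0:
        raise KernelValidationError("kernel matrix must be a non-empty 2-D array")
    nr, nc = arr.shape
    if row_labels is None:
        row_labels = tuple(range(1, nr + 1))
    if col_labels is None:
        col_labels = tuple(range(1, nc + 1))
    row_labels, col_labels = tuple(row_labels), tuple(col_labels)
    if len(row_labels) != nr or len(col_labels) != nc:
        raise ShapeError(
            f"label counts ({len(row_labels)}, {len(col_labels)}) do not match "
            f"matrix shape {arr.shape}"
        )
    if len(set(row_labels)) != nr or len(set(col_labels)) != nc:
        raise KernelValidationError("labels must be unique")
    exact = _is_exact(arr)
    if not exact and not np.all(np.isfinite(arr)):
        raise KernelValidationError("kernel entries must be finite")
    for i in range(nr):
        for j in range(nc):
            if arr[i, j] < 0:
                raise KernelValidationError(
                    f"negative entry at cell ({row_labels[i]}, {col_labels[j]}): "
                    f"{arr[i, j]}"
                )
    out = arr.copy()
    for i in range(nr):
        s = out[i].sum()
        if abs(s - 1) > tol_row:
            raise KernelValidationError(
                f"row {row_labels[i]} sum {float(s):.10g} is not 1 "
                f"within tolerance {tol_row:g}"
            )
        if s != 1:
            out[i] = out[i] / s
    return Kernel(row_labels, col_labels, out)


def _require_square(k: Kernel):
    if not k.is_square:
        raise ShapeError(
            f"operation requires a square kernel; got row labels {k.row_labels} "
            f"!= col labels {k.col_labels}"
        )


def _identity_like(k: Kernel) -> Kernel:
    n = k.n
    if k.exact:
        m = np.empty((n, n), dtype=object)
        for i in range(n):
            for j in range(n):
                m[i, j] = Fraction(int(i == j))
    else:
        m = np.eye(n)
    return Kernel(k.row_labels, k.row_labels, m)


# ---------------------------------------------------------------------------
# algebra
# ---------------------------------------------------------------------------

def compose(k1: Kernel, k2: Kernel) -> Kernel:
    """Kernel composition = matrix product; labels must chain."""
    if k1.col_labels != k2.row_labels:
        raise ShapeError(
            f"cannot compose: first kernel columns {k1.col_labels} != "
            f"second kernel rows {k2.row_labels}"
        )
    prod = k1.matrix @ k2.matrix
    out = Kernel(k1.row_labels, k2.col_labels, prod)
    for i in range(out.shape[0]):
        assert abs(out.matrix[i].sum() - 1) <= 1e-8, "composition broke stochasticity"
    return out


def power(q: Kernel, m: int) -> Kernel:
    """Q^m by repeated squaring; Q^0 is the identity."""
    _require_square(q)
    if not isinstance(m, (int, np.integer)) or m < 0:
        raise ValueError(f"power exponent must be a non-negative integer, got {m!r}")
    result = _identity_like(q)
    base = q
    m = int(m)
    while m:
        if m & 1:
            result = compose(result, base)
        m >>= 1
        if m:
            base = compose(base, base)
    return result


def kernel_derivative(q: Kernel) -> np.ndarray:
    """The discrete kernel derivative Q^2 - Q (rows sum to zero, not Markovian).

    On the two-state polytope with coordinates x = Q(1,2), y = Q(2,1) the
    off-diagonals are (x(1-x-y), y(1-x-y)), the flow field of the unit square.
    """
    _require_square(q)
    return q.matrix @ q.matrix - q.matrix


def is_idempotent(q: Kernel, tol: float = TOL_IDEMPOTENT) -> bool:
    """True iff max|Q^2 - Q| <= tol.  Idempotent kernels are stationary."""
    _require_square(q)
    return float(np.max(np.abs(kernel_derivative(q)))) <= tol


# ---------------------------------------------------------------------------
# chain structure
# ---------------------------------------------------------------------------

def communicating_classes(q: Kernel, tol_zero: float = 0.0) -> ClassStructure:
    """Communicating classes of a square kernel.

    Classes are the strongly connected components of the support digraph
    (entries > ``tol_zero``).  A class is recurrent iff no support edge leaves
    it; absorbing states are singleton recurrent classes with self-probability
    one.  Recurrent classes carry their period (gcd of support-cycle lengths).
    Classes are returned sorted by their smallest member in label order.
    """
    _require_square(q)
    g = q.support_graph(tol_zero)
    order = {a: i for i, a in enumerate(q.row_labels)}
    sccs = [frozenset(c) for c in nx.strongly_connected_components(g)]
    sccs.sort(key=lambda c: min(order[a] for a in c))
    recurrent = []
    periods = []
    for c in sccs:
        leaves = any(v not in c for a in c for v in g.successors(a))
        recurrent.append(not leaves)
        periods.append(_class_period(g, c) if not leaves else None)
    absorbing = set()
    for c, r in zip(sccs, recurrent):
        if r and len(c) == 1:
            (a,) = c
            i = order[a]
            if abs(q.matrix[i, i] - 1) <= TOL_ROW:
                absorbing.add(a)
    return ClassStructure(
        states=q.row_labels,
        classes=tuple(sccs),
        recurrent=tuple(recurrent),
        absorbing=frozenset(absorbing),
        periods=tuple(periods),
    )


def _class_period(g: nx.DiGraph, cls: frozenset) -> int:
    """Period of a strongly connected class: gcd of (level(u)+1-level(v)) over
    internal edges u->v from any BFS levelling."""
    root = next(iter(cls))
    level = {root: 0}
    queue = [root]
    while queue:
        u = queue.pop()
        for v in g.successors(u):
            if v in cls and v not in level:
                level[v] = level[u] + 1
                queue.append(v)
    d = 0
    for u in cls:
        for v in g.successors(u):
            if v in cls:
                d = math.gcd(d, level[u] + 1 - level[v])
    return abs(d) if d else 1


# ---------------------------------------------------------------------------
# invariant measures and flow
# ---------------------------------------------------------------------------

def _solve_stationary_exact(sub: np.ndarray) -> list:
    """Stationary vector of an irreducible Fraction matrix by Gaussian
    elimination on (Q^T - I) with the normalization row appended."""
    m = sub.shape[0]
    aug = [[Fraction(sub[j, i]) - Fraction(int(i == j)) for j in range(m)] + [Fraction(0)]
           for i in range(m)]
    aug.append([Fraction(1)] * m + [Fraction(1)])
    # Gauss-Jordan with partial (first-nonzero) pivoting over rationals
    rows, cols = len(aug), m
    piv_row = 0
    pivots = []
    for col in range(cols):
        sel = next((r for r in range(piv_row, rows) if aug[r][col] != 0), None)
        if sel is None:
            continue
        aug[piv_row], aug[sel] = aug[sel], aug[piv_row]
        pv = aug[piv_row][col]
        aug[piv_row] = [v / pv for v in aug[piv_row]]
        for r in range(rows):
            if r != piv_row and aug[r][col] != 0:
                f = aug[r][col]
                aug[r] = [a - f * b for a, b in zip(aug[r], aug[piv_row])]
        pivots.append(col)
        piv_row += 1
        if piv_row == rows:
            break
    sol = [Fraction(0)] * m
    for r, col in enumerate(pivots):
        sol[col] = aug[r][-1]
    return sol


def _solve_stationary_float(sub: np.ndarray) -> np.ndarray:
    m = sub.shape[0]
    a = np.vstack([sub.T - np.eye(m), np.ones((1, m))])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    sol = np.clip(sol, 0.0, None)
    return sol / sol.sum()


def invariant_measures(q: Kernel, tol_zero: float = 0.0) -> list[np.ndarray]:
    """Extremal invariant probability measures of a square kernel.

    One measure per recurrent class, supported on that class, in class order
    (classes sorted by smallest state).  Every invariant measure of the chain
    is a convex combination of these.  The list has one element iff the chain
    has a unique recurrent class.
    """
    _require_square(q)
    cs = communicating_classes(q, tol_zero)
    order = {a: i for i, a in enumerate(q.row_labels)}
    out = []
    for cls in cs.recurrent_classes:
        idx = sorted(order[a] for a in cls)
        sub = q.matrix[np.ix_(idx, idx)]
        if q.exact:
            pi = _solve_stationary_exact(sub)
            mu = np.empty(q.n, dtype=object)
            mu[:] = Fraction(0)
            for pos, i in enumerate(idx):
                mu[i] = pi[pos]
        else:
            pi = _solve_stationary_float(sub)
            mu = np.zeros(q.n)
            mu[idx] = pi
        out.append(mu)
    return out


def _absorption_probabilities(q: Kernel, cs: ClassStructure):
    """For each transient state, the probability of absorption into each
    recurrent class.  Returns (transient index list, matrix T x R)."""
    order = {a: i for i, a in enumerate(q.row_labels)}
    t_idx = sorted(order[a] for a in cs.transient_states)
    r_classes = cs.recurrent_classes
    if not t_idx:
        return t_idx, None
    m = q.matrix
    qtt = m[np.ix_(t_idx, t_idx)]
    rhs_cols = []
    for cls in r_classes:
        c_idx = sorted(order[a] for a in cls)
        col = m[np.ix_(t_idx, c_idx)].sum(axis=1)
        rhs_cols.append(col)
    if q.exact:
        nt = len(t_idx)
        b = np.empty((nt, len(r_classes)), dtype=object)
        for k, col in enumerate(rhs_cols):
            sol = _solve_linear_exact(qtt, col, nt)
            for i in range(nt):
                b[i, k] = sol[i]
        return t_idx, b
    a = np.eye(len(t_idx)) - qtt.astype(float)
    b = np.linalg.solve(a, np.column_stack(rhs_cols).astype(float))
    return t_idx, b


def _solve_linear_exact(qtt: np.ndarray, col, nt: int) -> list:
    """Solve (I - Qtt) x = col over Fractions."""
    aug = [[Fraction(int(i == j)) - Fraction(qtt[i, j]) for j in range(nt)]
           + [Fraction(col[i])] for i in range(nt)]
    for c in range(nt):
        sel = next(r for r in range(c, nt) if aug[r][c] != 0)
        aug[c], aug[sel] = aug[sel], aug[c]
        pv = aug[c][c]
        aug[c] = [v / pv for v in aug[c]]
        for r in range(nt):
            if r != c and aug[r][c] != 0:
                f = aug[r][c]
                aug[r] = [a - f * b for a, b in zip(aug[r], aug[c])]
    return [aug[i][-1] for i in range(nt)]


def flow(q: Kernel, mode: str = "power", tol_zero: float = 0.0):
    """Long-run limit of the kernel powers, computed algebraically.

    mode "power"
        The limit P = lim Q^m, which exists iff every recurrent class is
        aperiodic.  If some class is periodic a :class:`PeriodicityReport`
        naming the classes and periods is returned instead of a kernel.
    mode "cesaro"
        The Cesaro limit lim (1/N) sum_{m<N} Q^m, which always exists and
        coincides with the power limit when the latter exists.

    The limit is assembled exactly from the class structure: each recurrent
    state's row is its class's stationary measure; each transient state's row
    mixes the stationary measures with its absorption probabilities.  The
    result is always idempotent.
    """
    _require_square(q)
    if mode not in ("power", "cesaro"):
        raise ValueError(f"unknown flow mode {mode!r}")
    cs = communicating_classes(q, tol_zero)
    if mode == "power":
        periodic = [
            (c, p)
            for c, r, p in zip(cs.classes, cs.recurrent, cs.periods)
            if r and p and p > 1
        ]
        if periodic:
            return PeriodicityReport(tuple(periodic))
    measures = invariant_measures(q, tol_zero)
    order = {a: i for i, a in enumerate(q.row_labels)}
    n = q.n
    if q.exact:
        limit = np.empty((n, n), dtype=object)
        limit[:] = Fraction(0)
    else:
        limit = np.zeros((n, n))
    for cls, mu in zip(cs.recurrent_classes, measures):
        for a in cls:
            limit[order[a], :] = mu
    t_idx, absorb = _absorption_probabilities(q, cs)
    if t_idx:
        for pos, i in enumerate(t_idx):
            if q.exact:
                row = np.empty(n, dtype=object)
                row[:] = Fraction(0)
                for k, mu in enumerate(measures):
                    row = row + absorb[pos, k] * mu
            else:
                row = np.zeros(n)
                for k, mu in enumerate(measures):
                    row += absorb[pos, k] * mu
            limit[i, :] = row
    return Kernel(q.row_labels, q.row_labels, limit)
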