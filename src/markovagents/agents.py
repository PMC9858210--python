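"""Conscious agents: kernel 6-tuples and their combinations.

An agent is a triple of finite label sets -- experiences X, actions G, world
states W -- together with three Markovian kernels that chain around them:
perception P: W -> X, decision D: X -> G, action A: G -> W.  Composing the
three gives the agent's qualia kernel Q = D A P, a Markov chain on X that
captures the agent's sequential experiencing with every other internal detail
integrated out.

Two agents combine in two ways.  The product combination takes cartesian
label sets and Kronecker-product kernels; the resulting qualia kernel factors
as Q1 (x) Q2, block-diagonal, so the constituents do not interact.  The union
combination instead places the constituent qualia side by side and admits
arbitrary Markovian cross terms between them; for two 1-agents this is the
two-parameter family Q(x, y) = [[1-x, x], [y, 1-y]] on the unit square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kernels import Kernel, ShapeError, compose, validate_kernel

__all__ = [
    "ConsciousAgent",
    "make_agent",
    "qualia_kernel",
    "combine_product",
    "combine_union",
    "realize_agent",
]


@dataclass(frozen=True)
class ConsciousAgent:
    """A 6-tuple (X, G, W, P, D, A) of label sets and chained kernels."""

    X: tuple
    G: tuple
    W: tuple
    P: Kernel  # W -> X
    D: Kernel  # X -> G
    A: Kernel  # G -> W


def make_agent(P: Kernel, D: Kernel, A: Kernel) -> ConsciousAgent:
    """Validate the shape chain W --P--> X --D--> G --A--> W and build the agent."""
    if D.col_labels != A.row_labels:
        raise ShapeError(
            f"D columns {D.col_labels} must equal A rows {A.row_labels} (action set G)"
        )
    if A.col_labels != P.row_labels:
        raise ShapeError(
            f"A columns {A.col_labels} must equal P rows {P.row_labels} (world set W)"
        )
    if P.col_labels != D.row_labels:
        raise ShapeError(
            f"P columns {P.col_labels} must equal D rows {D.row_labels} "
            f"(experience set X)"
        )
    return ConsciousAgent(
        X=P.col_labels, G=D.col_labels, W=A.col_labels, P=P, D=D, A=A
    )


def qualia_kernel(agent: ConsciousAgent) -> Kernel:
    """Q = D A P, a square Markov kernel on the experience set X."""
    return compose(compose(agent.D, agent.A), agent.P)


def _product_labels(l1: Sequence, l2: Sequence) -> tuple:
    """Cartesian product labels, first factor major (lexicographic)."""
    return tuple((a, b) for a in l1 for b in l2)


def _kron(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    if m1.dtype == object or m2.dtype == object:
        r1, c1 = m1.shape
        r2, c2 = m2.shape
        out = np.empty((r1 * r2, c1 * c2), dtype=object)
        for i in range(r1):
            for j in range(c1):
                out[i * r2 : (i + 1) * r2, j * c2 : (j + 1) * c2] = m1[i, j] * m2
        return out
    return np.kron(m1, m2)


def tensor(k1: Kernel, k2: Kernel) -> Kernel:
    """Kronecker product of kernels on cartesian-product labels."""
    return Kernel(
        _product_labels(k1.row_labels, k2.row_labels),
        _product_labels(k1.col_labels, k2.col_labels),
        _kron(k1.matrix, k2.matrix),
    )


def combine_product(a1: ConsciousAgent, a2: ConsciousAgent) -> ConsciousAgent:
    """Product combination: cartesian label sets, tensor-product kernels.

    The qualia kernel of the product agent is Q1 (x) Q2 (mixed-product
    property), block-diagonal when the factors do not interact.
    """
    return make_agent(
        P=tensor(a1.P, a2.P), D=tensor(a1.D, a2.D), A=tensor(a1.A, a2.A)
    )


def combine_union(qualia_labels: Sequence, cross) -> Kernel:
    """Union combination of n 1-agents with arbitrary Markovian cross terms.

    ``cross`` is any valid n x n row-stochastic matrix over the pooled qualia
    labels; entry (i, j) is the probability that the next experience is quale
    j given that the current one is quale i.  Zero off-diagonals mean the
    constituent agents do not interact.
    """
    labels = tuple(qualia_labels)
    k = validate_kernel(cross, labels, labels)
    return k


def realize_agent(q: Kernel) -> ConsciousAgent:
    """A constructive witness that any Markov kernel is some agent's qualia
    kernel: take X = G = W = states, D = Q, A = P = identity.  The round trip
    qualia_kernel(realize_agent(Q)) == Q holds exactly (no arithmetic on Q)."""
    if not q.is_square:
        raise ShapeError("realize_agent requires a square kernel")
    n = q.n
    if q.exact:
        from fractions import Fraction

        eye = np.empty((n, n), dtype=object)
        for i in range(n):
            for j in range(n):
                eye[i, j] = Fraction(int(i == j))
    else:
        eye = np.eye(n)
    ident = Kernel(q.row_labels, q.row_labels, eye)
    return make_agent(P=ident, D=q, A=ident)
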