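"""Bridge decomposition and on-shell (plabic) diagrams.

A decorated permutation is peeled into a minimal sequence of adjacent
transpositions: repeatedly take the lexicographically first pair (a, c) with
a < c, sigma(a) < sigma(c), both endpoints non-fixed, and every number
strictly between a and c a decorated fixed point; record (a, c) and swap the
images at positions a and c.  The process ends at a decoration of the
identity.  (Restricting the endpoints to non-fixed positions is what makes
the peeling terminate at an identity decoration; with fixed endpoints
admitted, chains such as [1,3,5] can be driven into a dead end.)

Replaying the transpositions as BCFW bridges over a row of lollipops (one per
leg, colored by the residual decoration) builds a reduced bicolored planar
diagram whose boundary trips -- turn left at white nodes, right at black,
straight through degree-2 nodes -- read the decorated permutation back off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .decorated import DecoratedPermutation, validate

__all__ = [
    "BridgeDiagram",
    "DiagramError",
    "decompose",
    "decompose_with_residual",
    "build_diagram",
    "diagram_of",
    "read_permutation",
    "simplify",
]

WHITE = "white"
BLACK = "black"
BOUNDARY = "boundary"


class DiagramError(ValueError):
    pass


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _is_fixed(images: list[int], a: int, n: int) -> bool:
    return images[a - 1] in (a, a + n)


def _first_bridge(images: list[int], n: int) -> tuple[int, int] | None:
    """Lexicographically first admissible adjacent transposition (a, c)."""
    for a in range(1, n + 1):
        if _is_fixed(images, a, n):
            continue
        # the only candidate c for this a is the next non-fixed position:
        # anything further has a non-fixed number strictly between.
        for c in range(a + 1, n + 1):
            if _is_fixed(images, c, n):
                continue
            if images[a - 1] < images[c - 1]:
                return a, c
            break
    return None


def decompose_with_residual(
    sigma: DecoratedPermutation,
) -> tuple[list[tuple[int, int]], DecoratedPermutation]:
    """Bridge decomposition; returns (transpositions, residual identity
    decoration).  Replaying the swaps in order reduces sigma to the residual."""
    n = sigma.n
    images = list(sigma.images)
    out: list[tuple[int, int]] = []
    for _ in range(n * n + 1):
        if all(_is_fixed(images, a, n) for a in range(1, n + 1)):
            return out, DecoratedPermutation(n, tuple(images))
        pair = _first_bridge(images, n)
        if pair is None:  # pragma: no cover - cannot happen for valid input
            raise DiagramError(f"no admissible transposition for {images}")
        a, c = pair
        assert a < c and images[a - 1] < images[c - 1]
        out.append(pair)
        images[a - 1], images[c - 1] = images[c - 1], images[a - 1]
    raise DiagramError(  # pragma: no cover - n^2 guard
        f"decomposition did not terminate within {n * n} steps"
    )


def decompose(sigma: DecoratedPermutation) -> list[tuple[int, int]]:
    """The minimal adjacent-transposition chain of a decorated permutation."""
    return decompose_with_residual(sigma)[0]


# ---------------------------------------------------------------------------
# diagrams
# ---------------------------------------------------------------------------

@dataclass
class BridgeDiagram:
    """A bicolored planar graph with boundary legs 1..n.

    ``colors`` maps node id -> white/black/boundary; ``order`` maps node id
    -> list of edge ids in counterclockwise cyclic order around the node;
    ``edges`` maps edge id -> (node, node).  Boundary nodes are ("b", i).
    """

    n: int
    colors: dict = field(default_factory=dict)
    order: dict = field(default_factory=dict)
    edges: dict = field(default_factory=dict)
    _next_edge: int = 0
    _next_node: int = 0

    # -- construction helpers ---------------------------------------------
    def _new_edge(self, u, v) -> int:
        e = self._next_edge
        self._next_edge += 1
        self.edges[e] = (u, v)
        return e

    def _new_node(self, color) -> tuple:
        node = ("v", self._next_node)
        self._next_node += 1
        self.colors[node] = color
        self.order[node] = []
        return node

    def other_end(self, e: int, node):
        u, v = self.edges[e]
        return v if node == u else u

    def degree(self, node) -> int:
        return len(self.order[node])

    @classmethod
    def empty(cls, n: int) -> "BridgeDiagram":
        d = cls(n=n)
        for i in range(1, n + 1):
            b = ("b", i)
            d.colors[b] = BOUNDARY
            d.order[b] = []
        return d

    def add_lollipop(self, leg: int, color: str) -> None:
        node = self._new_node(color)
        e = self._new_edge(("b", leg), node)
        self.order[("b", leg)].append(e)
        self.order[node].append(e)

    def _top_edge(self, leg: int) -> int:
        b = ("b", leg)
        if not self.order[b]:
            raise DiagramError(f"leg {leg} has no incident edge")
        return self.order[b][0]

    def _subdivide_top(self, leg: int, color: str) -> tuple:
        """Insert a new colored node on the edge at the boundary of ``leg``.
        Returns the node; its ccw order is left to the caller to extend with
        the bridge edge.  After insertion the node's order list is [up, down].
        """
        b = ("b", leg)
        e = self._top_edge(leg)
        lower = self.other_end(e, b)
        node = self._new_node(color)
        e_up = self._new_edge(b, node)
        e_down = self._new_edge(node, lower)
        self.order[b][self.order[b].index(e)] = e_up
        self.order[lower][self.order[lower].index(e)] = e_down
        del self.edges[e]
        self.order[node] = [e_up, e_down]
        return node

    def add_bridge(self, a: int, c: int) -> None:
        """BCFW bridge: white node on leg a, black node on leg c (a < c),
        inserted next to the boundary, joined by a horizontal edge."""
        if not (1 <= a < c <= self.n):
            raise DiagramError(f"bridge legs must satisfy 1 <= a < c <= n, got {(a, c)}")
        w = self._subdivide_top(a, WHITE)
        bk = self._subdivide_top(c, BLACK)
        e_bridge = self._new_edge(w, bk)
        # ccw orders by compass angle (boundary up, bridge toward the other leg):
        # white on leg a, bridge east:  [bridge(0), up(90), down(270)]
        up_w, down_w = self.order[w]
        self.order[w] = [e_bridge, up_w, down_w]
        # black on leg c, bridge west:  [up(90), bridge(180), down(270)]
        up_b, down_b = self.order[bk]
        self.order[bk] = [up_b, e_bridge, down_b]

    def insert_degree2(self, e: int, color: str = WHITE) -> tuple:
        """Subdivide edge ``e`` with a degree-2 node (a bipartite pass-through);
        trips are unaffected.  Used to exercise :func:`simplify`."""
        u, v = self.edges[e]
        node = self._new_node(color)
        e1 = self._new_edge(u, node)
        e2 = self._new_edge(node, v)
        self.order[u][self.order[u].index(e)] = e1
        self.order[v][self.order[v].index(e)] = e2
        del self.edges[e]
        self.order[node] = [e1, e2]
        return node

    # -- trips -------------------------------------------------------------
    def _step(self, e: int, node) -> int:
        """Edge the trip leaves by after entering ``node`` via edge ``e``."""
        edges = self.order[node]
        deg = len(edges)
        if deg == 1:
            return e  # lollipop: bounce
        if deg == 2:
            return edges[1 - edges.index(e)]  # pass straight through
        i = edges.index(e)
        if self.colors[node] == WHITE:
            return edges[(i - 1) % deg]  # next clockwise: turn left
        if self.colors[node] == BLACK:
            return edges[(i + 1) % deg]  # next counterclockwise: turn right
        raise DiagramError(f"trip re-entered boundary node {node}")

    def trip(self, leg: int) -> tuple[int, str | None]:
        """Walk the trip from boundary leg ``leg``.

        Returns (ending leg, color of the last degree-1 node bounced at, or
        None if the trip never bounced)."""
        start = ("b", leg)
        if not self.order[start]:
            raise DiagramError(f"leg {leg} is not attached")
        e = self.order[start][0]
        node = self.other_end(e, start)
        bounce = None
        for _ in range(4 * len(self.edges) + 4):
            if self.colors[node] == BOUNDARY:
                return node[1], bounce
            if self.degree(node) == 1:
                bounce = self.colors[node]
            e = self._step(e, node)
            node = self.other_end(e, node)
        raise DiagramError("trip did not reach the boundary (malformed diagram)")

    # -- export ------------------------------------------------------------
    def to_dot(self) -> str:
        lines = ["graph onshell {"]
        for node, color in self.colors.items():
            name = f'"{node[0]}{node[1]}"'
            if color == BOUNDARY:
                lines.append(f"  {name} [shape=plaintext label={node[1]}];")
            else:
                fill = "white" if color == WHITE else "black"
                lines.append(
                    f'  {name} [shape=circle style=filled fillcolor={fill} label=""];'
                )
        for u, v in self.edges.values():
            lines.append(f'  "{u[0]}{u[1]}" -- "{v[0]}{v[1]}";')
        lines.append("}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "nodes": [
                    {"id": list(node), "color": color}
                    for node, color in self.colors.items()
                ],
                "edges": [
                    {"id": e, "ends": [list(u), list(v)]}
                    for e, (u, v) in self.edges.items()
                ],
                "cyclic_order": [
                    {"node": list(node), "edges": edges}
                    for node, edges in self.order.items()
                ],
            }
        )


def build_diagram(
    transpositions: list[tuple[int, int]],
    residual: DecoratedPermutation,
) -> BridgeDiagram:
    """Assemble the reduced diagram for a bridge decomposition.

    Start from one lollipop per leg, colored by the residual identity
    decoration (white for b -> b, black for b -> b+n), then stack the bridges
    in reverse extraction order so the first-extracted bridge sits nearest
    the boundary.
    """
    if not residual.is_identity_decoration():
        raise DiagramError(f"residual {residual} is not a decoration of the identity")
    n = residual.n
    for a, c in transpositions:
        if not (1 <= a < c <= n):
            raise DiagramError(f"invalid transposition {(a, c)} for n={n}")
    d = BridgeDiagram.empty(n)
    for b in range(1, n + 1):
        d.add_lollipop(b, WHITE if residual(b) == b else BLACK)
    for a, c in reversed(transpositions):
        d.add_bridge(a, c)
    return d


def diagram_of(sigma: DecoratedPermutation) -> BridgeDiagram:
    """Reduced on-shell diagram of a decorated permutation."""
    chain, residual = decompose_with_residual(sigma)
    return build_diagram(chain, residual)


def read_permutation(d: BridgeDiagram) -> DecoratedPermutation:
    """Trip-read the decorated permutation off a diagram.

    For each leg i the trip ends at some leg e: sigma(i) = e if e > i, e + n
    if e < i; a trip returning to its own leg is decorated by the color of
    the lollipop it bounced at (white -> i, black -> i + n).
    """
    n = d.n
    images = []
    for i in range(1, n + 1):
        e, bounce = d.trip(i)
        if e > i:
            images.append(e)
        elif e < i:
            images.append(e + n)
        else:
            if bounce is None:
                raise DiagramError(
                    f"trip from leg {i} returned without touching a lollipop"
                )
            images.append(i if bounce == WHITE else i + n)
    return validate(images, n)


def simplify(d: BridgeDiagram) -> BridgeDiagram:
    """Remove all internal degree-2 nodes, merging their two edges.

    Trips pass straight through degree-2 nodes, so the trip permutation is
    unchanged.  Returns a new diagram; the input is not modified.
    """
    out = BridgeDiagram(n=d.n)
    out.colors = dict(d.colors)
    out.order = {k: list(v) for k, v in d.order.items()}
    out.edges = dict(d.edges)
    out._next_edge = d._next_edge
    out._next_node = d._next_node
    changed = True
    while changed:
        changed = False
        for node in list(out.colors):
            if out.colors[node] == BOUNDARY or out.degree(node) != 2:
                continue
            e1, e2 = out.order[node]
            if e1 == e2:
                continue  # degree-2 self-loop lollipop: leave alone
            u = out.other_end(e1, node)
            v = out.other_end(e2, node)
            merged = out._new_edge(u, v)
            out.order[u][out.order[u].index(e1)] = merged
            out.order[v][out.order[v].index(e2)] = merged
            del out.edges[e1], out.edges[e2]
            del out.order[node], out.colors[node]
            changed = True
            break
    return out
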