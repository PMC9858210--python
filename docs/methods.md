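# Methods

## Kernels and their analysis

A kernel is a labeled matrix with non-negative entries and unit row sums
(tolerance `tol_row = 1e-9`; rows within tolerance are renormalized exactly,
anything further off is rejected). Matrices of `fractions.Fraction` entries
are carried through every operation with exact rational arithmetic; float
matrices use numpy. The exact mode exists so that boundary statements — a
kernel *is* idempotent, a round trip *is* the identity — can be certified
rather than approximated.

Communicating classes are the strongly connected components of the support
digraph; entries at or below `tol_zero` (default exactly 0) are structural
zeros, and `tol_zero` is configurable because float renormalization can leave
dust in entries that are semantically zero. A class is recurrent iff no
support edge leaves it; its period is the gcd of `level(u)+1−level(v)` over
internal edges of any BFS levelling, the standard linear-time period
computation. Absorbing states are singleton recurrent classes with
self-probability 1 (within `tol_row`).

Extremal invariant measures are computed one per recurrent class, in class
order (classes sorted by smallest state label, for deterministic output), by
solving `μQ = μ, Σμ = 1` restricted to the class — least-squares on the
stacked system in float mode, Gauss–Jordan over rationals in exact mode.

The flow `P = lim Qᵐ` is assembled algebraically, never by iterating powers:
recurrent rows are their class's stationary vector; transient rows mix the
stationary vectors with absorption probabilities obtained from the
fundamental-matrix system `(I − Q_TT) B = Q_T→classes`. Iteration cannot
certify a limit and fails on stiff chains, while the algebraic form is exact
and manifestly idempotent. In `power` mode the limit is only returned when
every recurrent class is aperiodic; otherwise a report names the periodic
classes. The `cesaro` mode returns the same matrix unconditionally, since the
Cesàro average always converges to it.

On the two-state polytope with coordinates `x = Q(1,2)`, `y = Q(2,1)`, the
kernel derivative `Q² − Q` has off-diagonals `(x(1−x−y), y(1−x−y))`; the
idempotent set is exactly the origin plus the line `x+y = 1`, and every
interior kernel flows to that line. These identities are verified on grids
plus exact boundary points in the test suite.

## Agents

Agent construction validates the shape chain `W →P→ X →D→ G →A→ W`; the
qualia kernel is the composition `DAP`. Product combination uses Kronecker
products with lexicographic product labels, first factor major — the
convention fixes the block structure of `Q₁⊗Q₂` so tests are reproducible.
Union combination accepts any row-stochastic cross-term matrix over the
pooled qualia labels (the two-agent case is the `Q(x,y)` family).
`realize_agent` provides a constructive witness that every Markov kernel on
`X` is some agent's qualia kernel (`D = Q`, `A = P = I`); the round trip is
exact because no arithmetic touches `Q`'s entries.

## Decorated permutations

The map from chains uses a single window rule: transient `a ↦ a`; recurrent
`a ↦ min{ b > a : residue(b) ∈ [a] and the cyclic window {a,…,b} covers [a] }`,
with residues in `{1..n}` via `((v−1) mod n)+1` (1-based labels everywhere).
The rule's two degenerate readings — a literal "window contains the class"
clause would give `b = a+1` for absorbing states — are reconciled by the
residue condition, which forces `b = a+n` for absorbing singletons. The rule
is locked by the 9-state worked example (all nine images), its
transient-variant, and the two-state corner kernels.

A consequence worth noting: the rule sees only the communicating class as a
*set*, so chains whose classes agree but whose internal cycle orders differ
(e.g. the two 3-cycles) receive the same σ. Our census of the 27
deterministic vertices of M₃ accordingly finds **14** distinct decorated
permutations, and the census over all 343 support patterns of M₃ also yields
14 cells. Both counts are computed exhaustively and regression-locked in the
tests. (Treatments that distinguish cycle order would count more.)

The graph map mirrors the chain map via strongly connected components. Nodes
whose component has no internal edge, or whose component has edges leaving
it, are treated as transient (`σ(a) = a`); a node whose only link is a
self-loop maps to `a+n`. Extending the transient convention from singleton
components to *all* leaky components is a deliberate design choice: it makes
the graph map agree exactly with the chain map on every support digraph,
which the library treats as the defining property of the generalization.

The Grassmannian map repeats the n columns of a full-rank `k×n` matrix and
assigns to a non-zero column `a` the first `b > a` with `c_a` in the span of
columns `a+1..b` (zero columns map to themselves). Span membership is a rank
comparison with relative tolerance `1e-9`, exact over rationals for
Fraction matrices.

## Bridge decomposition and diagrams

The decomposition repeatedly extracts the lexicographically first pair
`(a, c)` with `a < c`, `σ(a) < σ(c)`, both endpoints non-fixed, and every
number strictly between a decorated fixed point, then swaps the images at
positions `a` and `c`. Requiring non-fixed endpoints is essential for
termination: with fixed endpoints admitted, `[1,3,5]` can be driven into a
state from which no admissible transposition exists. The swap-the-images
semantics is locked by the printed chain `(12)(23)(24)(12)(25)` for
`[3,5,4,6,7]`. A guard aborts after `n²` steps.

Diagrams are built in reverse: one lollipop per leg colored by the residual
identity decoration (white for `b↦b`, black for `b↦b+n`), then bridges are
stacked toward the boundary in reverse extraction order, each a white node on
the lower leg joined to a black node on the higher leg. The planar embedding
is combinatorial — each node stores its incident edges in counterclockwise
cyclic order — and trips implement turn-left-at-white / turn-right-at-black
as previous/next in that cyclic order, passing straight through degree-2
nodes and bouncing at lollipops. Diagram equality in tests is
trip-equivalence, not graph isomorphism, since diagrams are only meaningful
up to moves; the tie-break for bridges sharing a leg column is stacking
order, which trips are insensitive to. The exhaustive round trip
σ → bridges → diagram → trips → σ holds for every decorated permutation with
n ≤ 4 (88 cases), and the decomposition length matches a breadth-first
minimality oracle that may use *any* admissible transposition at each step.

## Polytope and fusion

Vertices of Mₙ are the 0/1 kernels in row-major function order; adjacency is
differ-in-exactly-one-row, the edge rule of a product of simplices, making
the vertex graph regular of degree `n(n−1)`. The cell census enumerates row
support patterns (each row a non-empty subset), since σ depends only on the
support; this replaces sampling a continuum with a finite exact enumeration.
Fusion points are parameterized by the invariant measure μ itself (for the
two-state fusion line `x+y=1` the stationary kernel's rows are `(1−x, x)`,
so the single line coordinate equals the weight of the *second* quale — the
measure convention avoids that ambiguity). `fuse` demands idempotence and
rank 1 within `1e-9` and reports which condition failed.

## Entropy

Profiles use `H(Xₙ|X₁) = Σ_a μ(a) H(rowₐ(Qⁿ⁻¹))` with `0·log 0 = 0`, base 2
by default. The start distribution must be stationary — that is the only
reading under which the marginal entropy is constant for every kernel — so an
explicit non-invariant start is rejected with an error, and when several
extremal measures exist the first is used with a logged warning.
Monotonicity and marginal constancy are theorems; `check_arrow` therefore
frames any violation beyond `1e-10` as an implementation bug.

## Synthetic fixtures

The fixture generator emulates three regimes of the polytope: flat-Dirichlet
rows (uniform over the interior — irreducible, aperiodic chains),
deterministic 0/1 kernels (the vertices), and support-pattern kernels
(uniformly chosen non-empty row supports with positive entries bounded away
from zero), which reach every boundary cell that Dirichlet draws never touch.
Identical specs are bit-for-bit reproducible. What these fixtures do not
model: near-degenerate kernels with entries at the edge of `tol_zero`, very
large state spaces, or any empirical transition data — passing tests
demonstrate correctness of the finite algebra and combinatorics, not
robustness to noisy estimated kernels.

Problem sizes used by the default test run: random-kernel properties at
n ∈ {2..7} with a few hundred draws, exhaustive diagram round trips at
n ≤ 4, cell censuses at n ≤ 3, entropy horizons ≤ 40. These sizes make every
stated check exhaustive or statistically redundant at desk scale.

## Known limitations

* Finite state spaces only; the measure-theoretic generality of kernels on
  σ-algebras is represented by finite label sets.
* No positroid geometry: Plücker coordinates, cell dimensions, amplitudes and
  differential forms are out of scope; σ labels are the only Grassmannian
  contact point.
* Diagram moves beyond degree-2 elimination (square moves, merge/expand) are
  not implemented; reduced-ness is by construction, not checked.
* The single-agent witness of `realize_agent` does not address whether a
  multi-agent network generates a given cross-term matrix.
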