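# markovagents

A library and CLI for the finite mathematics of kernel-defined "conscious
agents": row-stochastic matrix algebra, the combination and fusion of agents
on Markov polytopes, the projection of Markov chains (and directed graphs and
Grassmannian matrices) to decorated permutations, bridge decompositions into
bicolored on-shell (plabic) diagrams, and the conditional-entropy arrow of
time. It is aimed at researchers in mathematical consciousness science and at
anyone studying the combinatorics that connects Markov chains to cells of the
positive Grassmannian.

## The objects

An **agent** is a 6-tuple `(X, G, W, P, D, A)`: finite label sets of
experiences `X`, actions `G` and world states `W`, chained by Markovian
kernels `P: W→X` (perception), `D: X→G` (decision) and `A: G→W` (action).
Composing them gives the agent's **qualia kernel** `Q = DAP`, a Markov chain
on `X`. Two agents combine either as a product (cartesian labels, Kronecker
kernels, `Q = Q₁⊗Q₂`) or as a union with arbitrary Markovian cross terms; for
two 1-agents the latter is the family `Q(x,y) = [[1−x, x], [y, 1−y]]` on the
unit square `M₂`.

The set of all `n×n` row-stochastic matrices is the **Markov polytope**
`Mₙ`, a product of `n` simplices of dimension `n(n−1)` with `nⁿ`
deterministic vertices. The discrete kernel derivative `Q² − Q` defines a
flow on `Mₙ` whose sinks are the rank-1 idempotent kernels — the **fusion
simplex** `Fₙ`, an `(n−1)`-simplex of kernels with all rows equal to a single
invariant measure μ. Reaching it "fuses" the `n` qualia into one mixture
quale with weights μ.

Each kernel projects to a **decorated permutation**
`σ: {1..n} → {1..2n}`, `a ≤ σ(a) ≤ a+n`, bijective mod n: transient states
map to themselves, and a recurrent state `a` maps to the first `b > a` whose
mod-n residue lies in `a`'s communicating class and whose cyclic window
`{a,…,b}` covers that class (so absorbing states map to `a+n`). The same σ
labels the cells of `Mₙ` and, via a column-span rule, cells of the positive
Grassmannian. A σ decomposes into a minimal chain of adjacent transpositions
(BCFW bridges), which assemble into a reduced plabic diagram whose boundary
trips — turn left at white nodes, right at black — read σ back off.

Finally, a chain started from an invariant measure has constant marginal
entropy `H(Xₙ)`, yet the conditional entropies `H(Xₙ|X₁)` are non-decreasing
in n: an entropic arrow induced purely by conditioning.

## Worked example

```python
import numpy as np
import markovagents as ma

# deterministic 9-state chain with cycles (158), (2), (34), (6), (79)
m = np.zeros((9, 9))
for a, b in {1:5, 5:8, 8:1, 2:2, 3:4, 4:3, 6:6, 7:9, 9:7}.items():
    m[a-1, b-1] = 1.0
print(ma.from_markov(ma.validate_kernel(m)))
# [8,11,4,12,10,15,9,14,16]

# bridge decomposition of a decorated permutation
print(ma.decompose(ma.validate_sigma([3, 5, 4, 6, 7])))
# [(1, 2), (2, 3), (2, 4), (1, 2), (2, 5)]

# flow and fusion of a two-state kernel at (x, y) = (0.5, 0.25)
q = ma.m2_kernel(0.5, 0.25)
print(ma.flow(q).matrix[0])          # [0.33333333 0.66666667]
print(ma.fuse(ma.flow(q)).weights)   # (0.333..., 0.666...)

# entropic arrow of the lazy bit-flip chain
prof = ma.entropy_profile(ma.validate_kernel([[0.9, 0.1], [0.1, 0.9]]), horizon=5)
print([round(v, 4) for v in prof.values])
# [0.469, 0.6801, 0.8016, 0.8753]
```

The permutation `[8,11,4,12,10,15,9,14,16]` encodes the chain's five
communicating classes (values above 9 mark wrap-arounds; `σ(2)=11=2+9` says
state 2 is absorbing). The flow row `(1/3, 2/3)` is the invariant measure of
`Q(0.5, 0.25)`; since both rows agree, the kernel has fused, and `fuse`
returns the new quale's mixture weights. The entropy profile rises toward
`H(μ) = 1` bit: conditioning on `X₁` induces a forward direction even though
the marginal entropy stays constant.

The same operations are exposed as a CLI:

```
markovagents decorate --kernel chain9.json     # -> [8,11,4,12,10,15,9,14,16]
markovagents decompose --sigma "[3,5,4,6,7]"   # -> (12)(23)(24)(12)(25)
markovagents summary --n 3                     # -> {"dimension": 6, "vertices": 27}
markovagents cells --n 2                       # cell census of M2
markovagents diagram --sigma "[3,4,5,6]"       # DOT plabic diagram
```

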