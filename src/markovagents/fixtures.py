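"""Seeded kernel generators for tests and experiments.

Three families:

* ``dirichlet`` -- each row an independent draw from the flat Dirichlet on
  the simplex: a uniform sample of the Markov polytope interior.
* ``deterministic`` -- 0/1 kernels (polytope vertices); enumerated in
  row-major function order when the requested count covers all n^n, sampled
  without enumeration otherwise.
* ``support-pattern`` -- a uniformly chosen non-empty support per row, with
  uniform positive entries renormalized on it; reaches every cell of the
  polytope, including the boundary cells the Dirichlet family never touches.

Identical specs yield bit-identical kernels (numpy Generator seeded).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .kernels import Kernel

__all__ = ["FixtureSpec", "make_fixtures", "random_kernel"]

FAMILIES = ("dirichlet", "deterministic", "support-pattern")


@dataclass(frozen=True)
class FixtureSpec:
    n: int
    count: int
    seed: int
    family: str = "dirichlet"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown fixture family {self.family!r}; choose from {FAMILIES}"
            )
        if self.n < 1 or self.count < 0:
            raise ValueError("n must be >= 1 and count >= 0")


def _labels(n: int) -> tuple:
    return tuple(range(1, n + 1))


def random_kernel(n: int, rng: np.random.Generator, family: str = "dirichlet") -> Kernel:
    """One random kernel from the given family."""
    labels = _labels(n)
    if family == "dirichlet":
        m = rng.dirichlet(np.ones(n), size=n)
    elif family == "deterministic":
        m = np.zeros((n, n))
        for i, j in enumerate(rng.integers(0, n, size=n)):
            m[i, j] = 1.0
    elif family == "support-pattern":
        m = np.zeros((n, n))
        for i in range(n):
            size = int(rng.integers(1, n + 1))
            support = rng.choice(n, size=size, replace=False)
            vals = rng.uniform(0.1, 1.0, size=size)
            m[i, support] = vals / vals.sum()
    else:
        raise ValueError(f"unknown fixture family {family!r}")
    return Kernel(labels, labels, m)


def make_fixtures(spec: FixtureSpec) -> list[Kernel]:
    """Deterministic list of kernels for a spec (same spec -> same kernels)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.family == "deterministic" and spec.count >= n ** n:
        labels = _labels(n)
        out = []
        for f in itertools.product(range(n), repeat=n):
            m = np.zeros((n, n))
            for i, j in enumerate(f):
                m[i, j] = 1.0
            out.append(Kernel(labels, labels, m))
        return out[: spec.count] if spec.count < len(out) else out
    return [random_kernel(n, rng, spec.family) for _ in range(spec.count)]
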