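"""Minimal neutral Kingman coalescent, used for test-statistic null distributions.

The simulator draws a single-population genealogy (exponential waiting times
with rate k(k-1)/2 in coalescent time units) and places mutations on
branches either as a Poisson process with rate theta/2 per unit branch
length, or as a fixed number S distributed multinomially in proportion to
branch length (simulation conditional on the observed number of segregating
sites, as used for neutrality-test p-values).

Each mutation is recorded as the set of samples that inherit it, which is
all the downstream statistics need: pairwise differences, haplotype
identity, singleton counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoalescentSample", "simulate_coalescent"]


@dataclass
class CoalescentSample:
    n: int
    mutation_sets: list[frozenset[int]]  # samples carrying each mutation

    @property
    def s(self) -> int:
        return len(self.mutation_sets)

    @property
    def pi(self) -> float:
        """Mean pairwise differences."""
        n = self.n
        tot = sum(len(m) * (n - len(m)) for m in self.mutation_sets)
        return 2.0 * tot / (n * (n - 1))

    def haplotype_count(self) -> int:
        profiles = [set() for _ in range(self.n)]
        for k, m in enumerate(self.mutation_sets):
            for i in m:
                profiles[i].add(k)
        return len({frozenset(p) for p in profiles})

    def singletons_per_sample(self) -> np.ndarray:
        u = np.zeros(self.n, int)
        for m in self.mutation_sets:
            if len(m) == 1:
                u[next(iter(m))] += 1
            elif len(m) == self.n - 1:
                # the complementary sample carries the rare (ancestral) state
                (i,) = set(range(self.n)) - m
                u[i] += 1
        return u


def simulate_coalescent(
    n: int,
    rng: np.random.Generator,
    theta: float | None = None,
    s: int | None = None,
) -> CoalescentSample:
    """One neutral constant-size coalescent sample.

    Exactly one of ``theta`` (Poisson mutation rate, theta/2 per branch-length
    unit) or ``s`` (fixed segregating-site count) must be given.
    """
    if (theta is None) == (s is None):
        raise ValueError("give exactly one of theta or s")
    branches: list[frozenset[int]] = []
    lengths: list[float] = []
    # per-lineage accumulated branch length until it coalesces
    active = {i: frozenset([i]) for i in range(n)}
    acc = {i: 0.0 for i in range(n)}
    next_id = n
    while len(active) > 1:
        k = len(active)
        t = rng.exponential(2.0 / (k * (k - 1)))
        for key in acc:
            acc[key] += t
        a_key, b_key = rng.choice(list(active), size=2, replace=False)
        for key in (a_key, b_key):
            branches.append(active[key])
            lengths.append(acc[key])
        merged = active[a_key] | active[b_key]
        del active[a_key], acc[a_key]
        del active[b_key], acc[b_key]
        active[next_id] = merged
        acc[next_id] = 0.0
        next_id += 1

    lengths_arr = np.array(lengths)
    total = lengths_arr.sum()
    if s is None:
        n_mut = rng.poisson(theta / 2.0 * total)
    else:
        n_mut = s
    if n_mut == 0:
        return CoalescentSample(n, [])
    which = rng.choice(len(branches), size=n_mut, p=lengths_arr / total)
    return CoalescentSample(n, [branches[w] for w in which])
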