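"""Shared fixtures: genotype space, engine, and the brute-force mating oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import settings

from flypsd import RecursionEngine, enumerate_genotypes, gamete_distribution

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def space():
    return enumerate_genotypes()


@pytest.fixture(scope="session")
def engine(space):
    return RecursionEngine(space)


class MatingTableOracle:
    """Explicit 80-cross recursion, independent of the vectorised engine.

    Enumerates every female x male cross, every gamete pair within the
    cross, and accumulates offspring genotype probabilities scalar by
    scalar.  Deliberately loop-based so it shares no code path with
    :class:`flypsd.RecursionEngine`.
    """

    def __init__(self, space):
        self.space = space
        self.gametes = [gamete_distribution(g) for g in space.genotypes]
        self.index_by_counts = {tuple(c): i for i, c in enumerate(space.counts)}

    def step(self, freqs, w_f, w_m):
        f_w = [freqs[i] * w_f[i] for i in range(10)]
        m_w = [freqs[10 + j] * w_m[j] for j in range(8)]
        sf, sm = sum(f_w), sum(m_w)
        if sf <= 0 or sm <= 0:
            raise RuntimeError("extinct")
        f_w = [w / sf for w in f_w]
        m_w = [w / sm for w in m_w]
        nxt = np.zeros(18)
        for i in range(10):
            for j in range(8):
                cw = f_w[i] * m_w[j]
                if cw == 0.0:
                    continue
                eggs, sperm = self.gametes[i], self.gametes[10 + j]
                for e, s in itertools.product(range(8), range(8)):
                    p = eggs[e] * sperm[s]
                    if p == 0.0:
                        continue
                    counts = (
                        ((e >> 2) & 1) + ((s >> 2) & 1),
                        ((e >> 1) & 1) + ((s >> 1) & 1),
                        (e & 1) + (s & 1),
                    )
                    nxt[self.index_by_counts[counts]] += cw * p
        return nxt / nxt.sum()

    def chromosome_frequencies(self, freqs):
        out = np.zeros(3)
        for g, f in zip(self.space.genotypes, freqs):
            for k in range(3):
                out[k] += f * g.counts[k] / 2.0
        return out


@pytest.fixture(scope="session")
def oracle(space):
    return MatingTableOracle(space)


def random_state_and_fitness(rng):
    """A random interior population state plus a random positive fitness array."""
    freqs = rng.dirichlet(np.ones(18))
    w_f = rng.uniform(0.05, 2.0, 10)
    w_m = rng.uniform(0.05, 2.0, 8)
    return freqs, w_f, w_m
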