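"""Wright-Fisher finite-population simulation over the 18-genotype space.

Sampling is applied at the zygote stage: each generation the deterministic
two-sex recursion gives the expected zygote distribution from the realised
genotype frequencies, and the next generation's N individuals are one
multinomial draw from it.  Selection is therefore embedded in the expected
distribution and drift enters only through the multinomial sample.  With
all fitness values equal the model reduces to pure genetic drift, which
serves as the no-selection control.

A derived chromosome is fixed when its copy count equals its pool total
(2N per pair) and lost at zero copies; without mutation both states are
absorbing.  Fixation probabilities are estimated as the fraction of
replicates ending absorbed; Pfix of a derived chromosome equals Ploss of
its standard homolog and vice versa.  Replicates in which one sex runs out
of viable parents are flagged extinct and excluded from the denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .deterministic import PopulationState, RecursionEngine, default_engine
from .fitness import FitnessArray
from .genotypes import DERIVED_ALLELES, N_GENOTYPES, STANDARD_ALLELES

#: copies of each chromosome pair carried by one diploid individual
COPIES_PER_INDIVIDUAL = 2


class ReplicateExtinct(RuntimeError):
    """No viable female or male parents remain in a finite replicate."""


def wright_fisher_step(
    counts: np.ndarray,
    fitness: FitnessArray,
    N: int,
    rng: np.random.Generator,
    engine: RecursionEngine | None = None,
) -> np.ndarray:
    """One Wright-Fisher generation: expectation by recursion, then sampling.

    ``counts`` are integer genotype counts summing to ``N``.  Raises
    :class:`ReplicateExtinct` when one sex has zero total parental weight.
    """
    engine = engine or default_engine()
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total != N:
        raise ValueError(f"counts sum to {total}, expected N={N}")
    freqs = counts / N
    expected, extinct = engine.step_batch(
        freqs[None, :], fitness.w_f[None, :], fitness.w_m[None, :]
    )
    if extinct[0]:
        raise ReplicateExtinct("no viable parents of one sex")
    return rng.multinomial(N, expected[0])


@dataclass
class FiniteRunSummary:
    """Fixation/loss probabilities over replicate Wright-Fisher runs."""

    pfix: dict[str, float]
    ploss: dict[str, float]
    replicates: int
    n_extinct: int
    N: int
    generations: int
    seed: object
    #: final genotype counts, (replicates, 18); extinct rows hold the last
    #: pre-extinction counts
    final_counts: np.ndarray = field(repr=False)
    extinct_mask: np.ndarray = field(repr=False)

    @property
    def n_evaluated(self) -> int:
        return self.replicates - self.n_extinct


def run_finite(
    fitness: FitnessArray,
    state0: PopulationState,
    N: int = 10_000,
    generations: int = 1000,
    replicates: int = 100,
    seed=None,
    exact_init: bool = False,
    engine: RecursionEngine | None = None,
) -> FiniteRunSummary:
    """Replicate Wright-Fisher runs from a common starting distribution.

    Each replicate draws an independent substream from ``seed`` (results do
    not depend on execution order) and is initialised by a multinomial draw
    of N individuals from ``state0`` -- or by largest-remainder rounding of
    the expected counts with ``exact_init=True``.
    """
    if N < 1 or generations < 1 or replicates < 1:
        raise ValueError("N, generations and replicates must be positive")
    engine = engine or default_engine()
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(child) for child in ss.spawn(replicates)]

    copies = engine.space.counts  # (18, 3) derived copies per genotype
    pool = COPIES_PER_INDIVIDUAL * N

    final_counts = np.zeros((replicates, N_GENOTYPES), dtype=np.int64)
    extinct_mask = np.zeros(replicates, dtype=bool)
    for r, rng in enumerate(streams):
        if exact_init:
            counts = _round_to_counts(state0.freqs, N)
        else:
            counts = rng.multinomial(N, state0.freqs)
        for _ in range(generations):
            try:
                counts = wright_fisher_step(counts, fitness, N, rng, engine)
            except ReplicateExtinct:
                extinct_mask[r] = True
                break
        final_counts[r] = counts

    ok = ~extinct_mask
    n_ok = int(ok.sum())
    derived_copies = final_counts[ok] @ copies  # (n_ok, 3)
    pfix: dict[str, float] = {}
    ploss: dict[str, float] = {}
    for j, (derived, standard) in enumerate(zip(DERIVED_ALLELES, STANDARD_ALLELES)):
        fixed = (derived_copies[:, j] == pool).mean() if n_ok else np.nan
        lost = (derived_copies[:, j] == 0).mean() if n_ok else np.nan
        pfix[derived] = float(fixed)
        ploss[derived] = float(lost)
        # the standard homolog mirrors the derived allele
        pfix[standard] = float(lost)
        ploss[standard] = float(fixed)
    return FiniteRunSummary(
        pfix=pfix,
        ploss=ploss,
        replicates=replicates,
        n_extinct=int(extinct_mask.sum()),
        N=N,
        generations=generations,
        seed=seed,
        final_counts=final_counts,
        extinct_mask=extinct_mask,
    )


def _round_to_counts(freqs: np.ndarray, N: int) -> np.ndarray:
    """Largest-remainder rounding of expected counts N * freqs."""
    raw = freqs * N
    base = np.floor(raw).astype(np.int64)
    short = N - int(base.sum())
    if short:
        order = np.argsort(raw - base)[::-1]
        base[order[:short]] += 1
    return base


@dataclass(frozen=True)
class DriftComparisonEntry:
    """Fisher's exact comparison of fixation counts, selection vs. drift."""

    k_selection: int
    n_selection: int
    k_drift: int
    n_drift: int
    p_value: float
    direction: str  # "deficiency", "excess", or "none"


def fisher_exact_compare(
    k_sel: int, n_sel: int, k_drift: int, n_drift: int
) -> DriftComparisonEntry:
    """Two-sided Fisher's exact test on a 2x2 fixation-count table.

    The p-value is the sum of hypergeometric probabilities no larger than
    the observed table's (minimum-likelihood method).  ``direction`` is
    derived from the raw proportions, not from the test: a deficiency means
    fewer fixations with selection than under drift alone.
    """
    for k, n in ((k_sel, n_sel), (k_drift, n_drift)):
        if n <= 0:
            raise ValueError("cannot compare fixation counts with n = 0")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    table = [[k_sel, n_sel - k_sel], [k_drift, n_drift - k_drift]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if k_sel * n_drift < k_drift * n_sel:
        direction = "deficiency"
    elif k_sel * n_drift > k_drift * n_sel:
        direction = "excess"
    else:
        direction = "none"
    return DriftComparisonEntry(k_sel, n_sel, k_drift, n_drift, min(p, 1.0), direction)
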