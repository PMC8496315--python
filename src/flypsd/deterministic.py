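"""Infinite-population two-sex genotype-frequency recursion.

One generation applies, in order:

1. selection as parental weights within each sex
   (``weight(g) = freq(g) * w(g)``, normalised among females and among
   males separately),
2. fitness-weighted gamete pooling (egg pool from females, sperm pool from
   males, via Mendelian segregation with independent assortment),
3. random union of gametes (random mating), and
4. epistatic sex determination of the resulting zygotes.

The zygote sex ratio is an emergent property of the model, and chromosome
frequencies are computed over zygotes weighted by the realised sex ratio.
Loss and fixation of a derived chromosome are threshold events (frequency
below 0.1% or above 99.9% of that pair's chromosome pool): a deterministic
recursion cannot reach exactly 0 or 1 in finite time.

The batch interface runs many fitness arrays side by side through the same
update; batch and one-at-a-time execution produce identical trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fitness import FitnessArray
from .genotypes import (
    DERIVED_ALLELES,
    GenotypeSpace,
    N_FEMALE,
    N_GAMETES,
    N_GENOTYPES,
    enumerate_genotypes,
    gamete_distribution,
)

logger = logging.getLogger(__name__)

LOSS_THRESHOLD = 0.001
FIXATION_THRESHOLD = 0.999
#: frequencies below this are flushed to zero to avoid denormal slowdown
FLUSH_LIMIT = 1e-300
#: per-generation change in derived-allele frequencies below which a
#: trajectory is treated as converged (early exit)
CONVERGENCE_TOL = 1e-14

LOST, POLYMORPHIC, FIXED = -1, 0, 1
OUTCOME_NAMES = {LOST: "lost", POLYMORPHIC: "polymorphic", FIXED: "fixed"}


class ExtinctionError(RuntimeError):
    """One sex has no viable parents (total parental weight zero)."""

    def __init__(self, message: str, generation: int | None = None):
        super().__init__(message)
        self.generation = generation


@dataclass
class PopulationState:
    """Zygote genotype-frequency distribution in canonical (f1..m8) order."""

    freqs: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (N_GENOTYPES,):
            raise ValueError(f"expected {N_GENOTYPES} frequencies")
        if (self.freqs < 0).any():
            raise ValueError("negative genotype frequency")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {self.freqs.sum()}, not 1")

    @classmethod
    def from_dict(cls, freqs: dict[str, float], space: GenotypeSpace | None = None,
                  generation: int = 0) -> "PopulationState":
        space = space or enumerate_genotypes()
        vec = np.zeros(N_GENOTYPES)
        for label, f in freqs.items():
            vec[space.index[label]] = f
        return cls(vec, generation)

    @property
    def female_share(self) -> float:
        return float(self.freqs[:N_FEMALE].sum())


@dataclass
class TrajectoryResult:
    """Endpoint and classification of one deterministic run."""

    final_state: PopulationState
    final_frequencies: dict[str, float]
    outcomes: dict[str, str]
    psd_maintained: bool
    generations_run: int
    converged: bool
    trajectory: np.ndarray | None = None  # (n_samples, 3) thinned chromosome freqs


@dataclass
class BatchResult:
    """Endpoints of a batch of deterministic runs (one fitness array per row)."""

    final_freqs: np.ndarray       # (B, 18)
    chromosome_freqs: np.ndarray  # (B, 3) in DERIVED_ALLELES order
    outcomes: np.ndarray          # (B, 3) in {LOST, POLYMORPHIC, FIXED}
    psd_maintained: np.ndarray    # (B,) bool
    generations_run: np.ndarray   # (B,)
    converged: np.ndarray         # (B,) bool
    extinct: np.ndarray           # (B,) bool


def classify(freq: float, thresholds=(LOSS_THRESHOLD, FIXATION_THRESHOLD)) -> int:
    lo, hi = thresholds
    if freq < lo:
        return LOST
    if freq > hi:
        return FIXED
    return POLYMORPHIC


class RecursionEngine:
    """Vectorised generation-update operator over the 18-genotype space."""

    def __init__(self, space: GenotypeSpace | None = None):
        self.space = space or enumerate_genotypes()
        space = self.space
        self.egg_gametes = np.array(
            [gamete_distribution(g) for g in space.females]
        )  # (10, 8)
        # males never carry IV^F, so only the 4 IV-bearing gametes can occur
        # in the sperm pool; dropping the impossible columns halves the work
        # and makes every egg x sperm combination reachable.
        self._sperm_cols = np.array([g for g in range(N_GAMETES) if not (g & 1)])
        self.sperm_gametes = np.array(
            [gamete_distribution(g) for g in space.males]
        )[:, self._sperm_cols]  # (8, 4)
        # cross[e * 4 + s, g] = 1 if egg gamete e + sperm gamete s -> genotype g
        index_by_counts = {tuple(c): i for i, c in enumerate(space.counts)}
        n_sperm = len(self._sperm_cols)
        cross = np.zeros((N_GAMETES * n_sperm, N_GENOTYPES))
        for e in range(N_GAMETES):
            ec = ((e >> 2) & 1, (e >> 1) & 1, e & 1)
            for si, s in enumerate(self._sperm_cols):
                sc = ((s >> 2) & 1, (s >> 1) & 1, s & 1)
                counts = (ec[0] + sc[0], ec[1] + sc[1], ec[2] + sc[2])
                cross[e * n_sperm + si, index_by_counts[counts]] = 1.0
        self.cross = cross
        # copy share: derived copies per genotype / 2 (per-pair pool is two
        # copies per individual)
        self.copy_share = space.counts.astype(float) / 2.0  # (18, 3)

    # ------------------------------------------------------------------ core
    def step_batch(
        self, freqs: np.ndarray, w_f: np.ndarray, w_m: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance a batch of populations one generation.

        Returns ``(next_freqs, extinct)``; rows flagged extinct (a sex with
        zero total parental weight) are passed through unchanged.
        """
        wf = freqs[:, :N_FEMALE] * w_f
        wm = freqs[:, N_FEMALE:] * w_m
        sf = wf.sum(axis=1, keepdims=True)
        sm = wm.sum(axis=1, keepdims=True)
        extinct = (sf[:, 0] <= 0.0) | (sm[:, 0] <= 0.0)
        if extinct.any():
            sf = np.where(sf > 0.0, sf, 1.0)
            sm = np.where(sm > 0.0, sm, 1.0)
        # einsum contractions (not BLAS) keep every output row's summation
        # order fixed, so batch results are bitwise independent of batch size
        eggs = np.einsum("bf,fg->bg", wf / sf, self.egg_gametes)
        sperm = np.einsum("bm,mg->bg", wm / sm, self.sperm_gametes)
        outer = eggs[:, :, None] * sperm[:, None, :]
        nxt = np.einsum(
            "bk,kg->bg",
            outer.reshape(freqs.shape[0], -1),
            self.cross,
        )
        # guard against slow denormals on long horizons, then renormalise
        tiny = (nxt != 0.0) & (nxt < FLUSH_LIMIT)
        if tiny.any():
            logger.debug("flushed %d subnormal frequencies to zero", tiny.sum())
            nxt[tiny] = 0.0
        rowsum = nxt.sum(axis=1, keepdims=True)
        nxt /= np.where(rowsum > 0.0, rowsum, 1.0)
        if extinct.any():
            nxt[extinct] = freqs[extinct]
        return nxt, extinct

    def next_generation(
        self, state: PopulationState, fitness: FitnessArray
    ) -> PopulationState:
        """Single-population convenience wrapper around :meth:`step_batch`."""
        nxt, extinct = self.step_batch(
            state.freqs[None, :], fitness.w_f[None, :], fitness.w_m[None, :]
        )
        if extinct[0]:
            raise ExtinctionError(
                "no viable parents of one sex", generation=state.generation
            )
        return PopulationState(nxt[0], state.generation + 1)

    # ------------------------------------------------------------- summaries
    def chromosome_frequencies(self, freqs: np.ndarray) -> np.ndarray:
        """Derived-allele share of each chromosome pool among zygotes.

        ``freq[d] = sum_g p_g * count_d(g) / 2`` -- the per-pair pool is two
        copies per individual, weighted by the realised zygote sex ratio.
        Accepts a single state vector or a batch.
        """
        return np.einsum(
            "...g,gc->...c", np.asarray(freqs, dtype=float), self.copy_share
        )

    def chromosome_frequencies_dict(self, state: PopulationState) -> dict[str, float]:
        cf = self.chromosome_frequencies(state.freqs)
        return dict(zip(DERIVED_ALLELES, map(float, cf)))

    # ------------------------------------------------------------------ runs
    def run_batch(
        self,
        freqs0: np.ndarray,
        w_f: np.ndarray,
        w_m: np.ndarray,
        generations: int,
        thresholds=(LOSS_THRESHOLD, FIXATION_THRESHOLD),
        early_exit: bool = False,
        convergence_tol: float = CONVERGENCE_TOL,
    ) -> BatchResult:
        """Iterate the recursion for a batch of fitness arrays.

        With ``early_exit`` a row stops once its three derived-allele
        frequencies change by less than ``convergence_tol`` in one
        generation; classifications are unchanged relative to running the
        full horizon because the remaining drift is bounded by
        ``generations * convergence_tol``.
        """
        if generations < 1:
            raise ValueError("generations must be >= 1")
        w_f = np.atleast_2d(np.asarray(w_f, dtype=float))
        w_m = np.atleast_2d(np.asarray(w_m, dtype=float))
        B = w_f.shape[0]
        freqs0 = np.asarray(freqs0, dtype=float)
        if freqs0.ndim == 1:
            freqs0 = np.broadcast_to(freqs0, (B, N_GENOTYPES))
        cur = np.array(freqs0, dtype=float)

        final = np.array(cur)
        gens_run = np.full(B, generations, dtype=np.int64)
        converged = np.zeros(B, dtype=bool)
        extinct_all = np.zeros(B, dtype=bool)
        active = np.arange(B)
        cf_prev = self.chromosome_frequencies(cur)
        wfa, wma = w_f, w_m

        for t in range(1, generations + 1):
            nxt, ext = self.step_batch(cur, wfa, wma)
            cf = self.chromosome_frequencies(nxt)
            done = ext.copy()
            if early_exit:
                done |= np.abs(cf - cf_prev).max(axis=1) < convergence_tol
            if done.any():
                idx = active[done]
                final[idx] = nxt[done]
                gens_run[idx] = t
                extinct_all[idx] = ext[done]
                converged[idx] = ~ext[done]
                keep = ~done
                active = active[keep]
                cur = nxt[keep]
                wfa = wfa[keep]
                wma = wma[keep]
                cf_prev = cf[keep]
                if active.size == 0:
                    break
            else:
                cur = nxt
                cf_prev = cf
        if active.size:
            final[active] = cur

        cf_final = self.chromosome_frequencies(final)
        lo, hi = thresholds
        outcomes = np.where(
            cf_final < lo, LOST, np.where(cf_final > hi, FIXED, POLYMORPHIC)
        ).astype(np.int8)
        maintained = (outcomes == POLYMORPHIC).all(axis=1) & ~extinct_all
        return BatchResult(
            final_freqs=final,
            chromosome_freqs=cf_final,
            outcomes=outcomes,
            psd_maintained=maintained,
            generations_run=gens_run,
            converged=converged,
            extinct=extinct_all,
        )

    def run(
        self,
        state0: PopulationState,
        fitness: FitnessArray,
        generations: int,
        thresholds=(LOSS_THRESHOLD, FIXATION_THRESHOLD),
        early_exit: bool = False,
        record_every: int | None = None,
    ) -> TrajectoryResult:
        """Run one fitness array and classify the outcome per chromosome.

        ``record_every`` optionally samples the chromosome-frequency
        trajectory every that many generations (thinned, starting at
        generation 0).
        """
        if generations < 1:
            raise ValueError("generations must be >= 1")
        cur = state0.freqs[None, :].copy()
        wf = fitness.w_f[None, :]
        wm = fitness.w_m[None, :]
        cf_prev = self.chromosome_frequencies(cur)[0]
        samples = [cf_prev] if record_every else None
        converged = False
        t = 0
        for t in range(1, generations + 1):
            nxt, ext = self.step_batch(cur, wf, wm)
            if ext[0]:
                raise ExtinctionError(
                    "no viable parents of one sex", generation=state0.generation + t
                )
            cur = nxt
            cf = self.chromosome_frequencies(cur)[0]
            if record_every and t % record_every == 0:
                samples.append(cf)
            if early_exit and np.abs(cf - cf_prev).max() < CONVERGENCE_TOL:
                converged = True
                break
            cf_prev = cf
        final_state = PopulationState(cur[0], state0.generation + t)
        cf_final = self.chromosome_frequencies(cur)[0]
        outcomes = {
            chrom: OUTCOME_NAMES[classify(float(f), thresholds)]
            for chrom, f in zip(DERIVED_ALLELES, cf_final)
        }
        return TrajectoryResult(
            final_state=final_state,
            final_frequencies=dict(zip(DERIVED_ALLELES, map(float, cf_final))),
            outcomes=outcomes,
            psd_maintained=all(v == "polymorphic" for v in outcomes.values()),
            generations_run=t,
            converged=converged,
            trajectory=np.array(samples) if samples is not None else None,
        )


# module-level convenience wrappers -----------------------------------------

_DEFAULT_ENGINE: RecursionEngine | None = None


def default_engine() -> RecursionEngine:
    global _DEFAULT_ENGINE
    if _DEFAULT_ENGINE is None:
        _DEFAULT_ENGINE = RecursionEngine()
    return _DEFAULT_ENGINE


def next_generation(state: PopulationState, fitness: FitnessArray) -> PopulationState:
    return default_engine().next_generation(state, fitness)


def chromosome_frequencies(state: PopulationState) -> dict[str, float]:
    return default_engine().chromosome_frequencies_dict(state)


def run_deterministic(
    state0: PopulationState,
    fitness: FitnessArray,
    generations: int,
    thresholds=(LOSS_THRESHOLD, FIXATION_THRESHOLD),
    **kwargs,
) -> TrajectoryResult:
    return default_engine().run(state0, fitness, generations, thresholds, **kwargs)
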