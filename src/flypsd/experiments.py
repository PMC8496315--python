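"""Experiment plans, starting-state fixtures, and the screening pipeline.

A screen draws n selection-coefficient sets from Uniform(-1, 1), builds the
fitness arrays for one dominance scheme, iterates the deterministic
recursion for 1000 generations from a chosen starting state, and records
final chromosome frequencies, maintenance status and the intersexual
fitness correlation for every array.  Long-run reclassification continues
PSD-maintaining arrays to a one-million-generation horizon to separate
stable polymorphisms from slow paths to proto-Y fixation.  A finite-
population block and top-k rejection fitting follow the same plan.

Default sizes are scaled down from the published screens (which used one
million arrays per scheme and starting state) to 10,000 arrays per scheme;
binomial sampling error at that size is about half a percentage point on
the maintenance fractions.

Randomness: a master seed spawns named substreams per (stage, scheme), so
enlarging one stage never perturbs the draws of another, and extending the
number of arrays extends the coefficient draw without changing earlier
rows.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .deterministic import (
    BatchResult,
    PopulationState,
    RecursionEngine,
    default_engine,
)
from .fitness import SCHEMES, build_fitness_arrays, sample_selection_coefficients
from .fitting import (
    FitResult,
    ObservedFrequencies,
    rho_mf_batch,
    select_best_fitting,
)
from .genotypes import DERIVED_ALLELES, N_GENOTYPES

logger = logging.getLogger(__name__)

#: stage keys for named seed substreams
_STAGE_KEYS = {"screen": 1, "null": 2, "finite": 3, "finite_drift": 4}


@dataclass
class ExperimentPlan:
    """Sizes, horizons and seed for one reproduction of the pipeline."""

    schemes: tuple[str, ...] = SCHEMES
    n_arrays: int = 10_000
    start: str = "equal"          # "equal" or a label resolvable by start_state()
    generations: int = 1000
    long_generations: int = 1_000_000
    n_longrun: int = 200          # PSD-maintaining arrays continued per scheme
    finite_N: int = 10_000
    finite_generations: int = 1000
    finite_replicates: int = 100
    fit_k: int = 1000
    populations: tuple[str, ...] = ("CA", "NC", "NY")
    seed: int = 0

    def __post_init__(self):
        for name in ("n_arrays", "generations", "long_generations", "n_longrun",
                     "finite_N", "finite_generations", "finite_replicates", "fit_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}")

    def substream(self, stage: str, scheme: str) -> np.random.Generator:
        key = (self.seed, _STAGE_KEYS[stage], SCHEMES.index(scheme))
        return np.random.default_rng(np.random.SeedSequence(key))

    def to_dict(self) -> dict:
        return asdict(self)


# ------------------------------------------------------------ start states
def equal_start() -> PopulationState:
    """All 18 genotypes at frequency 1/18 (female share 10/18)."""
    return PopulationState(np.full(N_GENOTYPES, 1.0 / N_GENOTYPES))


def monogenic_zw_start() -> PopulationState:
    """Both proto-Ys fixed, IV^F segregating: 50% f10 and 50% m8 zygotes.

    This is the monogenic ZW configuration; under neutral fitness it is an
    exact fixed point of the recursion with IV^F at 25% of fourth
    chromosomes.
    """
    return PopulationState.from_dict({"f10": 0.5, "m8": 0.5})


_START_STATES = {"equal": equal_start, "monogenic_zw": monogenic_zw_start}


def start_state(label: str) -> PopulationState:
    try:
        return _START_STATES[label]()
    except KeyError:
        raise ValueError(
            f"unknown start state {label!r}; known: {sorted(_START_STATES)}"
        ) from None


# ------------------------------------------------------------------ screen
@dataclass
class ScreenResult:
    """Everything the downstream stages need about one scheme's screen."""

    scheme: str
    plan: ExperimentPlan
    coefficients: np.ndarray  # (n, 2, 3)
    w_f: np.ndarray           # (n, 10)
    w_m: np.ndarray           # (n, 8)
    batch: BatchResult
    table: pd.DataFrame
    maintenance_fraction: float


def run_screen(
    plan: ExperimentPlan,
    scheme: str,
    engine: RecursionEngine | None = None,
    neutral_override: bool = False,
) -> ScreenResult:
    """Screen ``plan.n_arrays`` random fitness arrays for one scheme.

    ``neutral_override`` forces all selection coefficients to zero (every
    array neutral) -- useful as a self-check, since neutrality preserves
    every interior starting frequency.
    """
    engine = engine or default_engine()
    t0 = time.perf_counter()
    rng = plan.substream("screen", scheme)
    coeffs = sample_selection_coefficients(rng, size=plan.n_arrays)
    if neutral_override:
        coeffs = np.zeros_like(coeffs)
    w_f, w_m = build_fitness_arrays(coeffs, scheme, engine.space)
    state0 = start_state(plan.start)
    batch = engine.run_batch(state0.freqs, w_f, w_m, plan.generations)
    rho = rho_mf_batch(w_f, w_m, engine.space)

    table = pd.DataFrame(
        {
            "array_id": np.arange(plan.n_arrays),
            "scheme": scheme,
            **{
                f"s_{sex}_{chrom}": coeffs[:, i, j]
                for i, sex in enumerate(("f", "m"))
                for j, chrom in enumerate(("YM", "IIIM", "IVF"))
            },
            **{
                f"freq_{chrom}": batch.chromosome_freqs[:, j]
                for j, chrom in enumerate(DERIVED_ALLELES)
            },
            "psd_maintained": batch.psd_maintained,
            "extinct": batch.extinct,
            "rho_mf": rho,
        }
    )
    frac = float(batch.psd_maintained.mean())
    logger.info(
        "screen scheme=%s arrays=%d generations=%d maintained=%.4f "
        "extinct=%d elapsed=%.1fs",
        scheme, plan.n_arrays, plan.generations, frac,
        int(batch.extinct.sum()), time.perf_counter() - t0,
    )
    return ScreenResult(
        scheme=scheme,
        plan=plan,
        coefficients=coeffs,
        w_f=w_f,
        w_m=w_m,
        batch=batch,
        table=table,
        maintenance_fraction=frac,
    )


# ----------------------------------------------------------------- longrun
def run_longrun(
    screen: ScreenResult,
    n_arrays: int | None = None,
    generations: int | None = None,
    early_exit: bool = True,
    engine: RecursionEngine | None = None,
) -> pd.DataFrame:
    """Continue PSD-maintaining arrays to the long horizon and reclassify.

    Returns one row per continued array with its long-run chromosome
    frequencies, whether a proto-Y (Y^M or III^M) crossed the 99.9%
    fixation threshold, and early-exit bookkeeping.  The continued arrays
    are the first ``n_arrays`` maintaining arrays by array id (the screen's
    draws are exchangeable, so any deterministic subset is unbiased).
    """
    engine = engine or default_engine()
    plan = screen.plan
    n_arrays = n_arrays or plan.n_longrun
    generations = generations or plan.long_generations
    ids = np.flatnonzero(screen.batch.psd_maintained)[:n_arrays]
    if ids.size == 0:
        raise ValueError(f"no PSD-maintaining arrays in {screen.scheme} screen")
    t0 = time.perf_counter()
    state0 = start_state(plan.start)
    batch = engine.run_batch(
        state0.freqs,
        screen.w_f[ids],
        screen.w_m[ids],
        generations,
        early_exit=early_exit,
    )
    proto_y_fixed = (batch.outcomes[:, :2] == 1).any(axis=1)
    out = pd.DataFrame(
        {
            "array_id": ids,
            "scheme": screen.scheme,
            **{
                f"freq_{chrom}": batch.chromosome_freqs[:, j]
                for j, chrom in enumerate(DERIVED_ALLELES)
            },
            "psd_maintained": batch.psd_maintained,
            "proto_y_fixed": proto_y_fixed,
            "generations_run": batch.generations_run,
            "converged": batch.converged,
            "extinct": batch.extinct,
        }
    )
    logger.info(
        "longrun scheme=%s arrays=%d horizon=%d proto_y_fixed=%.4f elapsed=%.1fs",
        screen.scheme, ids.size, generations,
        float(proto_y_fixed.mean()), time.perf_counter() - t0,
    )
    return out


# --------------------------------------------------------------------- fit
def run_fit(
    screen: ScreenResult,
    observed: dict[str, ObservedFrequencies] | None = None,
) -> dict[str, FitResult]:
    """Top-k rejection fit of the screen against each observed population."""
    plan = screen.plan
    if observed is None:
        observed = {
            pop: ObservedFrequencies.placeholder(pop) for pop in plan.populations
        }
    fits = {}
    for pop, obs in observed.items():
        fits[pop] = select_best_fitting(
            np.arange(plan.n_arrays),
            screen.batch.chromosome_freqs,
            screen.batch.psd_maintained,
            obs,
            k=plan.fit_k,
        )
    return fits
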