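"""Rejection fitting to observed chromosome frequencies and antagonism summaries.

The fitting step is plain top-k rejection (an approximate Bayesian
computation without kernels or tolerances): among fitness arrays that keep
all three proto-sex chromosomes polymorphic, rank by the mean squared error
between simulated and observed chromosome frequencies and keep the k best.

The sexual-antagonism summaries are:

* ``rho_mf`` -- Spearman's rank correlation of fitness between the eight
  male genotypes and their partner female genotypes (the female that
  differs only by one IV^F copy); a negative value is the hallmark of
  sexually antagonistic multi-chromosome genotypes,
* the per-(sex, chromosome) distributions of selection coefficients over a
  set of arrays, and
* the rank correlation between the female benefit of IV^F and its
  equilibrium frequency.

Observed CA/NC/NY frequencies ship as synthetic placeholders consistent
with the published ranges (III^M below 3% of third chromosomes, IV^F at
2-9% of fourth chromosomes); real tables can be supplied as YAML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import stats

from .genotypes import DERIVED_ALLELES, GenotypeSpace, enumerate_genotypes

logger = logging.getLogger(__name__)

#: synthetic placeholder fixtures: frequencies inside the published ranges,
#: NOT the exact values observed in the three North American populations
OBSERVED_PLACEHOLDERS = {
    "CA": {"YM": 0.30, "IIIM": 0.020, "IVF": 0.050},
    "NC": {"YM": 0.25, "IIIM": 0.015, "IVF": 0.030},
    "NY": {"YM": 0.20, "IIIM": 0.010, "IVF": 0.070},
}


@dataclass(frozen=True)
class ObservedFrequencies:
    """Observed derived-chromosome frequencies for one population."""

    population: str
    ym: float
    iiim: float
    ivf: float

    def __post_init__(self):
        for f in (self.ym, self.iiim, self.ivf):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"observed frequency {f} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.ym, self.iiim, self.ivf])

    @classmethod
    def placeholder(cls, population: str) -> "ObservedFrequencies":
        vals = OBSERVED_PLACEHOLDERS[population]
        logger.warning(
            "using synthetic placeholder frequencies for population %s", population
        )
        return cls(population, vals["YM"], vals["IIIM"], vals["IVF"])


def load_observed(path) -> dict[str, ObservedFrequencies]:
    """Load observed frequencies from a YAML mapping.

    Expected layout: ``{population: {YM: f, IIIM: f, IVF: f}, ...}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        pop: ObservedFrequencies(pop, v["YM"], v["IIIM"], v["IVF"])
        for pop, v in raw.items()
    }


def mse_to_observed(sim, obs) -> float:
    """Mean squared error over the three derived-chromosome frequencies."""
    sim = np.asarray(sim.as_array() if hasattr(sim, "as_array") else sim, dtype=float)
    obs = np.asarray(obs.as_array() if hasattr(obs, "as_array") else obs, dtype=float)
    if sim.shape != (3,) or obs.shape != (3,):
        raise ValueError("expected three chromosome frequencies on each side")
    return float(np.mean((sim - obs) ** 2))


@dataclass
class FitResult:
    """Top-k rejection ranking of fitness arrays against one population."""

    population: str
    k: int
    array_ids: np.ndarray   # (m,) ids of the selected arrays, best first
    mse: np.ndarray         # (m,) non-decreasing


def select_best_fitting(array_ids, chrom_freqs, maintained, obs, k: int = 1000) -> FitResult:
    """Rank PSD-maintaining arrays by MSE to the observed frequencies.

    ``chrom_freqs`` is (n, 3) in (Y^M, III^M, IV^F) order; ties in MSE are
    broken by ascending array id so the ranking is total and reproducible.
    Returns all maintaining arrays (with a warning) when fewer than k exist.
    """
    array_ids = np.asarray(array_ids)
    chrom_freqs = np.asarray(chrom_freqs, dtype=float)
    maintained = np.asarray(maintained, dtype=bool)
    if array_ids.size == 0:
        raise ValueError("no arrays supplied")
    target = obs.as_array() if hasattr(obs, "as_array") else np.asarray(obs)
    pop = getattr(obs, "population", "custom")

    ids = array_ids[maintained]
    if ids.size == 0:
        warnings.warn(f"no PSD-maintaining arrays to fit for {pop}")
        return FitResult(pop, k, np.array([], dtype=array_ids.dtype), np.array([]))
    errs = np.mean((chrom_freqs[maintained] - target) ** 2, axis=1)
    order = np.lexsort((ids, errs))  # primary: MSE ascending, ties by id
    if ids.size < k:
        warnings.warn(
            f"only {ids.size} PSD-maintaining arrays available for {pop} "
            f"(requested k={k})"
        )
    order = order[:k]
    return FitResult(pop, k, ids[order], errs[order])


def rho_mf(w_f, w_m, space: GenotypeSpace | None = None) -> float:
    """Intersexual fitness correlation over the eight male-female genotype pairs.

    Spearman's rank correlation between male genotype fitness (m1..m8) and
    the fitness of each male genotype's partner female genotype (f3..f10),
    with average ranks for ties.  Returns NaN (undefined) when either
    vector is constant.
    """
    space = space or enumerate_genotypes()
    w_f = np.asarray(w_f, dtype=float)
    w_m = np.asarray(w_m, dtype=float)
    paired_f = w_f[space.paired_female_positions]
    if np.ptp(paired_f) == 0.0 or np.ptp(w_m) == 0.0:
        return float("nan")
    return float(stats.spearmanr(w_m, paired_f).statistic)


def rho_mf_batch(w_f, w_m, space: GenotypeSpace | None = None) -> np.ndarray:
    """Vectorised :func:`rho_mf` over (n, 10) and (n, 8) fitness arrays."""
    space = space or enumerate_genotypes()
    w_f = np.atleast_2d(np.asarray(w_f, dtype=float))
    w_m = np.atleast_2d(np.asarray(w_m, dtype=float))
    paired_f = w_f[:, space.paired_female_positions]
    out = np.empty(w_m.shape[0])
    for i in range(w_m.shape[0]):
        if np.ptp(paired_f[i]) == 0.0 or np.ptp(w_m[i]) == 0.0:
            out[i] = np.nan
        else:
            out[i] = stats.spearmanr(w_m[i], paired_f[i]).statistic
    return out


def maintenance_fraction(maintained) -> float:
    """Share of fitness arrays keeping all three derived chromosomes polymorphic."""
    flags = np.asarray(
        [r.psd_maintained if hasattr(r, "psd_maintained") else r for r in maintained],
        dtype=bool,
    )
    if flags.size == 0:
        raise ValueError("empty batch")
    return float(flags.mean())


def effect_frequency_association(s_f_ivf, freq_ivf) -> dict[str, float]:
    """Rank correlation between IV^F female benefit and IV^F frequency.

    The benefit convention is ``benefit = -s`` (the carrier fitness is
    ``1 - s``, so more negative s means more female-beneficial); a positive
    correlation therefore reads "the more female-beneficial the IV^F, the
    higher its frequency".  The raw-s correlation is reported alongside.
    Returns NaN correlations for fewer than 3 points or constant inputs.
    """
    s = np.asarray(s_f_ivf, dtype=float)
    f = np.asarray(freq_ivf, dtype=float)
    if s.shape != f.shape:
        raise ValueError("mismatched input lengths")
    if s.size < 3 or np.ptp(s) == 0.0 or np.ptp(f) == 0.0:
        return {"rho_benefit": float("nan"), "rho_raw": float("nan")}
    rho_raw = float(stats.spearmanr(s, f).statistic)
    return {"rho_benefit": -rho_raw, "rho_raw": rho_raw}
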