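"""Selection coefficients and dominance schemes for proto-sex chromosomes.

Each proto-Y (Y^M, III^M) and the proto-W (IV^F) chromosome is assigned a
per-sex selection coefficient ``s`` drawn from Uniform(-1, 1).  Single-pair
genotype fitness follows the dominance table below, where columns are the
number of derived-allele copies (0, 1, 2) in the pair:

====================  ===========  ==============  =========
scheme                0 copies     1 copy          2 copies
====================  ===========  ==============  =========
additive, s > 0       1 - s        1 - s/2         1
additive, s < 0       1            1 + s/2         1 + s
dominant, s > 0       1 - s        1               1
dominant, s < 0       1            1 + s           1 + s
recessive, s > 0      1 - s        1 - s           1
recessive, s < 0      1            1                1 + s
overdominant, s > 0   1 - s        1               1 - s
overdominant, s < 0   1 + s        1               1 + s
====================  ===========  ==============  =========

The overdominant rows apply to proto-Y pairs in males only (the male
heterozygote always has fitness 1, a heterozygote advantage of magnitude
|s|); under the overdominant scheme females use the additive rows.  The
IV^F pair has a single carrier state (IV/IV^F, males never transmit IV^F)
whose fitness is ``1 - s`` for all s, so negative s is female-beneficial.

Multi-chromosome genotype fitness is the product of the three single-pair
values, evaluated with that genotype's sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import (
    DERIVED_ALLELES,
    FEMALE,
    GenotypeSpace,
    InvalidGenotypeError,
    MALE,
    enumerate_genotypes,
)

SCHEMES = ("additive", "dominant", "recessive", "overdominant")
SEXES = (FEMALE, MALE)


@dataclass(frozen=True)
class SelectionCoefficients:
    """Per-sex, per-derived-chromosome selection coefficients in [-1, 1].

    ``s[male][IVF]`` exists for symmetry but is never consulted: males
    cannot carry IV^F.
    """

    female: tuple[float, float, float]  # (YM, IIIM, IVF)
    male: tuple[float, float, float]

    def __post_init__(self):
        for sex_vals in (self.female, self.male):
            for s in sex_vals:
                if not -1.0 <= s <= 1.0:
                    raise ValueError(f"selection coefficient {s} outside [-1, 1]")

    @classmethod
    def neutral(cls) -> "SelectionCoefficients":
        return cls(female=(0.0, 0.0, 0.0), male=(0.0, 0.0, 0.0))

    @classmethod
    def from_array(cls, arr) -> "SelectionCoefficients":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (2, 3):
            raise ValueError(f"expected shape (2, 3), got {arr.shape}")
        return cls(female=tuple(arr[0]), male=tuple(arr[1]))

    def as_array(self) -> np.ndarray:
        """Shape (2, 3): rows (female, male), columns (YM, IIIM, IVF)."""
        return np.array([self.female, self.male], dtype=float)

    def get(self, sex: str, chromosome: str) -> float:
        row = self.female if sex == FEMALE else self.male
        return row[DERIVED_ALLELES.index(chromosome)]


def sample_selection_coefficients(rng: np.random.Generator, size: int | None = None):
    """Draw Uniform(-1, 1) coefficients for each sex and derived chromosome.

    With ``size=None`` returns one :class:`SelectionCoefficients`; otherwise
    an array of shape ``(size, 2, 3)`` (rows female/male, columns
    Y^M/III^M/IV^F).  Extending ``size`` extends the draw without
    perturbing earlier rows (row-major fill of a single uniform stream).
    """
    if size is None:
        return SelectionCoefficients.from_array(rng.uniform(-1.0, 1.0, size=(2, 3)))
    return rng.uniform(-1.0, 1.0, size=(int(size), 2, 3))


def _proto_y_table(scheme: str, s: float) -> tuple[float, float, float]:
    if s >= 0:
        rows = {
            "additive": (1.0 - s, 1.0 - 0.5 * s, 1.0),
            "dominant": (1.0 - s, 1.0, 1.0),
            "recessive": (1.0 - s, 1.0 - s, 1.0),
            "overdominant": (1.0 - s, 1.0, 1.0 - s),
        }
    else:
        rows = {
            "additive": (1.0, 1.0 + 0.5 * s, 1.0 + s),
            "dominant": (1.0, 1.0 + s, 1.0 + s),
            "recessive": (1.0, 1.0, 1.0 + s),
            "overdominant": (1.0 + s, 1.0, 1.0 + s),
        }
    return rows[scheme]


def single_pair_fitness(
    scheme: str, s: float, derived_count: int, sex: str, pair: int
) -> float:
    """Fitness of one chromosome-pair genotype under a dominance scheme.

    ``pair`` is 0 (X/Y^M), 1 (III/III^M) or 2 (IV/IV^F); ``derived_count``
    is the number of derived-allele copies.  Overdominance applies to
    proto-Y pairs in males only; females fall back to the additive rows.
    The IV^F pair ignores the scheme: its sole carrier state has fitness
    ``1 - s``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown dominance scheme {scheme!r}")
    if not -1.0 <= s <= 1.0:
        raise ValueError(f"selection coefficient {s} outside [-1, 1]")
    if pair == 2:
        if derived_count not in (0, 1):
            raise InvalidGenotypeError("IV^F derived count must be 0 or 1")
        return 1.0 - s if derived_count == 1 else 1.0
    if derived_count not in (0, 1, 2):
        raise InvalidGenotypeError("proto-Y derived count must be 0, 1, or 2")
    effective = scheme
    if scheme == "overdominant" and sex == FEMALE:
        effective = "additive"
    return _proto_y_table(effective, s)[derived_count]


@dataclass(frozen=True)
class FitnessArray:
    """Multiplicative fitness of the 10 female and 8 male genotypes."""

    w_f: np.ndarray  # (10,)
    w_m: np.ndarray  # (8,)

    def __post_init__(self):
        object.__setattr__(self, "w_f", np.asarray(self.w_f, dtype=float))
        object.__setattr__(self, "w_m", np.asarray(self.w_m, dtype=float))
        if self.w_f.shape != (10,) or self.w_m.shape != (8,):
            raise ValueError("fitness arrays must have shapes (10,) and (8,)")
        if (self.w_f < 0).any() or (self.w_m < 0).any():
            raise ValueError("fitness values must be nonnegative")

    @classmethod
    def neutral(cls) -> "FitnessArray":
        return cls(np.ones(10), np.ones(8))


def build_fitness_array(
    coeffs: SelectionCoefficients,
    scheme: str,
    space: GenotypeSpace | None = None,
) -> FitnessArray:
    """Multiply single-pair fitness values over the three chromosome pairs."""
    space = space or enumerate_genotypes()
    w_f = np.empty(len(space.females))
    w_m = np.empty(len(space.males))
    for arr, genotypes, sex, row in (
        (w_f, space.females, FEMALE, coeffs.female),
        (w_m, space.males, MALE, coeffs.male),
    ):
        for i, g in enumerate(genotypes):
            w = 1.0
            for pair in range(3):
                w *= single_pair_fitness(scheme, row[pair], g.counts[pair], sex, pair)
            arr[i] = w
    return FitnessArray(w_f, w_m)


def _proto_y_fitness_vec(scheme: str, s: np.ndarray, count: int) -> np.ndarray:
    """Vectorised dominance table lookup for one derived-copy count."""
    sp = np.maximum(s, 0.0)  # positive part
    sn = np.minimum(s, 0.0)  # negative part
    if scheme == "additive":
        vals = (1.0 - sp, 1.0 - 0.5 * sp + 0.5 * sn, 1.0 + sn)
    elif scheme == "dominant":
        vals = (1.0 - sp, 1.0 + sn, 1.0 + sn)
    elif scheme == "recessive":
        vals = (1.0 - sp, 1.0 - sp, 1.0 + sn)
    elif scheme == "overdominant":
        vals = (1.0 - sp + sn, np.ones_like(s), 1.0 - sp + sn)
    else:  # pragma: no cover
        raise ValueError(f"unknown dominance scheme {scheme!r}")
    return vals[count]


def build_fitness_arrays(
    coeff_array: np.ndarray,
    scheme: str,
    space: GenotypeSpace | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch version of :func:`build_fitness_array`.

    ``coeff_array`` has shape (n, 2, 3); returns ``(w_f, w_m)`` of shapes
    (n, 10) and (n, 8).  Bitwise-identical to the scalar builder.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown dominance scheme {scheme!r}")
    space = space or enumerate_genotypes()
    coeff_array = np.asarray(coeff_array, dtype=float)
    n = coeff_array.shape[0]
    female_scheme = "additive" if scheme == "overdominant" else scheme
    w_f = np.ones((n, len(space.females)))
    w_m = np.ones((n, len(space.males)))
    for out, genotypes, sex_idx, sex_scheme in (
        (w_f, space.females, 0, female_scheme),
        (w_m, space.males, 1, scheme),
    ):
        for i, g in enumerate(genotypes):
            w = np.ones(n)
            for pair in range(2):
                s = coeff_array[:, sex_idx, pair]
                w = w * _proto_y_fitness_vec(sex_scheme, s, g.counts[pair])
            if g.counts[2] == 1:
                w = w * (1.0 - coeff_array[:, sex_idx, 2])
            out[:, i] = w
    return w_f, w_m
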