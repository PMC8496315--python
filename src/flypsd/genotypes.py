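"""Proto-sex chromosome genotype space of the house fly.

The house fly (*Musca domestica*) segregates three proto-sex chromosome
pairs within single populations:

* pair 1: standard X vs. the proto-Y ``Y^M`` carrying the male determiner
  *Mdmd*,
* pair 3: standard III vs. the proto-Y ``III^M``, also carrying *Mdmd*,
* pair 4: standard IV vs. the proto-W ``IV^F`` carrying the epistatically
  dominant female determiner *Md-tra^D*.

Sex is determined epistatically: any copy of IV^F forces female development
regardless of *Mdmd*; otherwise any proto-Y copy makes a male; with neither,
the default is female.  Because males never carry IV^F, no union of gametes
can produce an IV^F/IV^F homozygote, and the reachable diploid space has
exactly 18 members: 10 female genotypes (f1..f10) and 8 male genotypes
(m1..m8).  Each male genotype has a partner female genotype differing only
by one IV^F copy; f1 and f2 have no male partner.

Genotypes are unordered allele multisets per chromosome pair (no
parental-origin tracking) and sex is always recomputed from the rule, never
stored as free data.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: chromosome-pair bookkeeping, in canonical order
PAIR_LABELS = ("pair1", "pair3", "pair4")
STANDARD_ALLELES = ("X", "III", "IV")
DERIVED_ALLELES = ("YM", "IIIM", "IVF")
#: maximum derived-allele copies per pair in the reachable space
MAX_DERIVED = (2, 2, 1)

N_FEMALE = 10
N_MALE = 8
N_GENOTYPES = 18
N_GAMETES = 8

FEMALE = "female"
MALE = "male"


class InvalidGenotypeError(ValueError):
    """Raised for derived-allele counts outside the reachable space."""


def _validate_counts(counts) -> tuple[int, int, int]:
    if len(counts) != 3:
        raise InvalidGenotypeError(f"expected 3 derived counts, got {counts!r}")
    c1, c3, c4 = (int(c) for c in counts)
    if not (0 <= c1 <= 2 and 0 <= c3 <= 2 and 0 <= c4 <= 1):
        raise InvalidGenotypeError(
            f"counts {counts!r} outside bounds (0..2, 0..2, 0..1)"
        )
    return c1, c3, c4


def determine_sex(counts) -> str:
    """Epistatic sex determination from derived-allele counts.

    ``counts`` is ``(n_YM, n_IIIM, n_IVF)``.  A copy of IV^F (Md-tra^D) is
    epistatically female-determining; otherwise any Mdmd-bearing chromosome
    (Y^M or III^M) is male-determining; the no-determiner genotype develops
    female.
    """
    c1, c3, c4 = _validate_counts(counts)
    if c4 >= 1:
        return FEMALE
    if c1 + c3 >= 1:
        return MALE
    return FEMALE


@dataclass(frozen=True)
class Genotype:
    """One unordered three-pair diploid genotype, e.g. X/Y^M; III/III; IV/IV^F."""

    label: str
    counts: tuple[int, int, int]

    @property
    def sex(self) -> str:
        return determine_sex(self.counts)

    def pair_string(self, pair: int) -> str:
        std, der = STANDARD_ALLELES[pair], DERIVED_ALLELES[pair]
        n = self.counts[pair]
        alleles = [std] * (2 - n) + [der] * n
        return "/".join(alleles)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label}: " + " ".join(self.pair_string(i) for i in range(3))


def gamete_distribution(genotype: Genotype | tuple[int, int, int]) -> np.ndarray:
    """Mendelian gamete distribution over the 8 haploid gamete types.

    Chromosome pairs assort independently and each heterozygous pair
    transmits either allele with probability 1/2.  Gamete ``g`` is indexed
    lexicographically by (pair1 allele, pair3 allele, pair4 allele) with
    standard < derived: ``index = 4*a1 + 2*a3 + a4`` where ``a`` is 1 for
    the derived allele.  Entries are multiples of 1/8, so the distribution
    sums to 1 exactly in binary floating point.
    """
    counts = genotype.counts if isinstance(genotype, Genotype) else genotype
    c = _validate_counts(counts)
    p_derived = [ci / 2.0 for ci in c]
    out = np.empty(N_GAMETES)
    for a1, a3, a4 in itertools.product((0, 1), repeat=3):
        prob = 1.0
        for a, p in zip((a1, a3, a4), p_derived):
            prob *= p if a else 1.0 - p
        out[4 * a1 + 2 * a3 + a4] = prob
    return out


@dataclass(frozen=True)
class GenotypeSpace:
    """The 18 reachable genotypes in canonical order: f1..f10 then m1..m8."""

    genotypes: tuple[Genotype, ...]
    females: tuple[Genotype, ...]
    males: tuple[Genotype, ...]
    #: male label -> female label of the partner differing by one IV^F copy
    pairing: dict[str, str]
    #: derived-allele counts, shape (18, 3), canonical order
    counts: np.ndarray = field(repr=False)
    #: label -> index into the canonical order
    index: dict[str, int] = field(repr=False)
    #: for male position j (0-based in males), index of the partner in females
    paired_female_positions: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.genotypes)

    def to_frame(self) -> pd.DataFrame:
        """Genotype table (id, pair1, pair3, pair4, sex) in canonical order."""
        rows = [
            {
                "id": g.label,
                "pair1": g.pair_string(0),
                "pair3": g.pair_string(1),
                "pair4": g.pair_string(2),
                "sex": g.sex,
            }
            for g in self.genotypes
        ]
        return pd.DataFrame(rows)

    def dump_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_frame().to_dict(orient="records"), fh, indent=1)


def enumerate_genotypes() -> GenotypeSpace:
    """Enumerate the 18 reachable genotypes with pairing map populated.

    Females are ordered f1 = X/X;III/III;IV/IV first, then the nine IV^F
    carriers by ascending (Y^M count, III^M count); males by the same key.
    This matches the conventional tabulation of the house fly system so all
    outputs are directly comparable to published genotype tables.
    """
    all_counts = [
        (c1, c3, c4)
        for c1 in range(3)
        for c3 in range(3)
        for c4 in range(2)
    ]
    # f1=(0,0,0) sorts first under (c1, c3, c4); the IV^F carriers follow
    females = sorted(
        (c for c in all_counts if determine_sex(c) == FEMALE),
        key=lambda c: (c[0], c[1], c[2]),
    )
    males = sorted(
        (c for c in all_counts if determine_sex(c) == MALE),
        key=lambda c: (c[0], c[1]),
    )
    female_gts = tuple(
        Genotype(f"f{i + 1}", c) for i, c in enumerate(females)
    )
    male_gts = tuple(Genotype(f"m{i + 1}", c) for i, c in enumerate(males))
    genotypes = female_gts + male_gts

    by_counts = {g.counts: g for g in genotypes}
    pairing = {}
    paired_pos = np.empty(len(male_gts), dtype=np.intp)
    for j, m in enumerate(male_gts):
        partner = by_counts[(m.counts[0], m.counts[1], 1)]
        pairing[m.label] = partner.label
        paired_pos[j] = female_gts.index(partner)

    counts = np.array([g.counts for g in genotypes], dtype=np.intp)
    index = {g.label: i for i, g in enumerate(genotypes)}
    return GenotypeSpace(
        genotypes=genotypes,
        females=female_gts,
        males=male_gts,
        pairing=pairing,
        counts=counts,
        index=index,
        paired_female_positions=paired_pos,
    )
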