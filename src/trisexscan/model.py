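"""Sex-determination model for a three sex chromosome (W/Z/Y) system.

Xenopus tropicalis carries three co-segregating sex chromosome types.  Sex
is determined by a dominance hierarchy: any individual carrying a Y is male;
otherwise any individual carrying a W is female; ZZ individuals are male.
Females can therefore be WW or WZ and males ZZ, ZY or WY, giving six
possible parental genotype combinations, each with its own expected
offspring sex ratio and pattern of parent-of-origin sex linkage.

This module enumerates those crosses and derives, analytically, the
offspring genotype distribution, the expected female fraction, and whether
genetic variation on a parental chromosome is expected to be completely
sex-linked (every son and no daughter inherits the paternal Y; every
daughter and no son inherits the maternal W).
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable


class ChromType(enum.IntEnum):
    """One of the three sex chromosome types, ordered W < Z < Y."""

    W = 0
    Z = 1
    Y = 2

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


FEMALE = "female"
MALE = "male"


def sex_of(alleles: Iterable[ChromType]) -> str:
    """Phenotypic sex of a two-chromosome genotype.

    Dominance rule: any Y -> male; otherwise any W -> female; else (ZZ)
    male.  YY does not arise from natural crosses but is classified male
    by the same rule.
    """
    pair = tuple(alleles)
    if len(pair) != 2:
        raise ValueError(f"a sex chromosome genotype has exactly 2 alleles, got {len(pair)}")
    if ChromType.Y in pair:
        return MALE
    if ChromType.W in pair:
        return FEMALE
    return MALE


@dataclass(frozen=True, order=True)
class SexChromGenotype:
    """Unordered pair of sex chromosome types; sex derives from the pair."""

    alleles: tuple[ChromType, ChromType]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("exactly two alleles required")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @classmethod
    def from_string(cls, s: str) -> "SexChromGenotype":
        return cls(tuple(ChromType[c] for c in s.upper()))

    @property
    def sex(self) -> str:
        return sex_of(self.alleles)

    def __str__(self) -> str:
        return "".join(a.name for a in self.alleles)

    def __repr__(self) -> str:
        return f"SexChromGenotype({self})"


def genotype(s: str) -> SexChromGenotype:
    """Shorthand constructor: genotype('WZ')."""
    return SexChromGenotype.from_string(s)


@dataclass(frozen=True)
class CrossSpec:
    """A mother x father pairing; parental sexes are enforced."""

    mother: SexChromGenotype
    father: SexChromGenotype

    def __post_init__(self) -> None:
        if self.mother.sex != FEMALE:
            raise ValueError(f"mother {self.mother} is not a female genotype")
        if self.father.sex != MALE:
            raise ValueError(f"father {self.father} is not a male genotype")

    def __str__(self) -> str:
        return f"{self.mother}x{self.father}"


@dataclass
class CrossExpectation:
    """Analytic expectations for one cross under Mendelian segregation."""

    cross: CrossSpec
    offspring_dist: dict[SexChromGenotype, Fraction]
    female_fraction: Fraction
    complete_paternal_Y_linkage: bool
    complete_maternal_W_linkage: bool
    # parent-of-origin resolved distribution: (maternal, paternal) -> prob
    ordered_dist: dict[tuple[ChromType, ChromType], Fraction] = field(default_factory=dict)

    @property
    def male_fraction(self) -> Fraction:
        return 1 - self.female_fraction

    def sex_ratio_male_per_female(self) -> float:
        """Males per female; inf when no daughters are expected."""
        if self.female_fraction == 0:
            return float("inf")
        return float(self.male_fraction / self.female_fraction)


FEMALE_GENOTYPES = (genotype("WW"), genotype("WZ"))
MALE_GENOTYPES = (genotype("ZZ"), genotype("ZY"), genotype("WY"))


def enumerate_crosses() -> list[CrossSpec]:
    """All six mother x father genotype combinations, in canonical order."""
    return [CrossSpec(m, f) for m, f in itertools.product(FEMALE_GENOTYPES, MALE_GENOTYPES)]


def cross_expectation(cross: CrossSpec, distortion: float = 0.5) -> CrossExpectation:
    """Offspring genotype distribution and linkage flags for one cross.

    Gametes are drawn with equal probability from each parent by default;
    ``distortion`` is the transmission probability of the first (canonically
    smaller) allele of each heterozygous parent and exists only to model
    segregation distortion explicitly — it defaults to fair Mendelian 0.5.
    """
    if not 0 <= distortion <= 1:
        raise ValueError("distortion must lie in [0, 1]")

    def gametes(parent: SexChromGenotype) -> dict[ChromType, Fraction]:
        a, b = parent.alleles
        if a == b:
            return {a: Fraction(1)}
        p = Fraction(distortion).limit_denominator(10**6)
        return {a: p, b: 1 - p}

    ordered: dict[tuple[ChromType, ChromType], Fraction] = {}
    for ma, mp in gametes(cross.mother).items():
        for fa, fp in gametes(cross.father).items():
            if mp * fp == 0:
                continue
            key = (ma, fa)
            ordered[key] = ordered.get(key, Fraction(0)) + mp * fp

    dist: dict[SexChromGenotype, Fraction] = {}
    for (ma, fa), p in ordered.items():
        g = SexChromGenotype((ma, fa))
        dist[g] = dist.get(g, Fraction(0)) + p

    female_fraction = sum((p for g, p in dist.items() if g.sex == FEMALE), Fraction(0))

    # Paternal Y linkage: father carries exactly one Y, every son inherits
    # the paternal Y and no daughter does.
    father_has_one_y = cross.father.alleles.count(ChromType.Y) == 1
    pat_y = father_has_one_y and all(
        (fa == ChromType.Y) == (sex_of((ma, fa)) == MALE) for (ma, fa) in ordered
    )
    # Maternal W linkage: every daughter inherits a maternal W and no son
    # does.  (Mothers never carry Y, so the informative allele is W.)
    mat_w = ChromType.W in cross.mother.alleles and all(
        (ma == ChromType.W) == (sex_of((ma, fa)) == FEMALE) for (ma, fa) in ordered
    )

    return CrossExpectation(
        cross=cross,
        offspring_dist=dist,
        female_fraction=female_fraction,
        complete_paternal_Y_linkage=pat_y,
        complete_maternal_W_linkage=mat_w,
        ordered_dist=ordered,
    )


def crosses_with_complete_paternal_linkage() -> list[CrossSpec]:
    """Crosses where paternal variation is completely male-linked."""
    return [c for c in enumerate_crosses() if cross_expectation(c).complete_paternal_Y_linkage]


def crosses_with_complete_maternal_linkage() -> list[CrossSpec]:
    """Crosses where maternal variation is completely female-linked."""
    return [c for c in enumerate_crosses() if cross_expectation(c).complete_maternal_W_linkage]


def null_full_linkage_probability(n_het_sex: int, n_hom_sex: int) -> float:
    """Probability of perfect co-segregation with sex under independence.

    If each individual is heterozygous with probability 1/2 regardless of
    sex, the chance that all ``n_het_sex`` individuals of one sex are
    heterozygous and all ``n_hom_sex`` of the other are homozygous is
    (1/2)^(n_het_sex + n_hom_sex).
    """
    if n_het_sex < 0 or n_hom_sex < 0:
        raise ValueError("counts must be non-negative")
    return 0.5 ** (n_het_sex + n_hom_sex)


def expectations_table() -> list[dict]:
    """All cross expectations as plain records (TSV/JSON friendly)."""
    rows = []
    for c in enumerate_crosses():
        exp = cross_expectation(c)
        for g, p in sorted(exp.offspring_dist.items()):
            rows.append(
                {
                    "cross": str(c),
                    "offspring_genotype": str(g),
                    "probability": float(p),
                    "sex": g.sex,
                    "female_fraction": float(exp.female_fraction),
                    "complete_paternal_Y_linkage": exp.complete_paternal_Y_linkage,
                    "complete_maternal_W_linkage": exp.complete_maternal_W_linkage,
                }
            )
    return rows


def expectations_json() -> str:
    return json.dumps(expectations_table(), indent=2)
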