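"""Shared domain types for the three-strain hybrid cross.

The cross design: three inbred strains — CA (the reference strain), WA and
LR — are crossed to produce two F1 hybrids, a CA/WA male and a CA/LR
hermaphrodite. Their F2 progeny carry one recombinant haplotype from each
F1 parent, so at any locus an F2 genotype is one of the four unordered
pairs CA/CA, CA/WA, CA/LR, WA/LR, and the strain labels uniquely identify
the transmitting parent: WA haplotypes only ever arrive through sperm, LR
haplotypes only through ova.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Strain(enum.IntEnum):
    """One of the three inbred parental strains."""

    CA = 0
    WA = 1
    LR = 2

    def __str__(self) -> str:  # TSV-friendly
        return self.name


STRAIN_NAMES = ("CA", "WA", "LR")

#: Sentinel for a missing / uncalled strain label in integer label arrays.
MISSING = -1


class Genotype(enum.IntEnum):
    """Four-way F2 genotype of a genomic block; NO_CALL for unresolved."""

    CA_CA = 0
    CA_WA = 1
    CA_LR = 2
    WA_LR = 3
    NO_CALL = -1

    def __str__(self) -> str:
        if self is Genotype.NO_CALL:
            return "no_call"
        return self.name.replace("_", "/")


GENOTYPE_NAMES = {g: str(g) for g in Genotype}


class Parent(enum.Enum):
    """Which F1 transmitted a haplotype: the male (paternal, CA/WA) or the
    hermaphrodite (maternal, CA/LR)."""

    PATERNAL = "paternal"
    MATERNAL = "maternal"

    def __str__(self) -> str:
        return self.value


#: Strains a haplotype from each parent can carry.
PARENT_STRAINS = {
    Parent.PATERNAL: (Strain.CA, Strain.WA),
    Parent.MATERNAL: (Strain.CA, Strain.LR),
}


@dataclass(frozen=True)
class ChromosomeSpec:
    """Physical description of one chromosome.

    Parameters
    ----------
    name:
        Chromosome identifier (e.g. ``"ChrI"``).
    length:
        Length in bp; must be positive.
    is_x:
        True for the X. Under XX/XO sex determination the male carries a
        single X with no pairing partner, so no paternal meiotic exchange
        is modeled for it and no male map exists.
    arm_boundaries:
        Two strictly increasing bp coordinates partitioning the chromosome
        into left arm / center / right arm. Recombination is elevated on
        the arms relative to the center. Defaults to the 25% and 75%
        points.
    """

    name: str
    length: int
    is_x: bool = False
    arm_boundaries: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.arm_boundaries is None:
            object.__setattr__(
                self,
                "arm_boundaries",
                (round(self.length * 0.25), round(self.length * 0.75)),
            )
        b1, b2 = self.arm_boundaries
        if not (0 <= b1 < b2 <= self.length):
            raise ValueError(
                f"chromosome {self.name}: arm_boundaries must be strictly "
                f"increasing within [0, {self.length}]"
            )


def default_karyotype() -> list[ChromosomeSpec]:
    """Six-chromosome (2n = 12) karyotype used by the simulator.

    Lengths are synthetic stand-ins summing to 156.7 Mb so the genome tiles
    into exactly 1567 non-overlapping 100-kb blocks; the X is the shortest
    chromosome.
    """
    mb = 1_000_000
    return [
        ChromosomeSpec("ChrI", int(36.8 * mb)),
        ChromosomeSpec("ChrII", int(28.4 * mb)),
        ChromosomeSpec("ChrIII", int(24.4 * mb)),
        ChromosomeSpec("ChrIV", int(26.0 * mb)),
        ChromosomeSpec("ChrV", int(23.9 * mb)),
        ChromosomeSpec("ChrX", int(17.2 * mb), is_x=True),
    ]


@dataclass
class COModel:
    """Crossover model for one meiosis.

    With ``obligate=True`` every meiosis receives exactly one crossover
    (plus a second with probability ``double_co_rate``); otherwise the
    crossover count is Poisson with mean ``co_per_meiosis``. Positions are
    drawn from a piecewise-uniform density: relative density ``arm_weight``
    on the arms, 1 in the center, 0 inside ``suppressed_regions``.
    """

    co_per_meiosis: float = 1.0
    obligate: bool = True
    arm_weight: float = 3.0
    suppressed_regions: list[tuple[str, int, int]] = field(default_factory=list)
    double_co_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.co_per_meiosis < 0:
            raise ValueError("co_per_meiosis must be >= 0")
        if self.arm_weight < 0:
            raise ValueError("arm_weight must be >= 0")
        if not 0.0 <= self.double_co_rate <= 1.0:
            raise ValueError("double_co_rate must be in [0, 1]")


@dataclass
class ViabilitySelection:
    """Single-locus viability selection against one parental haplotype.

    An F2 whose haplotype of origin ``parent`` carries ``disfavored_strain``
    at ``(chromosome, position)`` survives with probability
    ``relative_viability``; all other F2 survive with probability 1.
    ``relative_viability = 1`` means no selection.
    """

    chromosome: str
    position: int
    disfavored_strain: Strain
    parent: Parent = Parent.MATERNAL
    relative_viability: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_viability <= 1.0:
            raise ValueError("relative_viability must be in (0, 1]")
        if self.disfavored_strain not in PARENT_STRAINS[self.parent]:
            raise ValueError(
                f"{self.disfavored_strain} cannot be transmitted by the "
                f"{self.parent} parent"
            )
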