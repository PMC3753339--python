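"""Genomes as chromosome copy-number vectors, gene linkage and mis-segregation.

A cell's genome is a multiset of whole chromosomes.  Each chromosome type
carries a fixed bundle of abstract regulatory genes drawn from three classes:

* *division* genes (proto-oncogene abstraction) promote proliferation,
* *apoptosis* genes (tumour-suppressor abstraction) promote crowding-induced
  death,
* *segregation* genes (genome-stability abstraction) protect the fidelity of
  chromosome segregation at mitosis.

Which classes share a chromosome ("genetic linkage") is the experimental
variable: linked genes are gained and lost together whenever a whole
chromosome mis-segregates.  Three two-chromosome layouts (``A``, ``B``, ``C``)
plus a fully ``unlinked`` three-chromosome control are predefined; arbitrary
layouts can be declared in configuration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "GeneClass",
    "GENE_ORDER",
    "ChromosomeType",
    "GeneDistribution",
    "Genome",
    "GenotypeState",
    "make_initial_genome",
    "genotype_state",
    "segregate",
    "rgb_color",
]


class GeneClass(enum.Enum):
    """The three abstract gene classes carried on chromosomes."""

    DIVISION = "division"
    APOPTOSIS = "apoptosis"
    SEGREGATION = "segregation"


#: Canonical component order of a genotype state: (division, apoptosis, segregation).
GENE_ORDER: tuple[GeneClass, ...] = (
    GeneClass.DIVISION,
    GeneClass.APOPTOSIS,
    GeneClass.SEGREGATION,
)


class GenotypeState(NamedTuple):
    """Total gene copy numbers ``(n_div, n_apop, n_seg)`` — the unit of clone identity.

    The initial diploid state is ``(2, 2, 2)``; mis-segregation moves a cell
    through this lattice one linked bundle at a time.
    """

    n_div: int
    n_apop: int
    n_seg: int


@dataclass(frozen=True)
class ChromosomeType:
    """A chromosome species and the gene copies one physical copy carries.

    ``content`` is the per-copy gene payload in :data:`GENE_ORDER`, e.g.
    ``(1, 1, 0)`` for a chromosome carrying one division and one apoptosis
    gene.
    """

    id: int
    content: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.content) != 3 or any(c < 0 for c in self.content):
            raise ConfigurationError(
                f"chromosome {self.id}: content must be three non-negative "
                f"gene counts, got {self.content!r}"
            )
        if not any(self.content):
            raise ConfigurationError(
                f"chromosome {self.id}: at least one gene class must be present"
            )

    @property
    def gene_content(self) -> dict[GeneClass, int]:
        return dict(zip(GENE_ORDER, self.content))


@dataclass(frozen=True)
class GeneDistribution:
    """A named arrangement of the three gene classes onto chromosome types.

    Invariant: the chromosome types partition the gene classes — every class
    sits on exactly one type, so a genotype state maps back to a unique
    chromosome copy-number vector.
    """

    name: str
    chromosome_types: tuple[ChromosomeType, ...]

    def __post_init__(self) -> None:
        for col, cls in enumerate(GENE_ORDER):
            carriers = [t for t in self.chromosome_types if t.content[col] > 0]
            if len(carriers) != 1:
                raise ConfigurationError(
                    f"distribution {self.name!r}: gene class {cls.value!r} must "
                    f"appear on exactly one chromosome type, found on "
                    f"{len(carriers)}"
                )

    @classmethod
    def from_name(cls, name: str) -> "GeneDistribution":
        """Return one of the four canonical layouts by name.

        ``A`` links division+apoptosis, ``B`` division+segregation, ``C``
        apoptosis+segregation; ``unlinked`` places each class on its own
        chromosome.
        """
        try:
            layout = _NAMED_LAYOUTS[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown gene distribution {name!r}; expected one of "
                f"{sorted(_NAMED_LAYOUTS)} or a custom chromosome list"
            ) from None
        types = tuple(
            ChromosomeType(id=i + 1, content=content)
            for i, content in enumerate(layout)
        )
        return cls(name=name, chromosome_types=types)

    @classmethod
    def custom(
        cls, contents: Iterable[tuple[int, int, int]], name: str = "custom"
    ) -> "GeneDistribution":
        types = tuple(
            ChromosomeType(id=i + 1, content=tuple(c))  # type: ignore[arg-type]
            for i, c in enumerate(contents)
        )
        return cls(name=name, chromosome_types=types)

    @property
    def n_types(self) -> int:
        return len(self.chromosome_types)

    @property
    def content_matrix(self) -> np.ndarray:
        """(n_types, 3) integer matrix mapping copy counts to genotype states."""
        return np.array([t.content for t in self.chromosome_types], dtype=np.int64)


# (division, apoptosis, segregation) payload per chromosome type.
_NAMED_LAYOUTS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "A": ((1, 1, 0), (0, 0, 1)),
    "B": ((1, 0, 1), (0, 1, 0)),
    "C": ((0, 1, 1), (1, 0, 0)),
    "unlinked": ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
}


@dataclass(frozen=True)
class Genome:
    """Copy counts per chromosome type of one cell, under a fixed distribution."""

    distribution: GeneDistribution
    copy_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.copy_counts) != self.distribution.n_types:
            raise ConfigurationError(
                f"genome has {len(self.copy_counts)} counts for "
                f"{self.distribution.n_types} chromosome types"
            )
        if any(c < 0 for c in self.copy_counts):
            raise DomainError(f"negative chromosome copy count: {self.copy_counts}")

    @property
    def total_copies(self) -> int:
        return sum(self.copy_counts)

    def state(self) -> GenotypeState:
        return genotype_state(self)


def make_initial_genome(distribution: GeneDistribution) -> Genome:
    """The diploid starting genome: two copies of every chromosome type.

    For every canonical layout this realises the genotype state ``(2, 2, 2)``.
    """
    return Genome(distribution, (2,) * distribution.n_types)


def genotype_state(genome: Genome) -> GenotypeState:
    """Total gene copies per class: copy counts times per-chromosome content."""
    counts = np.asarray(genome.copy_counts, dtype=np.int64)
    totals = counts @ genome.distribution.content_matrix
    return GenotypeState(int(totals[0]), int(totals[1]), int(totals[2]))


def segregate(
    genome: Genome,
    missegregate: bool,
    rng: np.random.Generator,
    sampling: str = "copy",
) -> tuple[Genome, Genome]:
    """Split a duplicated genome into two daughters.

    Faithful division copies the mother into both daughters.  A
    mis-segregation event picks one chromosome and distributes it
    asymmetrically: one daughter gains a copy, the other loses one.  Which
    daughter gains is a fair coin (it affects only spatial placement).

    ``sampling`` selects the target chromosome: ``"copy"`` draws uniformly
    over physical chromosome copies (a type at higher copy number is
    proportionally more exposed), ``"type"`` uniformly over the types present.

    Conservation holds by construction: daughter counts sum to twice the
    mother's.
    """
    if not missegregate:
        return genome, genome
    counts = np.asarray(genome.copy_counts, dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        raise DomainError("cannot mis-segregate a genome with zero chromosomes")
    if sampling == "copy":
        r = rng.random() * total
        chosen = int((r >= np.cumsum(counts)).sum())
    elif sampling == "type":
        present = np.flatnonzero(counts > 0)
        chosen = int(present[int(rng.random() * present.size)])
    else:
        raise ConfigurationError(f"unknown mis-segregation sampling {sampling!r}")
    gained = list(genome.copy_counts)
    lost = list(genome.copy_counts)
    gained[chosen] += 1
    lost[chosen] -= 1
    d_gain = Genome(genome.distribution, tuple(gained))
    d_lose = Genome(genome.distribution, tuple(lost))
    if rng.random() < 0.5:
        return d_gain, d_lose
    return d_lose, d_gain


def rgb_color(
    state: GenotypeState, max_state: GenotypeState
) -> tuple[float, float, float]:
    """Map a genotype state to an RGB triplet in the unit colour cube.

    Each component is the gene count normalised by the maximum observed count
    for that class: red for division, green for apoptosis (death), blue for
    segregation.  ``(0,0,0)`` renders black, the diploid ``(2,2,2)`` under a
    maximum of ``(5,5,5)`` dark grey, and the maximum itself white.  Classes
    whose maximum is zero map to zero.
    """
    out = []
    for value, peak in zip(state, max_state):
        if peak <= 0:
            out.append(0.0)
        else:
            out.append(min(1.0, max(0.0, value / peak)))
    return (out[0], out[1], out[2])
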