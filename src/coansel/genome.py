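"""Genome layout and diploid population containers.

A genome is a set of chromosomes of equal genetic length (in Morgans), each
carrying the same number of equally spaced biallelic loci. Individuals are
stored as pairs of 0/1 haplotype vectors over all loci, ordered by
(chromosome, position), together with sex and generation labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

MALE = 0
FEMALE = 1


@dataclass(frozen=True)
class GenomeMap:
    """Equally spaced biallelic loci on equal-length chromosomes.

    Parameters
    ----------
    n_chromosomes
        Number of chromosomes.
    loci_per_chromosome
        Number of loci on each chromosome.
    chromosome_length
        Genetic length of each chromosome in Morgans (default 1.0).
    """

    n_chromosomes: int = 10
    loci_per_chromosome: int = 10100
    chromosome_length: float = 1.0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.loci_per_chromosome < 1:
            raise InvalidArgumentError("genome needs >=1 chromosome and >=1 locus")
        if self.chromosome_length <= 0:
            raise InvalidArgumentError("chromosome_length must be positive (Morgans)")

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    @property
    def locus_spacing(self) -> float:
        """Genetic distance between adjacent loci, in Morgans."""
        return self.chromosome_length / self.loci_per_chromosome

    def within_chromosome_positions(self) -> np.ndarray:
        """Positions (Morgans) of the loci of one chromosome, in [0, L)."""
        return (
            np.arange(self.loci_per_chromosome, dtype=np.float64)
            * self.locus_spacing
        )

    def locus_positions(self) -> np.ndarray:
        """Within-chromosome position of every locus, ordered genome-wide."""
        return np.tile(self.within_chromosome_positions(), self.n_chromosomes)

    def locus_chromosomes(self) -> np.ndarray:
        """Chromosome index (0-based) of every locus."""
        return np.repeat(
            np.arange(self.n_chromosomes), self.loci_per_chromosome
        )

    def chromosome_slice(self, c: int) -> slice:
        start = c * self.loci_per_chromosome
        return slice(start, start + self.loci_per_chromosome)


@dataclass
class Population:
    """A set of diploid individuals over a :class:`GenomeMap`.

    ``haplotypes`` has shape ``(n, 2, n_loci)`` with alleles in {0, 1};
    ``sexes`` uses 0 = male, 1 = female.
    """

    gmap: GenomeMap
    haplotypes: np.ndarray
    sexes: np.ndarray
    generations: np.ndarray = field(default=None)  # type: ignore[assignment]
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.sexes = np.asarray(self.sexes, dtype=np.uint8)
        n = self.haplotypes.shape[0]
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise InvalidArgumentError("haplotypes must have shape (n, 2, n_loci)")
        if self.haplotypes.shape[2] != self.gmap.n_loci:
            raise InvalidArgumentError(
                f"haplotype length {self.haplotypes.shape[2]} != "
                f"map loci {self.gmap.n_loci}"
            )
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise InvalidArgumentError("alleles must be 0/1")
        if self.sexes.shape != (n,):
            raise InvalidArgumentError("sexes must be one per individual")
        if self.generations is None:
            self.generations = np.zeros(n, dtype=np.int32)
        else:
            self.generations = np.asarray(self.generations, dtype=np.int32)
        if self.ids is None:
            self.ids = np.arange(n, dtype=np.int64)
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64)

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def males(self) -> np.ndarray:
        """Row indices of males."""
        return np.flatnonzero(self.sexes == MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sexes == FEMALE)

    def genotype_counts(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Copies of allele 1 per (individual, locus), values in {0, 1, 2}."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.int64)

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus frequency of allele 1 over all 2n gametes."""
        return self.haplotypes.mean(axis=(0, 1))

    def copy(self) -> "Population":
        return Population(
            self.gmap,
            self.haplotypes.copy(),
            self.sexes.copy(),
            self.generations.copy(),
            self.ids.copy(),
        )
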