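"""Forward-in-time neutral simulator for the mutation-drift-recombination base.

The base population is evolved with non-overlapping generations: every
generation all individuals are first mutated (each allele copy flips 0<->1
independently with probability ``mu``), then each offspring is produced by a
sire and a dam drawn uniformly at random with replacement, one recombinant
gamete from each. Crossover counts per chromosome are Poisson with mean equal
to the chromosome length in Morgans; crossover positions are uniform.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError, InvalidStateError
from .genome import FEMALE, MALE, GenomeMap, Population


def init_base(
    gmap: GenomeMap, n_individuals: int, rng: np.random.Generator
) -> Population:
    """Create a base population with every allele drawn uniformly from {0, 1}.

    Half of the individuals are male, half female; the expected per-locus
    heterozygosity is 0.5.
    """
    if n_individuals < 2 or n_individuals % 2 != 0:
        raise InvalidArgumentError("n_individuals must be even and >= 2")
    haps = rng.integers(0, 2, size=(n_individuals, 2, gmap.n_loci), dtype=np.uint8)
    sexes = np.empty(n_individuals, dtype=np.uint8)
    sexes[: n_individuals // 2] = MALE
    sexes[n_individuals // 2 :] = FEMALE
    return Population(gmap, haps, sexes)


def mutate(pop: Population, mu: float, rng: np.random.Generator) -> Population:
    """Flip each allele copy independently with probability ``mu``."""
    if not 0.0 <= mu <= 1.0:
        raise InvalidArgumentError(f"mutation rate {mu} outside [0, 1]")
    out = pop.copy()
    if mu > 0.0:
        flips = rng.random(out.haplotypes.shape) < mu
        out.haplotypes ^= flips.astype(np.uint8)
    return out


def make_gamete(
    parent_haplotypes: np.ndarray, gmap: GenomeMap, rng: np.random.Generator
) -> np.ndarray:
    """Recombinant gamete from a pair of parental haplotypes.

    Per chromosome: k ~ Poisson(length in Morgans) crossovers at uniform
    positions; the gamete alternates between the two parental haplotypes at
    each crossover, starting from a uniformly chosen haplotype. Chromosomes
    are independent.
    """
    parent_haplotypes = np.asarray(parent_haplotypes, dtype=np.uint8)
    if parent_haplotypes.shape != (2, gmap.n_loci):
        raise InvalidArgumentError("parent must have two haplotypes over the map")
    length = gmap.chromosome_length
    pos = gmap.within_chromosome_positions()
    out = np.empty(gmap.n_loci, dtype=np.uint8)
    for c in range(gmap.n_chromosomes):
        sl = gmap.chromosome_slice(c)
        k = rng.poisson(length)
        start = int(rng.integers(2))
        if k == 0:
            out[sl] = parent_haplotypes[start, sl]
        else:
            cuts = np.sort(rng.uniform(0.0, length, size=k))
            source = (start + np.searchsorted(cuts, pos, side="right")) % 2
            out[sl] = np.where(
                source == 0, parent_haplotypes[0, sl], parent_haplotypes[1, sl]
            )
    return out


def gametes_from_parents(
    haplotypes: np.ndarray,
    gmap: GenomeMap,
    sire_rows: np.ndarray,
    dam_rows: np.ndarray,
    mu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring haplotype pairs (paternal gamete first) with gametic mutation.

    ``mu`` is applied to the freshly formed gametes; pass 0 to disable.
    """
    if not 0.0 <= mu <= 1.0:
        raise InvalidArgumentError(f"mutation rate {mu} outside [0, 1]")
    n_off = len(sire_rows)
    out = np.empty((n_off, 2, gmap.n_loci), dtype=np.uint8)
    for j in range(n_off):
        out[j, 0] = make_gamete(haplotypes[sire_rows[j]], gmap, rng)
        out[j, 1] = make_gamete(haplotypes[dam_rows[j]], gmap, rng)
    if mu > 0.0:
        flips = rng.random(out.shape) < mu
        out ^= flips.astype(np.uint8)
    return out


def _random_parent_rows(
    pop: Population, n_offspring: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    males = pop.males()
    females = pop.females()
    if males.size == 0 or females.size == 0:
        raise InvalidStateError("population must contain both sexes to breed")
    sires = rng.choice(males, size=n_offspring, replace=True)
    dams = rng.choice(females, size=n_offspring, replace=True)
    return sires, dams


def evolve_base(
    pop: Population,
    n_generations: int,
    mu: float,
    rng: np.random.Generator,
) -> Population:
    """Evolve the base under random mating with mutation, constant size.

    Per generation: mutate every individual, then produce ``n`` offspring,
    each from a sire and a dam drawn uniformly with replacement (one gamete
    each); offspring sexes are half male, half female; generations do not
    overlap.
    """
    n = pop.n_individuals
    half = n // 2
    sexes = np.empty(n, dtype=np.uint8)
    sexes[:half] = MALE
    sexes[half:] = FEMALE
    for _ in range(n_generations):
        pop = mutate(pop, mu, rng)
        sires, dams = _random_parent_rows(pop, n, rng)
        haps = gametes_from_parents(pop.haplotypes, pop.gmap, sires, dams, 0.0, rng)
        pop = Population(
            pop.gmap, haps, sexes.copy(), pop.generations[:1].repeat(n) + 1
        )
    return pop


def heterozygosity(pop: Population) -> float:
    """Mean over individuals and loci of the two alleles differing."""
    if pop.n_individuals == 0:
        raise InvalidArgumentError("empty population")
    return float(np.mean(pop.haplotypes[:, 0, :] != pop.haplotypes[:, 1, :]))
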