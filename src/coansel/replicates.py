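"""Replicate construction: QTL sampling, founder draws, recorded random mating.

Each replicate reuses one shared base population but draws its own QTLs and
founders. Founders form pedigree generation 0 with unknown parents; the
recorded random-mating generations append every birth to the pedigree.
Mutation during recorded generations is applied to the gametes at birth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base_population import gametes_from_parents
from .errors import InvalidArgumentError, InvalidStateError
from .genome import FEMALE, MALE, GenomeMap, Population
from .pedigree import Pedigree


@dataclass(frozen=True)
class MarkerPanel:
    """An evenly thinned subset of loci used as the genotyping panel."""

    indices: np.ndarray
    markers_per_chromosome: int
    marker_chromosomes: np.ndarray

    @property
    def n_markers(self) -> int:
        return self.indices.size


def marker_panel(gmap: GenomeMap, markers_per_chromosome: int) -> MarkerPanel:
    """Evenly spaced marker subset; full density returns every locus."""
    loci = gmap.loci_per_chromosome
    if markers_per_chromosome < 1 or markers_per_chromosome > loci:
        raise InvalidArgumentError(
            f"requested {markers_per_chromosome} markers/chromosome, have {loci}"
        )
    if loci % markers_per_chromosome != 0:
        raise InvalidArgumentError(
            f"{markers_per_chromosome} does not thin {loci} loci evenly"
        )
    stride = loci // markers_per_chromosome
    within = np.arange(markers_per_chromosome, dtype=np.int64) * stride
    indices = np.concatenate(
        [within + c * loci for c in range(gmap.n_chromosomes)]
    )
    chroms = np.repeat(np.arange(gmap.n_chromosomes), markers_per_chromosome)
    return MarkerPanel(indices, markers_per_chromosome, chroms)


def roh_threshold_span_cm(
    gmap: GenomeMap, markers_per_chromosome: int, min_run: int = 100
) -> float:
    """Genetic span (cM) covered by a minimum-length ROH on a thinned panel.

    A run of ``min_run`` contiguous panel markers spans ``min_run - 1``
    inter-marker intervals; at 2525 markers on a 1 Morgan chromosome this is
    about 4 cM, at 10,100 markers about 1 cM.
    """
    panel = marker_panel(gmap, markers_per_chromosome)
    spacing_cm = gmap.chromosome_length * 100.0 / panel.markers_per_chromosome
    return (min_run - 1) * spacing_cm


def sample_qtls(
    base: Population,
    n_qtl: int,
    freq_lo: float,
    freq_hi: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw QTL loci uniformly among loci with freq_lo < p_j < freq_hi.

    p_j is the allele-1 frequency in the base population; bounds are strict.
    """
    if n_qtl < 1:
        raise InvalidArgumentError("n_qtl must be >= 1")
    p = base.allele_frequencies()
    eligible = np.flatnonzero((p > freq_lo) & (p < freq_hi))
    if eligible.size < n_qtl:
        raise InvalidStateError(
            f"only {eligible.size} loci with {freq_lo} < p < {freq_hi}, "
            f"need {n_qtl}"
        )
    return np.sort(rng.choice(eligible, size=n_qtl, replace=False))


def draw_founders(
    base: Population, n_per_sex: int, rng: np.random.Generator
) -> tuple[Population, Pedigree]:
    """Sample N sires and N dams without replacement from the base.

    Returns the founder population (pedigree ids 1..2N, generation 0) and
    the initialised pedigree with unknown parents.
    """
    if n_per_sex < 1:
        raise InvalidArgumentError("need at least one founder per sex")
    males = base.males()
    females = base.females()
    if males.size < n_per_sex or females.size < n_per_sex:
        raise InvalidArgumentError(
            f"base has {males.size} males / {females.size} females, "
            f"need {n_per_sex} of each"
        )
    sires = rng.choice(males, size=n_per_sex, replace=False)
    dams = rng.choice(females, size=n_per_sex, replace=False)
    rows = np.concatenate([sires, dams])
    n = 2 * n_per_sex
    ids = np.arange(1, n + 1, dtype=np.int64)
    sexes = np.concatenate(
        [np.full(n_per_sex, MALE, np.uint8), np.full(n_per_sex, FEMALE, np.uint8)]
    )
    pop = Population(
        base.gmap,
        base.haplotypes[rows].copy(),
        sexes,
        np.zeros(n, dtype=np.int32),
        ids,
    )
    ped = Pedigree()
    ped.append_cohort(ids, np.zeros(n), np.zeros(n), sexes, 0)
    return pop, ped


def breed_random_cohort(
    pop: Population,
    n_per_sex: int,
    mu: float,
    rng: np.random.Generator,
    id_start: int,
    generation: int,
) -> tuple[Population, np.ndarray, np.ndarray]:
    """One recorded random-mating cohort of N males + N females.

    Each offspring draws its sire and dam independently, uniformly with
    replacement, from the current generation; returns the offspring
    population plus parent pedigree-id arrays.
    """
    males = pop.males()
    females = pop.females()
    if males.size == 0 or females.size == 0:
        raise InvalidStateError("both sexes are required to breed")
    n = 2 * n_per_sex
    sire_rows = rng.choice(males, size=n, replace=True)
    dam_rows = rng.choice(females, size=n, replace=True)
    haps = gametes_from_parents(pop.haplotypes, pop.gmap, sire_rows, dam_rows, mu, rng)
    sexes = np.concatenate(
        [np.full(n_per_sex, MALE, np.uint8), np.full(n_per_sex, FEMALE, np.uint8)]
    )
    ids = np.arange(id_start, id_start + n, dtype=np.int64)
    off = Population(
        pop.gmap, haps, sexes, np.full(n, generation, np.int32), ids
    )
    return off, pop.ids[sire_rows], pop.ids[dam_rows]


def random_mating_generations(
    pop: Population,
    ped: Pedigree,
    n_generations: int,
    n_per_sex: int,
    mu: float,
    rng: np.random.Generator,
) -> tuple[Population, Pedigree]:
    """Run recorded random mating, appending every birth to the pedigree."""
    gen = int(pop.generations.max()) if pop.n_individuals else 0
    for _ in range(n_generations):
        gen += 1
        pop, sire_ids, dam_ids = breed_random_cohort(
            pop, n_per_sex, mu, rng, ped.max_id + 1, gen
        )
        ped.append_cohort(pop.ids, sire_ids, dam_ids, pop.sexes, gen)
    return pop, ped
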