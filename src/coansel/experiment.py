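"""The selection experiment: truncation BLUP selection under a chosen matrix.

One replicate runs: QTL and founder draws from the shared base population,
recorded random-mating generations, then truncation selection in which each
round (i) estimates variance components by MCEM REML under the selection
matrix, (ii) solves the mixed-model equations for all recorded individuals,
(iii) selects the top fraction of each sex of the current cohort by EBV and
(iv) mates the selected parents at random to produce N sires and N dams.

Every generation the mean TBV, heterozygosity, and all four coancestry and
inbreeding summaries of the current cohort are recorded regardless of which
matrix drives selection (the cross-performance design). Coancestry
trajectories are additionally expressed as log((1 - f)/(1 - f_base)) with the
baseline taken at the last pre-selection generation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .base_population import evolve_base, gametes_from_parents, init_base
from .errors import InvalidArgumentError, InvalidStateError
from .genome import FEMALE, MALE, GenomeMap, Population
from .kernels import roh_segment_totals, tabular_relationship
from .pedigree import Pedigree
from .relationships import (
    MATRIX_KINDS,
    RelationshipMatrix,
    _chromosome_bounds,
    ibs_G,
    roh_R,
    vanraden_from_haplotypes,
)
from .replicates import MarkerPanel, draw_founders, marker_panel, sample_qtls
from .reml import mcem_reml
from .blup import solve_mme
from .traits import (
    TraitArchitecture,
    calibrate_variances,
    compute_tbv,
    draw_effects,
    simulate_phenotypes,
)

logger = logging.getLogger("coansel")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (defaults are the full-scale study design)."""

    N: int = 50  # sires per generation (= dams)
    h2: float = 0.25
    markers_per_chromosome: int = 10100
    selection_matrix: str = "A"
    select_fraction: float = 0.5
    n_random_generations: int = 6
    n_selection_generations: int = 15
    n_qtl: int = 1000
    qtl_freq_lo: float = 0.05
    qtl_freq_hi: float = 0.95
    trait_mean: float = 100.0
    mutation_rate: float = 2.5e-3
    mutate_during_breeding: bool = True
    roh_min_run: int = 100
    reml_n_iter: int = 6000
    reml_burnin: int = 1000
    use_true_variances: bool = False
    mme_records_window: int | None = None  # None = all recorded generations
    n_chromosomes: int = 10
    loci_per_chromosome: int = 10100
    chromosome_length: float = 1.0
    base_size: int = 1000
    base_generations: int = 10000
    seed: int = 0
    label: str = ""

    def validate(self) -> None:
        checks = [
            (self.N >= 1, "N must be >= 1"),
            (0.0 < self.h2 < 1.0, "h2 must be in (0, 1)"),
            (0.0 < self.select_fraction <= 1.0, "select_fraction in (0, 1]"),
            (self.selection_matrix in MATRIX_KINDS, "selection_matrix in A/G/R/V"),
            (self.n_random_generations >= 0, "n_random_generations >= 0"),
            (self.n_selection_generations >= 0, "n_selection_generations >= 0"),
            (self.n_qtl >= 1, "n_qtl >= 1"),
            (0.0 <= self.qtl_freq_lo < self.qtl_freq_hi <= 1.0, "QTL freq bounds"),
            (0.0 <= self.mutation_rate <= 1.0, "mutation_rate in [0, 1]"),
            (self.roh_min_run >= 1, "roh_min_run >= 1"),
            (0 <= self.reml_burnin < self.reml_n_iter, "REML burnin < n_iter"),
            (self.base_size >= 2 and self.base_size % 2 == 0, "base_size even"),
            (
                self.mme_records_window is None or self.mme_records_window >= 1,
                "mme_records_window >= 1 or null",
            ),
            (self.base_generations >= 0, "base_generations >= 0"),
            (self.markers_per_chromosome >= 1, "markers_per_chromosome >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidArgumentError(msg)

    def genome_map(self) -> GenomeMap:
        return GenomeMap(
            self.n_chromosomes, self.loci_per_chromosome, self.chromosome_length
        )

    @property
    def scenario_label(self) -> str:
        if self.label:
            return self.label
        return (
            f"N{self.N}_h{self.h2:g}_m{self.markers_per_chromosome}"
            f"_{self.selection_matrix}"
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def build_base_population(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> Population:
    """Initialise and burn in the shared base population for a scenario set."""
    pop = init_base(cfg.genome_map(), cfg.base_size, rng)
    return evolve_base(pop, cfg.base_generations, cfg.mutation_rate, rng)


def truncation_select(
    ebv: np.ndarray,
    sexes: np.ndarray,
    fraction: float = 0.5,
    ids: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the top ``fraction`` of each sex by EBV (ties by lower id)."""
    ebv = np.asarray(ebv, dtype=np.float64)
    sexes = np.asarray(sexes)
    if not 0.0 < fraction <= 1.0:
        raise InvalidArgumentError("fraction must be in (0, 1]")
    if ids is None:
        ids = np.arange(ebv.size)
    ids = np.asarray(ids)
    picked = []
    for sex in (MALE, FEMALE):
        members = np.flatnonzero(sexes == sex)
        if members.size == 0:
            raise InvalidStateError("a candidate sex class is empty")
        k = int(np.floor(fraction * members.size))
        if k < 1:
            raise InvalidStateError(
                f"fraction {fraction} selects nobody from {members.size}"
            )
        order = np.lexsort((ids[members], -ebv[members]))
        picked.append(members[order[:k]])
    return np.concatenate(picked)


def log_ratio_metric(f_t: float, f_base: float) -> float:
    """log((1 - f_t) / (1 - f_base)); more negative = faster coancestry gain."""
    if f_t >= 1.0 or f_base >= 1.0:
        raise InvalidArgumentError("log ratio undefined for f >= 1")
    return float(np.log((1.0 - f_t) / (1.0 - f_base)))


def mate_selected(
    parents: Population,
    sire_ids: np.ndarray,
    dam_ids: np.ndarray,
    n_per_sex: int,
    mu: float,
    rng: np.random.Generator,
    pedigree: Pedigree,
) -> tuple[Population, Pedigree]:
    """Random mating among selected parents producing N sires and N dams."""
    if len(sire_ids) == 0 or len(dam_ids) == 0:
        raise InvalidStateError("need selected parents of both sexes")
    id_to_row = {int(i): r for r, i in enumerate(parents.ids)}
    sire_rows = np.array([id_to_row[int(i)] for i in sire_ids])
    dam_rows = np.array([id_to_row[int(i)] for i in dam_ids])
    n = 2 * n_per_sex
    chosen_s = rng.choice(sire_rows, size=n, replace=True)
    chosen_d = rng.choice(dam_rows, size=n, replace=True)
    haps = gametes_from_parents(
        parents.haplotypes, parents.gmap, chosen_s, chosen_d, mu, rng
    )
    sexes = np.concatenate(
        [np.full(n_per_sex, MALE, np.uint8), np.full(n_per_sex, FEMALE, np.uint8)]
    )
    gen = int(parents.generations.max()) + 1
    ids = np.arange(pedigree.max_id + 1, pedigree.max_id + 1 + n, dtype=np.int64)
    off = Population(parents.gmap, haps, sexes, np.full(n, gen, np.int32), ids)
    pedigree.append_cohort(
        ids, parents.ids[chosen_s], parents.ids[chosen_d], sexes, gen
    )
    return off, pedigree


class _ReplicateRecords:
    """All individuals recorded so far in one replicate (haplotypes,
    pedigree links as row indices, phenotypes, TBVs)."""

    def __init__(self, gmap: GenomeMap, panel: MarkerPanel, arch: TraitArchitecture):
        self.gmap = gmap
        self.panel = panel
        self.arch = arch
        self.hap = np.empty((0, 2, gmap.n_loci), dtype=np.uint8)
        self.sire_idx = np.empty(0, dtype=np.int64)
        self.dam_idx = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.uint8)
        self.gen = np.empty(0, dtype=np.int64)
        self.tbv = np.empty(0)
        self.phen = np.empty(0)

    @property
    def n(self) -> int:
        return self.hap.shape[0]

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n + 1, dtype=np.int64)

    def add_cohort(
        self,
        haps: np.ndarray,
        sire_idx: np.ndarray,
        dam_idx: np.ndarray,
        sexes: np.ndarray,
        generation: int,
        rng: np.random.Generator,
    ) -> None:
        x = haps[:, :, self.arch.qtl_indices].sum(axis=1, dtype=np.int64)
        tbv = compute_tbv(x, self.arch.effects)
        phen = simulate_phenotypes(tbv, self.arch, rng)
        self.hap = np.concatenate([self.hap, haps])
        self.sire_idx = np.concatenate([self.sire_idx, sire_idx])
        self.dam_idx = np.concatenate([self.dam_idx, dam_idx])
        self.sex = np.concatenate([self.sex, np.asarray(sexes, np.uint8)])
        self.gen = np.concatenate(
            [self.gen, np.full(haps.shape[0], generation, np.int64)]
        )
        self.tbv = np.concatenate([self.tbv, tbv])
        self.phen = np.concatenate([self.phen, phen])

    def cohort_rows(self, generation: int) -> np.ndarray:
        return np.flatnonzero(self.gen == generation)

    def panel_haplotypes(self, rows: np.ndarray | None = None) -> np.ndarray:
        h = self.hap if rows is None else self.hap[rows]
        return np.ascontiguousarray(h[:, :, self.panel.indices])

    def pedigree(self) -> Pedigree:
        ids = self.ids
        sire = np.where(self.sire_idx >= 0, self.sire_idx + 1, 0)
        dam = np.where(self.dam_idx >= 0, self.dam_idx + 1, 0)
        return Pedigree(ids, sire, dam, self.sex, self.gen)

    def full_A(self) -> np.ndarray:
        return tabular_relationship(self.sire_idx, self.dam_idx)


class _RohTracker:
    """Incrementally grown ROH relationship over all recorded individuals."""

    def __init__(self, panel: MarkerPanel, min_run: int):
        self.starts, self.ends = _chromosome_bounds(panel.marker_chromosomes)
        self.min_run = min_run
        self.m = panel.n_markers
        self.values = np.empty((0, 0))

    def update(self, records: _ReplicateRecords) -> np.ndarray:
        n0 = self.values.shape[0]
        n1 = records.n
        if n1 == n0:
            return self.values
        hap_all = records.panel_haplotypes()
        block = roh_segment_totals(
            hap_all[n0:], hap_all, self.starts, self.ends, self.min_run
        ) / (2.0 * self.m)
        grown = np.empty((n1, n1))
        grown[:n0, :n0] = self.values
        grown[n0:, :] = block
        grown[:n0, n0:] = block[:, :n0].T
        self.values = grown
        return self.values


def _selection_matrix(
    records: _ReplicateRecords, kind: str, min_run: int, roh_tracker: _RohTracker
) -> RelationshipMatrix:
    if kind == "A":
        return RelationshipMatrix("A", records.full_A(), records.ids)
    if kind == "G":
        return ibs_G(records.panel_haplotypes(), records.ids)
    if kind == "V":
        return vanraden_from_haplotypes(records.panel_haplotypes(), records.ids)
    if kind == "R":
        return RelationshipMatrix("R", roh_tracker.update(records), records.ids)
    raise InvalidArgumentError(f"unknown matrix kind {kind!r}")


def _cohort_metrics(
    records: _ReplicateRecords,
    generation: int,
    full_a: np.ndarray,
    min_run: int,
) -> dict:
    rows = records.cohort_rows(generation)
    hp = records.panel_haplotypes(rows)
    mats = {
        "A": RelationshipMatrix("A", full_a[np.ix_(rows, rows)], rows),
        "G": ibs_G(hp),
        "R": roh_R(hp, records.panel.marker_chromosomes, min_run),
        "V": vanraden_from_haplotypes(hp),
    }
    h = records.hap[rows]
    out = {
        "generation": generation,
        "n_candidates": rows.size,
        "mean_tbv": float(records.tbv[rows].mean()),
        "mean_phenotype": float(records.phen[rows].mean()),
        "heterozygosity": float(np.mean(h[:, 0, :] != h[:, 1, :])),
    }
    for kind, mat in mats.items():
        out[f"mean_f_{kind}"] = mat.mean_pairwise_coancestry()
        out[f"mean_F_{kind}"] = float(mat.inbreeding().mean())
    return out


def run_replicate(
    cfg: ScenarioConfig,
    base: Population,
    replicate_index: int = 0,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Run one replicate; returns per-generation metrics.

    Replicate ``r`` uses seed ``(base_seed + r) mod 2^31`` so scenarios that
    differ only in the selection matrix share QTL/founder draws and the whole
    pre-selection phase (paired comparisons).
    """
    cfg.validate()
    seed = cfg.seed if base_seed is None else base_seed
    rng = np.random.default_rng((int(seed) + int(replicate_index)) % 2**31)
    gmap = base.gmap
    panel = marker_panel(gmap, cfg.markers_per_chromosome)
    mu = cfg.mutation_rate if cfg.mutate_during_breeding else 0.0

    qtl = sample_qtls(base, cfg.n_qtl, cfg.qtl_freq_lo, cfg.qtl_freq_hi, rng)
    effects = draw_effects(cfg.n_qtl, rng)
    base_tbv = compute_tbv(base.genotype_counts(qtl), effects)
    sigma2_a, sigma2_e = calibrate_variances(base_tbv, cfg.h2)
    arch = TraitArchitecture(
        qtl, effects, cfg.trait_mean, sigma2_a, sigma2_e, cfg.h2
    )

    founders, _ = draw_founders(base, cfg.N, rng)
    records = _ReplicateRecords(gmap, panel, arch)
    n_cohort = 2 * cfg.N
    unknown = np.full(n_cohort, -1, dtype=np.int64)
    records.add_cohort(founders.haplotypes, unknown, unknown, founders.sexes, 0, rng)
    roh_tracker = _RohTracker(panel, cfg.roh_min_run)

    rows_out: list[dict] = []

    def record_metrics(gen: int, extra: dict | None = None) -> None:
        full_a = records.full_A()
        row = _cohort_metrics(records, gen, full_a, cfg.roh_min_run)
        row.update(extra or {})
        rows_out.append(row)

    record_metrics(0)

    # recorded random mating
    for gen in range(1, cfg.n_random_generations + 1):
        parent_rows = records.cohort_rows(gen - 1)
        males = parent_rows[records.sex[parent_rows] == MALE]
        females = parent_rows[records.sex[parent_rows] == FEMALE]
        sires = rng.choice(males, size=n_cohort, replace=True)
        dams = rng.choice(females, size=n_cohort, replace=True)
        haps = gametes_from_parents(records.hap, gmap, sires, dams, mu, rng)
        sexes = np.concatenate(
            [np.full(cfg.N, MALE, np.uint8), np.full(cfg.N, FEMALE, np.uint8)]
        )
        records.add_cohort(haps, sires, dams, sexes, gen, rng)
        record_metrics(gen)

    # truncation selection
    for step in range(cfg.n_selection_generations):
        gen = cfg.n_random_generations + 1 + step
        K = _selection_matrix(
            records, cfg.selection_matrix, cfg.roh_min_run, roh_tracker
        )
        if cfg.mme_records_window is not None:
            rows = np.flatnonzero(
                records.gen > (gen - 1) - cfg.mme_records_window
            )
            K = K.submatrix(rows)
        else:
            rows = np.arange(records.n)
        y = records.phen[rows]
        if cfg.use_true_variances:
            s2a_hat, s2e_hat = arch.sigma2_a, arch.sigma2_e
        else:
            est = mcem_reml(y, K, cfg.reml_n_iter, cfg.reml_burnin, rng)
            s2a_hat, s2e_hat = est.sigma2_a, est.sigma2_e
        sol = solve_mme(y, K, s2a_hat, s2e_hat)

        cand = records.cohort_rows(gen - 1)
        cand_pos = np.searchsorted(rows, cand)
        sel_local = truncation_select(
            sol.ebv[cand_pos],
            records.sex[cand],
            cfg.select_fraction,
            records.ids[cand],
        )
        sel = cand[sel_local]
        sel_males = sel[records.sex[sel] == MALE]
        sel_females = sel[records.sex[sel] == FEMALE]
        sires = rng.choice(sel_males, size=n_cohort, replace=True)
        dams = rng.choice(sel_females, size=n_cohort, replace=True)
        haps = gametes_from_parents(records.hap, gmap, sires, dams, mu, rng)
        sexes = np.concatenate(
            [np.full(cfg.N, MALE, np.uint8), np.full(cfg.N, FEMALE, np.uint8)]
        )
        records.add_cohort(haps, sires, dams, sexes, gen, rng)
        record_metrics(
            gen, {"sigma2_a_hat": s2a_hat, "sigma2_e_hat": s2e_hat}
        )
        logger.debug(
            "replicate %d gen %d (%s): mean TBV %.3f",
            replicate_index, gen, cfg.selection_matrix,
            rows_out[-1]["mean_tbv"],
        )

    df = pd.DataFrame(rows_out)
    baseline = df[df["generation"] == cfg.n_random_generations].iloc[0]
    df["delta_tbv"] = df["mean_tbv"] - baseline["mean_tbv"]
    for kind in MATRIX_KINDS:
        df[f"log_ratio_f_{kind}"] = np.log(
            (1.0 - df[f"mean_f_{kind}"]) / (1.0 - baseline[f"mean_f_{kind}"])
        )
    df.insert(0, "selection_matrix", cfg.selection_matrix)
    df.insert(0, "replicate", replicate_index)
    df.insert(0, "scenario", cfg.scenario_label)
    return df


def run_scenario_grid(
    configs: list[ScenarioConfig],
    n_replicates: int,
    seed: int,
    base: Population | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every scenario for ``n_replicates`` replicates off one shared base.

    Returns (per-replicate metrics, per-scenario/generation aggregates with
    replicate means, SDs and standard errors).
    """
    if not configs:
        raise InvalidArgumentError("need at least one scenario")
    if base is None:
        first = configs[0]
        for cfg in configs[1:]:
            same = (
                cfg.n_chromosomes == first.n_chromosomes
                and cfg.loci_per_chromosome == first.loci_per_chromosome
                and cfg.chromosome_length == first.chromosome_length
                and cfg.base_size == first.base_size
                and cfg.base_generations == first.base_generations
            )
            if not same:
                raise InvalidArgumentError(
                    "scenarios sharing a base must share genome/base parameters"
                )
        logger.info("building shared base population")
        base = build_base_population(first, np.random.default_rng(seed % 2**31))
    parts = []
    for cfg in configs:
        for r in range(n_replicates):
            logger.info("scenario %s replicate %d", cfg.scenario_label, r)
            parts.append(run_replicate(cfg, base, r, base_seed=seed))
    per_rep = pd.concat(parts, ignore_index=True)
    value_cols = [
        c
        for c in per_rep.columns
        if c not in ("scenario", "replicate", "selection_matrix", "generation")
        and np.issubdtype(per_rep[c].dtype, np.number)
    ]
    agg = per_rep.groupby(["scenario", "generation"])[value_cols].agg(
        ["mean", "std", "sem"]
    )
    suffix = {"mean": "mean", "std": "sd", "sem": "se"}
    agg.columns = [f"{col}_{suffix[stat]}" for col, stat in agg.columns]
    agg = agg.reset_index()
    return per_rep, agg
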