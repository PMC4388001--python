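"""The four relationship matrices: pedigree A, IBS G, ROH-segment R, VanRaden V.

All matrices are stored on the *relationship* scale, i.e. twice the
coancestry coefficient, so the pedigree matrix has the familiar diagonal
1 + F. Coancestries are recovered by halving.

* A — expected identity by descent from the pedigree (tabular recursion).
* G — identity by state: for a pair of individuals, the mean over markers of
  the number of matching ordered gamete pairs (out of 4), f_G = (1/4M) sum.
* R — shared segments: runs of contiguous identical markers between gamete
  pairs; runs of at least ``min_run`` markers contribute their length, and
  f_R = total length / (4L) with both lengths counted in markers.
* V — allele-frequency-centred cross-product with all reference frequencies
  fixed at 0.5: f_V = (1/M) sum (g_i - 0.5)(g_k - 0.5) / 0.25 with g the
  gene-frequency code (copies of allele 1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidArgumentError
from .kernels import roh_segment_totals, tabular_relationship
from .pedigree import Pedigree

MatrixKind = Literal["A", "G", "R", "V"]

MATRIX_KINDS: tuple[str, ...] = ("A", "G", "R", "V")


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix (2 x coancestry) tagged by kind."""

    kind: str
    values: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.kind not in MATRIX_KINDS:
            raise InvalidArgumentError(f"unknown matrix kind {self.kind!r}")
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.ids.shape != (n,):
            raise InvalidArgumentError("values must be square with one id per row")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def coancestry(self) -> np.ndarray:
        return self.values / 2.0

    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficient, F_i = K_ii - 1.

        On the relationship scale this is the classical 1 + F diagonal for A,
        the homozygosity fraction for G, the own-gamete ROH fraction for R
        and the VanRaden diagonal excess for V.
        """
        return np.diag(self.values) - 1.0

    def mean_pairwise_coancestry(self) -> float:
        if self.n < 2:
            raise InvalidArgumentError("need >=2 individuals for pairwise mean")
        iu = np.triu_indices(self.n, k=1)
        return float(self.values[iu].mean() / 2.0)

    def submatrix(self, rows: np.ndarray) -> "RelationshipMatrix":
        rows = np.asarray(rows)
        return RelationshipMatrix(
            self.kind, self.values[np.ix_(rows, rows)], self.ids[rows]
        )


def pedigree_A(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method.

    a_ii = 1 + a_sd/2 for parents (s, d); a_ij = (a_js + a_jd)/2 for older j;
    founders are non-inbred and mutually unrelated.
    """
    sire_idx, dam_idx = ped.parent_indices()
    values = tabular_relationship(sire_idx, dam_idx)
    return RelationshipMatrix("A", values, ped.ids)


def _check_haplotypes(haplotypes: np.ndarray) -> np.ndarray:
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    if haplotypes.ndim != 3 or haplotypes.shape[1] != 2:
        raise InvalidArgumentError("haplotypes must have shape (n, 2, M)")
    if haplotypes.shape[2] < 1:
        raise InvalidArgumentError("need at least one marker")
    return haplotypes


def ibs_G(
    haplotypes: np.ndarray, ids: np.ndarray | None = None
) -> RelationshipMatrix:
    """Identity-by-state relationship from marker haplotypes.

    Closed form over genotype counts x in {0,1,2}: the number of matching
    ordered gamete pairs at one marker is x_i x_k + (2-x_i)(2-x_k), hence
    2 f_G = (X X' + (2-X)(2-X)') / (2M).
    """
    haplotypes = _check_haplotypes(haplotypes)
    n, _, m = haplotypes.shape
    x = haplotypes.sum(axis=1).astype(np.float64)
    values = (x @ x.T + (2.0 - x) @ (2.0 - x).T) / (2.0 * m)
    if ids is None:
        ids = np.arange(n)
    return RelationshipMatrix("G", values, ids)


def _chromosome_bounds(marker_chromosomes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    chrom = np.asarray(marker_chromosomes)
    if chrom.size and np.any(np.diff(chrom) < 0):
        raise InvalidArgumentError("markers must be ordered by chromosome")
    change = np.flatnonzero(np.diff(chrom) != 0) + 1
    starts = np.concatenate([[0], change]).astype(np.int64)
    ends = np.concatenate([change, [chrom.size]]).astype(np.int64)
    return starts, ends


def roh_R(
    haplotypes: np.ndarray,
    marker_chromosomes: np.ndarray,
    min_run: int = 100,
    ids: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Shared-segment (ROH) relationship from marker haplotypes.

    ``marker_chromosomes`` gives the chromosome of each marker column (runs
    never span chromosome boundaries). Lengths are counted in markers, with
    the genome length L equal to the total marker count, so the ``min_run``
    threshold and the length metric share units at every panel density.
    """
    haplotypes = _check_haplotypes(haplotypes)
    if min_run < 1:
        raise InvalidArgumentError("min_run must be >= 1")
    n, _, m = haplotypes.shape
    if len(marker_chromosomes) != m:
        raise InvalidArgumentError("one chromosome label per marker required")
    starts, ends = _chromosome_bounds(marker_chromosomes)
    totals = roh_segment_totals(haplotypes, haplotypes, starts, ends, min_run)
    values = totals / (2.0 * m)
    if ids is None:
        ids = np.arange(n)
    return RelationshipMatrix("R", values, ids)


def vanraden_V(
    gene_frequencies: np.ndarray,
    p: float = 0.5,
    ids: np.ndarray | None = None,
) -> RelationshipMatrix:
    """VanRaden relationship from gene-frequency codes g in {0, 0.5, 1}.

    f_V(i,k) = (1/M) sum_n (g_in - p)(g_kn - p) / (p(1-p)) with the reference
    frequency p fixed (0.5 by default). Entries may be negative.
    """
    g = np.asarray(gene_frequencies, dtype=np.float64)
    if g.ndim != 2 or g.shape[1] < 1:
        raise InvalidArgumentError("gene frequencies must be (n, M) with M >= 1")
    if not np.all(np.isin(g, (0.0, 0.5, 1.0))):
        raise InvalidArgumentError("gene-frequency codes must be in {0, 0.5, 1}")
    if not 0.0 < p < 1.0:
        raise InvalidArgumentError("p must be in (0, 1)")
    n, m = g.shape
    centred = g - p
    values = 2.0 * (centred @ centred.T) / (m * p * (1.0 - p))
    if ids is None:
        ids = np.arange(n)
    return RelationshipMatrix("V", values, ids)


def vanraden_from_haplotypes(
    haplotypes: np.ndarray, ids: np.ndarray | None = None
) -> RelationshipMatrix:
    """Convenience wrapper: g = (copies of allele 1) / 2."""
    haplotypes = _check_haplotypes(haplotypes)
    g = haplotypes.sum(axis=1, dtype=np.float64) / 2.0
    return vanraden_V(g, ids=ids)


@dataclass
class CoancestrySummary:
    """Summary of one relationship matrix on the coancestry scale."""

    kind: str
    mean_coancestry: float
    mean_inbreeding: float
    var_coancestry: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def coancestry_summary(
    matrix: RelationshipMatrix, bins: int = 30
) -> CoancestrySummary:
    """Pairwise coancestry mean/variance/histogram and mean inbreeding.

    The histogram and variance are over the off-diagonal coancestries
    (sample variance, ddof=1); inbreeding comes from the diagonal.
    """
    if matrix.n < 2:
        raise InvalidArgumentError("need >=2 individuals to summarise")
    iu = np.triu_indices(matrix.n, k=1)
    f = matrix.values[iu] / 2.0
    counts, edges = np.histogram(f, bins=bins)
    return CoancestrySummary(
        kind=matrix.kind,
        mean_coancestry=float(f.mean()),
        mean_inbreeding=float(matrix.inbreeding().mean()),
        var_coancestry=float(f.var(ddof=1)) if f.size > 1 else 0.0,
        hist_counts=counts,
        hist_edges=edges,
    )
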