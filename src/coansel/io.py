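"""Text-format import/export: genotype TSV, PLINK-like .ped/.map, matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .genome import GenomeMap, Population
from .relationships import RelationshipMatrix


def write_genotypes_tsv(pop: Population, path: str | Path) -> None:
    """One row per individual: id, sex, then two allele columns per locus."""
    n_loci = pop.gmap.n_loci
    cols = {"id": pop.ids, "sex": pop.sexes}
    data = np.empty((pop.n_individuals, 2 * n_loci), dtype=np.uint8)
    data[:, 0::2] = pop.haplotypes[:, 0, :]
    data[:, 1::2] = pop.haplotypes[:, 1, :]
    allele_cols = pd.DataFrame(
        data,
        columns=[f"l{j}_{a}" for j in range(n_loci) for a in (1, 2)],
    )
    pd.concat([pd.DataFrame(cols), allele_cols], axis=1).to_csv(
        path, sep="\t", index=False
    )


def write_plink(pop: Population, prefix: str | Path) -> None:
    """PLINK-like .ped/.map export.

    .map columns: chromosome (1-based), locus id, genetic position in cM,
    base-pair column set to the locus index. .ped columns: family (always 1),
    id, sire 0, dam 0, sex (1=male, 2=female), phenotype 0, then two alleles
    per locus coded 1/2.
    """
    prefix = Path(prefix)
    gmap = pop.gmap
    chroms = gmap.locus_chromosomes() + 1
    cm = gmap.locus_positions() * 100.0
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(gmap.n_loci):
            fh.write(f"{chroms[j]}\tl{j}\t{cm[j]:.6f}\t{j}\n")
    alleles = pop.haplotypes + 1  # 0/1 -> 1/2
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(pop.n_individuals):
            lead = f"1\t{pop.ids[i]}\t0\t0\t{int(pop.sexes[i]) + 1}\t0"
            pair = np.empty(2 * gmap.n_loci, dtype=np.uint8)
            pair[0::2] = alleles[i, 0]
            pair[1::2] = alleles[i, 1]
            fh.write(lead + "\t" + "\t".join(map(str, pair)) + "\n")


def read_plink(prefix: str | Path) -> Population:
    """Read a .ped/.map pair written by :func:`write_plink`."""
    prefix = Path(prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"),
        sep="\t",
        header=None,
        names=["chrom", "locus", "cm", "bp"],
    )
    n_chrom = int(mp["chrom"].max())
    loci_per = len(mp) // n_chrom
    if loci_per * n_chrom != len(mp):
        raise InvalidArgumentError("chromosomes must have equal locus counts")
    spacing_cm = mp["cm"].iloc[1] - mp["cm"].iloc[0] if loci_per > 1 else 1.0
    gmap = GenomeMap(n_chrom, loci_per, loci_per * spacing_cm / 100.0)
    ped = pd.read_csv(prefix.with_suffix(".ped"), sep="\t", header=None)
    ids = ped.iloc[:, 1].to_numpy(np.int64)
    sexes = ped.iloc[:, 4].to_numpy(np.int64) - 1
    alleles = ped.iloc[:, 6:].to_numpy(np.uint8) - 1
    haps = np.empty((len(ped), 2, len(mp)), dtype=np.uint8)
    haps[:, 0, :] = alleles[:, 0::2]
    haps[:, 1, :] = alleles[:, 1::2]
    return Population(gmap, haps, sexes.astype(np.uint8), ids=ids)


def write_matrix_tsv(mat: RelationshipMatrix, path: str | Path) -> None:
    """Square TSV with an id header; the kind goes in a leading comment."""
    with open(path, "w") as fh:
        fh.write(f"# kind={mat.kind}\n")
        fh.write("id\t" + "\t".join(map(str, mat.ids)) + "\n")
        for i in range(mat.n):
            fh.write(
                f"{mat.ids[i]}\t"
                + "\t".join(f"{v:.8g}" for v in mat.values[i])
                + "\n"
            )


def write_matrix_long_tsv(mat: RelationshipMatrix, path: str | Path) -> None:
    """Long-format (id_i, id_k, value) TSV of the upper triangle."""
    iu = np.triu_indices(mat.n)
    pd.DataFrame(
        {
            "id_i": mat.ids[iu[0]],
            "id_k": mat.ids[iu[1]],
            "kind": mat.kind,
            "value": mat.values[iu],
        }
    ).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> RelationshipMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("# kind="):
        raise InvalidArgumentError("missing '# kind=' metadata line")
    kind = header.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", skiprows=1, index_col=0)
    return RelationshipMatrix(
        kind, df.to_numpy(float), df.index.to_numpy(np.int64)
    )
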