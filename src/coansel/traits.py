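"""Quantitative-trait machinery: additive QTL model, TBVs and phenotypes.

The trait is purely additive over n_S selective loci (QTLs):

    TBV_i = sum_j a_j (x_ij - 1),        y_i = mu + TBV_i + e_i,

with x_ij the number of copies of allele 1 at QTL j, allele effects a_j
drawn i.i.d. standard normal, and e_i ~ N(0, sigma2_e). The additive
variance sigma2_a is the empirical variance of the TBVs in the base
population; sigma2_e is then set so that sigma2_a/(sigma2_a + sigma2_e)
equals the target heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class TraitArchitecture:
    qtl_indices: np.ndarray
    effects: np.ndarray
    mean: float
    sigma2_a: float
    sigma2_e: float
    h2: float

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.effects = np.asarray(self.effects, dtype=np.float64)
        if self.qtl_indices.shape != self.effects.shape:
            raise InvalidArgumentError("one effect per QTL required")
        if self.sigma2_a <= 0 or self.sigma2_e < 0:
            raise InvalidArgumentError("sigma2_a must be > 0 and sigma2_e >= 0")
        implied = self.sigma2_a / (self.sigma2_a + self.sigma2_e)
        if abs(implied - self.h2) > 1e-8:
            raise InvalidArgumentError(
                f"variances imply h2={implied:.6f}, declared {self.h2}"
            )


def draw_effects(n_qtl: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. standard-normal allele effects."""
    if n_qtl < 1:
        raise InvalidArgumentError("n_qtl must be >= 1")
    return rng.standard_normal(n_qtl)


def compute_tbv(genotype_counts: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """TBV_i = sum_j a_j (x_ij - 1) for x in {0, 1, 2}."""
    x = np.asarray(genotype_counts)
    effects = np.asarray(effects, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != effects.size:
        raise InvalidArgumentError(
            f"genotype counts {x.shape} do not match {effects.size} effects"
        )
    if x.size and (x.min() < 0 or x.max() > 2):
        raise InvalidArgumentError("genotype counts must be in {0, 1, 2}")
    return (x.astype(np.float64) - 1.0) @ effects


def calibrate_variances(base_tbvs: np.ndarray, h2: float) -> tuple[float, float]:
    """Empirical base-population additive variance and matching residual.

    sigma2_a is the sample variance (n-1 denominator) of the base TBVs;
    sigma2_e = sigma2_a (1 - h2) / h2.
    """
    tbvs = np.asarray(base_tbvs, dtype=np.float64)
    if tbvs.size < 2:
        raise InvalidArgumentError("need >= 2 TBVs to estimate a variance")
    if not 0.0 < h2 < 1.0:
        raise InvalidArgumentError("h2 must be in (0, 1)")
    sigma2_a = float(tbvs.var(ddof=1))
    sigma2_e = sigma2_a * (1.0 - h2) / h2
    return sigma2_a, sigma2_e


def simulate_phenotypes(
    tbvs: np.ndarray, arch: TraitArchitecture, rng: np.random.Generator
) -> np.ndarray:
    """y_i = mean + TBV_i + e_i with e_i ~ N(0, sigma2_e) i.i.d."""
    tbvs = np.asarray(tbvs, dtype=np.float64)
    noise = rng.normal(0.0, np.sqrt(arch.sigma2_e), size=tbvs.shape)
    return arch.mean + tbvs + noise
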