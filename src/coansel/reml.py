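"""REML variance components by Monte-Carlo EM (stochastic EM with Gibbs draws).

Model: y = Z u + 1 mu + e with u ~ N(0, K sigma2_a), e ~ N(0, I sigma2_e).
Each EM iteration performs one Gibbs sweep sampling (mu, u) from their full
conditionals given the current variances, then updates

    sigma2_a <- u' K^{-1} u / q,        sigma2_e <- e'e / n.

Final estimates are the means of the post-burn-in per-iteration values.

The matrix K is eigendecomposed once per call; sampling and the quadratic
form u'K^{-1}u are evaluated in the eigenbasis, where the full conditional of
u is diagonal for balanced designs (equal record counts per level of u, which
includes the animal model with one record per individual). No per-iteration
refactorisation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, NumericalError
from .relationships import RelationshipMatrix

_EIGENVALUE_FLOOR = 1e-8
_VARIANCE_FLOOR = 1e-8


@dataclass
class VarianceEstimate:
    sigma2_a: float
    sigma2_e: float
    n_iterations: int
    n_burnin: int
    chain_sigma2_a: np.ndarray
    chain_sigma2_e: np.ndarray

    @property
    def mc_se_a(self) -> float:
        kept = self.chain_sigma2_a[self.n_burnin :]
        return float(kept.std(ddof=1) / np.sqrt(kept.size))

    @property
    def mc_se_e(self) -> float:
        kept = self.chain_sigma2_e[self.n_burnin :]
        return float(kept.std(ddof=1) / np.sqrt(kept.size))

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


def mcem_reml(
    y: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    n_iter: int = 6000,
    burnin: int = 1000,
    rng: np.random.Generator | None = None,
    groups: np.ndarray | None = None,
    jitter: float = 1e-6,
) -> VarianceEstimate:
    """Estimate (sigma2_a, sigma2_e) by Monte-Carlo EM REML.

    Parameters
    ----------
    y
        Phenotype records.
    K
        Relationship matrix (q x q) of the random effect levels.
    n_iter, burnin
        Chain length and number of discarded initial iterations.
    groups
        Level index of each record (balanced designs only, i.e. the same
        number of records per level). ``None`` means one record per level in
        order (the animal model).
    jitter
        Ridge added to the diagonal of K before decomposition.
    """
    if rng is None:
        rng = np.random.default_rng()
    if burnin < 0 or burnin >= n_iter:
        raise InvalidArgumentError("need 0 <= burnin < n_iter")
    y = np.asarray(y, dtype=np.float64)
    kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    q = kv.shape[0]
    n = y.size
    if groups is None:
        if n != q:
            raise InvalidArgumentError(f"{n} records for {q} matrix rows")
        m = 1
        ybar = y
        ss_within = 0.0
    else:
        groups = np.asarray(groups)
        counts = np.bincount(groups, minlength=q)
        if counts.min() < 1 or counts.min() != counts.max():
            raise InvalidArgumentError(
                "groups must be balanced (equal records per level)"
            )
        m = int(counts[0])
        sums = np.bincount(groups, weights=y, minlength=q)
        ybar = sums / m
        ss_within = float(np.sum((y - ybar[groups]) ** 2))

    try:
        lam, Q = np.linalg.eigh(kv + jitter * np.eye(q))
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError("eigendecomposition of K failed") from exc
    lam = np.clip(lam, _EIGENVALUE_FLOOR, None)

    ybar_t = Q.T @ ybar  # group means in the eigenbasis
    ones_t = Q.T @ np.ones(q)
    ytot = float(y.sum())

    var_y = float(y.var()) if n > 1 else 1.0
    s2a = max(var_y / 2.0, _VARIANCE_FLOOR)
    s2e = max(var_y / 2.0, _VARIANCE_FLOOR)
    u_t = np.zeros(q)

    chain_a = np.empty(n_iter)
    chain_e = np.empty(n_iter)
    for it in range(n_iter):
        # mu | u: N(mean(y - Zu), s2e / n)
        mu = rng.normal(
            (ytot - m * float(ones_t @ u_t)) / n, np.sqrt(s2e / n)
        )
        # u | mu (eigenbasis, diagonal full conditional)
        d = 1.0 / (m / s2e + 1.0 / (lam * s2a))
        mean_u = d * (m / s2e) * (ybar_t - mu * ones_t)
        u_t = mean_u + np.sqrt(d) * rng.standard_normal(q)
        # M-step from the current sample
        resid_t = ybar_t - mu * ones_t - u_t
        sse = ss_within + m * float(resid_t @ resid_t)
        s2a = max(float(np.mean(u_t**2 / lam)), _VARIANCE_FLOOR)
        s2e = max(sse / n, _VARIANCE_FLOOR)
        chain_a[it] = s2a
        chain_e[it] = s2e

    if not (np.isfinite(chain_a).all() and np.isfinite(chain_e).all()):
        raise NumericalError("MCEM chain diverged (non-finite variances)")
    return VarianceEstimate(
        sigma2_a=float(chain_a[burnin:].mean()),
        sigma2_e=float(chain_e[burnin:].mean()),
        n_iterations=n_iter,
        n_burnin=burnin,
        chain_sigma2_a=chain_a,
        chain_sigma2_e=chain_e,
    )
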