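"""BLUP via Henderson's mixed-model equations.

With X a column of ones (overall mean as the only fixed effect), Z the
identity (one record per individual), and lambda = sigma2_e / sigma2_a:

    [ X'X   X'Z             ] [ mu  ]   [ X'y ]
    [ Z'X   Z'Z + lambda K^-1] [ EBV ] = [ Z'y ]

solved exactly by a dense symmetric factorisation. K may be any of the four
relationship matrices; a small ridge keeps near-singular genomic matrices
invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import InvalidArgumentError, NumericalError
from .relationships import RelationshipMatrix


@dataclass
class MMESolution:
    mu_hat: float
    ebv: np.ndarray
    matrix_kind: str
    lam: float


def solve_mme(
    y: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    sigma2_a: float,
    sigma2_e: float,
    jitter: float = 1e-6,
) -> MMESolution:
    """Solve the mixed-model equations for (mu_hat, EBVs)."""
    y = np.asarray(y, dtype=np.float64)
    if isinstance(K, RelationshipMatrix):
        kind, kv = K.kind, K.values
    else:
        kind, kv = "A", np.asarray(K, dtype=np.float64)
    n = kv.shape[0]
    if y.size != n:
        raise InvalidArgumentError(
            f"{y.size} phenotypes for {n} individuals in K"
        )
    if sigma2_a <= 0 or sigma2_e < 0:
        raise InvalidArgumentError("sigma2_a must be > 0 and sigma2_e >= 0")
    lam = sigma2_e / sigma2_a
    kreg = kv + jitter * np.eye(n)
    try:
        c_factor = scipy.linalg.cho_factor(kreg)
        kinv = scipy.linalg.cho_solve(c_factor, np.eye(n))
    except np.linalg.LinAlgError:
        # segment-based matrices need not be positive semi-definite; invert
        # on the eigenvalue-clipped nearest PD surrogate
        w, q = np.linalg.eigh(kreg)
        if w.max() <= 0:
            raise NumericalError("K has no positive eigenvalues")
        w = np.clip(w, 1e-6, None)
        kinv = (q / w) @ q.T

    lhs = np.empty((n + 1, n + 1))
    lhs[0, 0] = n
    lhs[0, 1:] = 1.0
    lhs[1:, 0] = 1.0
    lhs[1:, 1:] = np.eye(n) + lam * kinv
    rhs = np.concatenate([[y.sum()], y])
    try:
        sol = scipy.linalg.solve(lhs, rhs, assume_a="sym")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise NumericalError("mixed-model equations are singular") from exc
    if not np.isfinite(sol).all():
        raise NumericalError("mixed-model solution is not finite")
    return MMESolution(
        mu_hat=float(sol[0]), ebv=sol[1:], matrix_kind=kind, lam=lam
    )
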