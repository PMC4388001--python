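"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, enumeration, closed
forms) and shares no code with the package's computational paths.
"""

from __future__ import annotations

import numpy as np


def brute_force_fG(hap_i: np.ndarray, hap_k: np.ndarray) -> float:
    """IBS coancestry by direct enumeration of the 4 ordered gamete pairs."""
    m = hap_i.shape[1]
    total = 0
    for n in range(m):
        for a in range(2):
            for b in range(2):
                if hap_i[a, n] == hap_k[b, n]:
                    total += 1
    return total / (4.0 * m)


def brute_force_fV(g_i: np.ndarray, g_k: np.ndarray, p: float = 0.5) -> float:
    """VanRaden coancestry by direct summation of the centred cross-product."""
    m = len(g_i)
    return sum(
        (g_i[n] - p) * (g_k[n] - p) / (p * (1.0 - p)) for n in range(m)
    ) / m


def _runs(seq_equal: list[bool]) -> list[int]:
    """Lengths of maximal runs of True."""
    runs, cur = [], 0
    for v in seq_equal:
        if v:
            cur += 1
        else:
            if cur:
                runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


def brute_force_fR(
    hap_i: np.ndarray,
    hap_k: np.ndarray,
    chromosomes: np.ndarray,
    min_run: int,
) -> float:
    """Shared-segment coancestry by explicit run enumeration per gamete pair."""
    m = hap_i.shape[1]
    total = 0
    for a in range(2):
        for b in range(2):
            for c in np.unique(chromosomes):
                cols = np.flatnonzero(chromosomes == c)
                eq = [bool(hap_i[a, j] == hap_k[b, j]) for j in cols]
                total += sum(r for r in _runs(eq) if r >= min_run)
    return total / (4.0 * m)


def kinship_recursive(ids, sire, dam):
    """Pedigree kinship f by the classical recursion (memoised).

    f(i,i) = (1 + f(s_i, d_i)) / 2; f(i,j) = (f(s_i,j) + f(d_i,j)) / 2 for i
    younger than j. Unknown parents contribute 0. Returns a dict over id
    pairs.
    """
    parents = {int(i): (int(s), int(d)) for i, s, d in zip(ids, sire, dam)}
    order = {int(i): n for n, i in enumerate(ids)}
    cache: dict[tuple[int, int], float] = {}

    def f(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return 0.0
        key = (min(i, j), max(i, j))
        if key in cache:
            return cache[key]
        if i == j:
            s, d = parents[i]
            val = 0.5 * (1.0 + f(s, d))
        else:
            if order[i] < order[j]:
                i, j = j, i  # make i the younger
            s, d = parents[i]
            val = 0.5 * (f(s, j) + f(d, j))
        cache[key] = val
        return val

    return f


def path_counting_relationship(ids, sire, dam) -> np.ndarray:
    """Additive relationship by Wright's path-counting method.

    a_ij = sum over common ancestors A and non-overlapping ancestral path
    pairs of (1/2)^(n_i + n_j) (1 + F_A); a_ii = 1 + F_i with F_i the kinship
    of i's parents (computed by path counting on the ancestors).
    """
    ids = [int(i) for i in ids]
    parents = {int(i): (int(s), int(d)) for i, s, d in zip(ids, sire, dam)}

    def ancestor_paths(i: int):
        """All paths (as id tuples) from i up to each ancestor, incl. i."""
        paths = [(i,)]
        s, d = parents[i]
        for p in (s, d):
            if p != 0:
                paths.extend((i,) + q for q in ancestor_paths(p))
        return paths

    def inbreeding(i: int) -> float:
        s, d = parents[i]
        if s == 0 or d == 0:
            return 0.0
        return 0.5 * relationship(s, d)

    def relationship(i: int, j: int) -> float:
        if i == j:
            return 1.0 + inbreeding(i)
        total = 0.0
        for pi in ancestor_paths(i):
            for pj in ancestor_paths(j):
                if pi[-1] != pj[-1]:
                    continue
                # paths must share only the common ancestor
                if set(pi[:-1]) & set(pj[:-1]):
                    continue
                n_links = (len(pi) - 1) + (len(pj) - 1)
                total += 0.5**n_links * (1.0 + inbreeding(pi[-1]))
        return total

    n = len(ids)
    a = np.empty((n, n))
    for r, i in enumerate(ids):
        for c, j in enumerate(ids):
            a[r, c] = relationship(i, j)
    return a


def gls_blup(y: np.ndarray, K: np.ndarray, s2a: float, s2e: float):
    """Closed-form GLS/BLUP: mu_hat by GLS, u_hat = s2a K Vy^-1 (y - 1 mu)."""
    n = len(y)
    vy = s2a * K + s2e * np.eye(n)
    vinv = np.linalg.inv(vy)
    ones = np.ones(n)
    mu = (ones @ vinv @ y) / (ones @ vinv @ ones)
    u = s2a * K @ vinv @ (y - mu * ones)
    return mu, u


def balanced_oneway_reml(y: np.ndarray, groups: np.ndarray):
    """Closed-form REML for the balanced one-way random-effects layout."""
    q = len(np.unique(groups))
    m = len(y) // q
    means = np.array([y[groups == g].mean() for g in range(q)])
    ss_within = sum((y[groups == g] - means[g]) @ (y[groups == g] - means[g])
                    for g in range(q))
    s2e = ss_within / (len(y) - q)
    ms_between = m * ((means - means.mean()) ** 2).sum() / (q - 1)
    s2a = (ms_between - s2e) / m
    return s2a, s2e
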