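"""Numba kernels for the O(n^2) relationship computations."""

import numpy as np
from numba import njit


@njit(cache=True)
def tabular_relationship(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Additive relationship matrix by the tabular recursion.

    ``sire``/``dam`` are row indices into the same ordering, -1 for unknown;
    parents must precede offspring.
    """
    n = sire.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        s = sire[i]
        d = dam[i]
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * a[j, s]
            if d >= 0:
                v += 0.5 * a[j, d]
            a[i, j] = v
            a[j, i] = v
        if s >= 0 and d >= 0:
            a[i, i] = 1.0 + 0.5 * a[s, d]
        else:
            a[i, i] = 1.0
    return a


@njit(cache=True)
def roh_segment_totals(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    min_run: int,
) -> np.ndarray:
    """Total qualifying shared-segment length between two haplotype sets.

    For every pair (i in ``hap_a``, k in ``hap_b``) and each of the 4 ordered
    gamete pairs, maximal runs of contiguous identical markers are found
    within each chromosome block [starts[c], ends[c]); runs of at least
    ``min_run`` markers contribute their length (in markers). Haplotype
    arrays have shape (n, 2, M) with alleles 0/1.
    """
    na = hap_a.shape[0]
    nb = hap_b.shape[0]
    nc = starts.shape[0]
    out = np.zeros((na, nb))
    for i in range(na):
        for k in range(nb):
            total = 0
            for ga in range(2):
                for gb in range(2):
                    x = hap_a[i, ga]
                    z = hap_b[k, gb]
                    for c in range(nc):
                        run = 0
                        for m in range(starts[c], ends[c]):
                            if x[m] == z[m]:
                                run += 1
                            else:
                                if run >= min_run:
                                    total += run
                                run = 0
                        if run >= min_run:
                            total += run
            out[i, k] = total
    return out
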