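"""Independent brute-force oracles used to verify the package's algorithms.

These are deliberately naive reimplementations (full dynamic programming,
exhaustive enumeration) kept free of any code shared with the package
internals they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sw_affine_score(query: str, ref: str, match=2, mismatch=-3,
                    gap_open=-4, gap_extend=-2) -> int:
    """Plain full-matrix affine-gap local alignment score (Gotoh)."""
    m, n = len(query), len(ref)
    NEG = -10 ** 9
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend,
                          E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend,
                          F[i - 1][j] + gap_extend)
            s = match if qi == ref[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def n50_brute(lengths) -> int:
    """Scan every candidate length for the N50 definition directly."""
    total = sum(lengths)
    best = 0
    for x in sorted(set(lengths)):
        covered = sum(l for l in lengths if l >= x)
        if covered >= total / 2 and x > best:
            best = x
    return best


def diploid_best_config(M: np.ndarray, e: float):
    """Exhaustive diploid configuration search over a reads x sites matrix.

    M entries: 1 alt, 0 ref, -1 missing.  Returns ((v1, v2), best_ll,
    homref_ll) with v1 <= v2 encoding per-site alt alleles in their bits,
    using the 50/50 haplotype mixture likelihood and a parsimony tie-break
    (fewest total alt alleles, then lexicographic order).
    """
    n, S = M.shape
    log_m = math.log(1.0 - e)
    log_x = math.log(e / 3.0)

    def read_ll(row, hap_bits):
        ll = 0.0
        for s in range(S):
            if row[s] < 0:
                continue
            allele = (hap_bits >> s) & 1
            ll += log_m if row[s] == allele else log_x
        return ll

    hap_ll = [[read_ll(M[r], v) for v in range(1 << S)] for r in range(n)]
    best = None
    for v1 in range(1 << S):
        for v2 in range(v1, 1 << S):
            ll = sum(
                np.logaddexp(hap_ll[r][v1], hap_ll[r][v2]) - math.log(2.0)
                for r in range(n)
            )
            weight = bin(v1).count("1") + bin(v2).count("1")
            key = (-ll, weight, v1, v2)
            if best is None or key < best[0]:
                best = (key, (v1, v2), float(ll))
    homref = sum(
        np.logaddexp(hap_ll[r][0], hap_ll[r][0]) - math.log(2.0)
        for r in range(n)
    )
    return best[1], best[2], float(homref)


def mec_brute(matrix: np.ndarray):
    """Minimum error correction by enumerating every phase vector."""
    n, k = matrix.shape
    best_cost = None
    best_phase = None
    for bits in itertools.product((0, 1), repeat=k):
        phase = np.array(bits, dtype=np.int8)
        cost = 0
        for row in matrix:
            obs = row >= 0
            c1 = int(((row != phase) & obs).sum())
            c2 = int(((row != 1 - phase) & obs).sum())
            cost += min(c1, c2)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_phase = phase
    return best_phase, best_cost


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact probability from the hypergeometric pmf."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def pmf(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = pmf(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))
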