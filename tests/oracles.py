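"""Independent straight-from-formula oracle implementations.

Everything here is written naively — explicit enumeration of haplotype
pairs, literal sums for the constants, per-site loops — and deliberately
shares no code with the package, so agreement is evidence of correctness
rather than of shared bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def haploidize(geno_column_major: np.ndarray) -> np.ndarray:
    """Dosage matrix (sites x samples) -> haplotype matrix (sites x 2N).

    Dosage 0 -> (0,0), 1 -> (0,1), 2 -> (1,1); missing (-1) -> (-1,-1).
    """
    m, n = geno_column_major.shape
    hap = np.empty((m, 2 * n), dtype=int)
    for j in range(n):
        g = geno_column_major[:, j]
        hap[:, 2 * j] = np.where(g < 0, -1, (g == 2).astype(int))
        hap[:, 2 * j + 1] = np.where(g < 0, -1, (g >= 1).astype(int))
    return hap


def pi_pairwise(hap: np.ndarray, L: float) -> float:
    """Mean pairwise difference per site by explicit pair enumeration,
    pairwise deletion of missing haplotypes per site."""
    m, n = hap.shape
    total = 0.0
    for site in range(m):
        row = hap[site]
        diffs = 0
        pairs = 0
        for a, b in itertools.combinations(range(n), 2):
            if row[a] < 0 or row[b] < 0:
                continue
            pairs += 1
            diffs += int(row[a] != row[b])
        if pairs > 0:
            total += diffs / pairs
    return total / L


def segregating_and_singletons(hap: np.ndarray) -> tuple[int, int]:
    S = eta1 = 0
    for site in range(hap.shape[0]):
        row = hap[site][hap[site] >= 0]
        c = int(row.sum())
        n = len(row)
        if 0 < c < n:
            S += 1
            if min(c, n - c) == 1:
                eta1 += 1
    return S, eta1


def watterson_theta(S: int, n: int, L: float) -> float:
    a1 = sum(1.0 / i for i in range(1, n))
    return S / (a1 * L)


def tajimas_d(S: int, pi_total: float, n: int) -> float:
    """Tajima (1989): D = (pi_total - S/a1) / sqrt(e1 S + e2 S(S-1))."""
    if S == 0:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_dstar(S: int, eta1: int, n: int) -> float:
    """Fu & Li (1993) D*, no outgroup, with the Simonsen et al. corrections."""
    if S == 0:
        return math.nan
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / i**2 for i in range(1, n))
    c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d = (
        c
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * (a + 1 / n) - 3) / (n - 2) - 1 / n)
    )
    v = ((n / (n - 1)) ** 2 * b + a**2 * d - 2 * n * a * (a + 1) / (n - 1) ** 2) / (
        a**2 + b
    )
    u = (n / (n - 1)) * (a - n / (n - 1)) - v
    return ((n / (n - 1)) * S - a * eta1) / math.sqrt(u * S + v * S**2)


def hudson_fst(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Hudson's FST (ratio of sums) by per-site loops."""
    num_sum = den_sum = 0.0
    for site in range(hap_a.shape[0]):
        ra = hap_a[site][hap_a[site] >= 0]
        rb = hap_b[site][hap_b[site] >= 0]
        n1, n2 = len(ra), len(rb)
        if n1 < 2 or n2 < 2:
            continue
        p1 = ra.sum() / n1
        p2 = rb.sum() / n2
        num_sum += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den_sum += p1 * (1 - p2) + p2 * (1 - p1)
    return num_sum / den_sum if den_sum > 0 else math.nan


def ld_from_haplotype_counts(c11: int, c10: int, c01: int, c00: int):
    """r^2 and D' from a fully observed 2x2 haplotype count table."""
    n = c11 + c10 + c01 + c00
    f11 = c11 / n
    pa = (c11 + c10) / n
    pb = (c11 + c01) / n
    d = f11 - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    dmax = min(pa * (1 - pb), (1 - pa) * pb) if d >= 0 else min(pa * pb, (1 - pa) * (1 - pb))
    return r2, d / dmax
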