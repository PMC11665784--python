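"""Independent brute-force oracles, deliberately written as plain scalar loops.

These reimplement each statistic from its definition (enumerating allele
pairs, interval membership, variance components) without touching the
vectorized library code paths they validate.
"""

from __future__ import annotations

import numpy as np


def pi_bruteforce(gt_rows):
    """π over a set of sites: enumerate every pair of called allele copies."""
    total_diffs = 0
    total_pairs = 0
    for row in gt_rows:
        alleles = []
        for g in row:
            if g < 0:
                continue
            alleles += {0: [0, 0], 1: [0, 1], 2: [1, 1]}[int(g)]
        n = len(alleles)
        if n < 2:
            continue
        for i in range(n):
            for j in range(i + 1, n):
                total_diffs += alleles[i] != alleles[j]
        total_pairs += n * (n - 1) // 2
    return total_diffs / total_pairs if total_pairs else float("nan")


def wc_fst_single_site(genos_a, genos_b):
    """Weir & Cockerham 1984 theta-hat for one biallelic site, two populations.

    Written from the published variance components a, b, c with explicit
    per-population sums (r = 2 populations, no inbreeding correction).
    """
    pops = [list(genos_a), list(genos_b)]
    r = 2
    n = [len(p) for p in pops]
    p_freq = [sum(g for g in pop) / (2 * len(pop)) for pop in pops]
    h_freq = [sum(1 for g in pop if g == 1) / len(pop) for pop in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p_freq)) / (r * nbar)
    if pbar in (0.0, 1.0):
        return float("nan")
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p_freq)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h_freq)) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


def sfs_tally(dosage_rows, n_alleles):
    """Unfolded SFS by per-site counting; returns (sfs, fixed_ref, fixed_derived)."""
    sfs = np.zeros(n_alleles - 1, dtype=int)
    fixed_ref = fixed_derived = 0
    for row in dosage_rows:
        k = sum(int(d) for d in row if d >= 0)
        called = 2 * sum(1 for d in row if d >= 0)
        if called == 0:
            continue
        if k == 0:
            fixed_ref += 1
        elif k == called:
            fixed_derived += 1
        else:
            sfs[k - 1] += 1
    return sfs, fixed_ref, fixed_derived


def point_in_intervals(contig, pos, intervals):
    """Membership of a 1-based position in half-open (contig, start, end) triples."""
    for c, start, end in intervals:
        if c == contig and start <= pos - 1 < end:
            return True
    return False
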