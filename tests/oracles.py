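"""Independent reference implementations used only to check the package.

Each oracle is transcribed directly from the primary literature or from
first principles (enumeration), deliberately sharing no code with
sweepscan.
"""

import itertools
import math

import numpy as np


def wc_fst_oracle(dosages_pop1, dosages_pop2):
    """Weir & Cockerham (1984) theta-hat for two populations of diploids.

    Literal transcription of the a, b, c variance components for one
    biallelic locus; dosage lists may contain None for missing calls.
    Returns None when either population has < 2 called genotypes, 0.0
    when the locus is monomorphic overall (degenerate a = b = c = 0).
    """
    pops = []
    for dos in (dosages_pop1, dosages_pop2):
        called = [d for d in dos if d is not None]
        if len(called) < 2:
            return None
        n_i = len(called)
        p_i = sum(called) / (2 * n_i)
        h_i = sum(1 for d in called if d == 1) / n_i
        pops.append((n_i, p_i, h_i))
    r = 2
    (n1, p1, h1), (n2, p2, h2) = pops
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0:
        return 0.0
    return a / denom


def tajima_d_oracle(minor_counts, n):
    """Tajima (1989) D from per-site minor-allele copy counts among n
    sequences; independent transcription of the a1..e2 constants."""
    S = sum(1 for c in minor_counts if 0 < c < n)
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    # pi: average number of pairwise differences
    pi = 0.0
    for c in minor_counts:
        if 0 < c < n:
            pi += c * (n - c) / math.comb(n, 2)
    theta_w = S / a1
    return (pi - theta_w) / math.sqrt(e1 * S + e2 * S * (S - 1))


def ehh_oracle(haplotypes, core_index, allele, target_index):
    """EHH at target_index by brute-force pair enumeration: the fraction
    of carrier pairs identical over every marker between core and target
    (inclusive)."""
    carriers = [h for h in haplotypes if h[core_index] == allele]
    if len(carriers) < 2:
        return None
    lo, hi = sorted((core_index, target_index))
    same = 0
    total = 0
    for h1, h2 in itertools.combinations(carriers, 2):
        total += 1
        if tuple(h1[lo : hi + 1]) == tuple(h2[lo : hi + 1]):
            same += 1
    return same / total


def ihh_oracle(haplotypes, positions, core_index, allele, cutoff):
    """Trapezoid iHH by walking outward with ehh_oracle, including the
    first below-cutoff marker as the final endpoint."""
    total = 0.0
    m = len(positions)
    for step in (1, -1):
        prev_e = 1.0
        prev_off = 0.0
        idx = core_index
        while True:
            idx += step
            if idx < 0 or idx >= m:
                break
            e = ehh_oracle(haplotypes, core_index, allele, idx)
            off = abs(positions[idx] - positions[core_index])
            total += (off - prev_off) * (prev_e + e) / 2.0
            prev_e, prev_off = e, off
            if e < cutoff:
                break
    return total


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up, straight from the definition:
    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in sorted order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj_sorted = []
    for rank_i in range(m):
        candidates = [
            pvals[order[j]] * m / (j + 1) for j in range(rank_i, m)
        ]
        adj_sorted.append(min(1.0, min(candidates)))
    adj = [0.0] * m
    for rank_i, i in enumerate(order):
        adj[i] = adj_sorted[rank_i]
    return adj


def fisher_exact_oracle(table):
    """Two-sided Fisher exact p for a 2xk table by exhaustive enumeration
    of all tables with the observed margins (conditional multivariate
    hypergeometric; sum probabilities <= the observed one)."""
    table = [list(map(int, row)) for row in table]
    cols = [sum(col) for col in zip(*table)]
    r1 = sum(table[0])
    n = sum(cols)

    def table_prob(top):
        num = 1
        for t, c in zip(top, cols):
            num *= math.comb(c, t)
        return num / math.comb(n, r1)

    p_obs = table_prob(table[0])
    total = 0.0
    for top in itertools.product(*(range(c + 1) for c in cols)):
        if sum(top) != r1:
            continue
        p = table_prob(top)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def genes_overlap_oracle(regions, genes):
    """All-pairs half-open interval overlap check."""
    hits = set()
    for r in regions:
        for g in genes:
            if g.chrom == r.chrom and g.start < r.end and r.start < g.end:
                hits.add(g.gene_id)
    return hits


def nj_three_taxa_lengths(d12, d13, d23):
    """Closed-form branch lengths for the 3-taxon star."""
    return (
        (d12 + d13 - d23) / 2.0,
        (d12 + d23 - d13) / 2.0,
        (d13 + d23 - d12) / 2.0,
    )


def additive_matrix_from_tree():
    """A fixed 4-taxon tree with branch lengths (1,2,3,4,5):
    leaves a,b attach to internal node u (lengths 1, 2); leaves c,d to v
    (lengths 3, 4); edge u-v has length 5. Returns ids and the implied
    additive distance matrix."""
    ids = ["a", "b", "c", "d"]
    la, lb, lc, ld, luv = 1.0, 2.0, 3.0, 4.0, 5.0
    D = np.array(
        [
            [0, la + lb, la + luv + lc, la + luv + ld],
            [la + lb, 0, lb + luv + lc, lb + luv + ld],
            [la + luv + lc, lb + luv + lc, 0, lc + ld],
            [la + luv + ld, lb + luv + ld, lc + ld, 0],
        ],
        dtype=float,
    )
    return ids, D
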