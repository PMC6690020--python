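"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: exact rational arithmetic, explicit
enumeration, no shortcuts shared with the code under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact rationals."""
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    pmf = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        for k in range(kmin, kmax + 1)
    }
    obs = pmf[a]
    return float(sum(q for q in pmf.values() if q <= obs))


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values straight from the step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pam_exhaustive_cost(d: np.ndarray, k: int) -> float:
    """Minimum total distance over every possible medoid set of size k."""
    n = d.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = d[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return float(best)


def positional_mean_profile(elements, sites_beta_by_pos, length: int, body_bins: int):
    """Per-bin mean methylation for equal-length elements, position by position.

    ``elements`` are (chrom, start, strand) triples; ``sites_beta_by_pos``
    maps (chrom, pos) -> beta. Walks every base of every element directly.
    """
    sums = np.zeros(body_bins)
    counts = np.zeros(body_bins, dtype=int)
    for chrom, start, strand in elements:
        for off in range(length):
            pos = start + off
            b = sites_beta_by_pos.get((chrom, pos))
            if b is None:
                continue
            oriented = off if strand == "+" else length - 1 - off
            bin_idx = min(body_bins * oriented // length, body_bins - 1)
            sums[bin_idx] += b
            counts[bin_idx] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions, from the contingency table."""
    import collections

    pairs = list(zip(labels_a, labels_b))
    n = len(pairs)
    contingency = collections.Counter(pairs)
    a_counts = collections.Counter(a for a, _ in pairs)
    b_counts = collections.Counter(b for _, b in pairs)
    sum_comb = sum(comb(c, 2) for c in contingency.values())
    sum_a = sum(comb(c, 2) for c in a_counts.values())
    sum_b = sum(comb(c, 2) for c in b_counts.values())
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)
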