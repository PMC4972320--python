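"""Independent brute-force oracles used by the test suite.

These re-derive expected results by exhaustive enumeration, sharing no code
path with the implementation they check.
"""

from __future__ import annotations

import itertools
import math


def gene_tss_oracle(window_start, window_end, member_tss, sparse_counts, threshold,
                    bin_width=200, bin_stride=10):
    """Exhaustive two-candidate gene-TSS call on a sparse count dict.

    Enumerates every position for candidate A and every bin placement for
    candidate B, applying the documented tie-breaks literally.
    """
    positions = {p: c for p, c in sparse_counts.items() if window_start <= p < window_end}
    if not positions or max(positions.values()) < threshold:
        return None

    def near(p):
        return min(abs(p - t) for t in member_tss)

    # candidate A: window-wide argmax, ties -> closest to an annotated TSS, then smallest
    best = max(positions.values())
    tied = [p for p, c in positions.items() if c == best]
    cand_a = min(tied, key=lambda p: (near(p), p))

    # candidate B: best fully-contained bin (ties -> leftmost), argmax inside (ties -> smallest)
    width = min(bin_width, window_end - window_start)
    best_bin, best_sum = None, -1
    s = window_start
    while s + width <= window_end:
        total = sum(c for p, c in positions.items() if s <= p < s + width)
        if total > best_sum:
            best_sum, best_bin = total, s
        s += bin_stride
    in_bin = {p: c for p, c in positions.items() if best_bin <= p < best_bin + width}
    if in_bin:
        top = max(in_bin.values())
        cand_b = min(p for p, c in in_bin.items() if c == top)
    else:
        cand_b = None

    if cand_b is None or near(cand_a) <= near(cand_b):
        pos = cand_a
    else:
        pos = cand_b
    return pos, positions[pos]


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Sums, over every table with the observed margins, the probabilities no
    larger than the observed table's (with a small relative slack for the
    boundary, as exact-test implementations use).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(nn, kk):
        return math.lgamma(nn + 1) - math.lgamma(kk + 1) - math.lgamma(nn - kk + 1)

    denom = log_comb(n, c1)

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return math.exp(log_comb(r1, k) + log_comb(r2, c1 - k) - denom)

    p_obs = prob(a)
    total = 0.0
    for k in range(0, min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def ranksum_exact_oracle(x, y):
    """Two-sided rank-sum p by enumerating all group assignments (small n)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = _midranks(pooled)
    obs = sum(ranks[i] for i in range(n1))
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        stat = sum(ranks[i] for i in combo)
        total += 1
        if abs(stat - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks
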