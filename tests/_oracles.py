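"""Independent brute-force oracles for the exact tests.

Deliberately naive: the two-sided p-value is obtained by enumerating every
assignment of individual samples to the positive label (N choose T subsets)
and counting, with exact integer arithmetic, the assignments whose induced
table is no more probable than the observed one. Feasible for N <= ~16.
"""

from collections import Counter
from fractions import Fraction
from itertools import combinations
from math import comb


def enumerate_tables(group_sizes, total_positives):
    """All vectors (k_1..k_K) with 0 <= k_i <= n_i and sum k_i = total."""
    sizes = list(group_sizes)

    def rec(i, remaining):
        if i == len(sizes) - 1:
            if remaining <= sizes[i]:
                yield (remaining,)
            return
        tail_cap = sum(sizes[i + 1:])
        lo = max(0, remaining - tail_cap)
        hi = min(sizes[i], remaining)
        for k in range(lo, hi + 1):
            for rest in rec(i + 1, remaining - k):
                yield (k,) + rest

    yield from rec(0, total_positives)


def fisher_2xk_bruteforce(group_sizes, positives) -> Fraction:
    """Exact two-sided p by enumeration of all sample-level assignments."""
    sizes = list(group_sizes)
    N = sum(sizes)
    T = sum(positives)
    if len(sizes) == 1 or T in (0, N):
        return Fraction(1)
    membership = [g for g, n in enumerate(sizes) for _ in range(n)]
    tally = Counter()
    for subset in combinations(range(N), T):
        key = [0] * len(sizes)
        for sample in subset:
            key[membership[sample]] += 1
        tally[tuple(key)] += 1
    # tally[t] equals prod_i C(n_i, k_i): the multiplicity IS the (unscaled)
    # point probability, so table comparisons are exact integer comparisons
    observed = tally[tuple(positives)]
    favorable = sum(count for count in tally.values() if count <= observed)
    return Fraction(favorable, comb(N, T))
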