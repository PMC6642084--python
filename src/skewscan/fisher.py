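"""Exact two-sided Fisher tests on 2xK contingency tables, in log space.

The test conditions on both margins: K group sizes n_1..n_K and the total
number of positives T. Under the null that positives are assigned to samples
uniformly at random, a table with k_i positives in group i has the
multivariate hypergeometric point probability

    P(k_1..k_K) = prod_i C(n_i, k_i) / C(N, T),      N = sum n_i.

The two-sided p-value sums P over every table with the same margins whose
point probability is no larger than the observed one (ties included, with a
small relative tolerance on the log scale to protect against floating-point
tie misses at extreme tails). Clade-level skews in this dataset reach
p < 1e-30, far beyond what chi-square approximations or off-the-shelf 2x2
routines cover, so all accumulation is done on natural-log probabilities
with log-sum-exp.

Rather than enumerating every table, the search runs depth-first over the
positive-count vectors with two classic prunings: a branch whose best
attainable log-probability already exceeds the tie threshold is dropped
whole, and a branch whose *worst* attainable log-probability is still within
the threshold is absorbed in one step using the Vandermonde identity
(sum over completions of prod C(n_j, k_j) = C(sum n_j, r)). The feasible
table count is still computed exactly beforehand and guarded (default 1e7)
so that pathological inputs fail loudly instead of running forever.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .errors import EnumerationLimitError, FormatError, ParameterError
from .hits import CladeMap, PresenceMatrix

LN10 = math.log(10.0)

#: Relative tolerance (on the log10/ln scale) within which a table's point
#: probability is considered tied with the observed one and included in the
#: two-sided tail.
DEFAULT_TIE_TOL = 1e-7

#: Guard on the number of feasible tables sharing the observed margins.
DEFAULT_MAX_TABLES = 10_000_000


def _ln_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _validate_table(group_sizes: Sequence[int],
                    positives: Sequence[int]) -> tuple[tuple[int, ...], tuple[int, ...]]:
    sizes = tuple(int(n) for n in group_sizes)
    pos = tuple(int(k) for k in positives)
    if len(sizes) != len(pos) or len(sizes) < 1:
        raise ParameterError(
            f"group_sizes and positives must be equal-length, non-empty "
            f"(got {len(sizes)} and {len(pos)})")
    for n, k in zip(sizes, pos):
        if n < 1:
            raise ParameterError(f"group sizes must be >= 1, got {n}")
        if not 0 <= k <= n:
            raise ParameterError(f"positives must satisfy 0 <= k <= n, got k={k}, n={n}")
    return sizes, pos


def log_table_prob(group_sizes: Sequence[int], positives: Sequence[int]) -> float:
    """Natural-log conditional (multivariate hypergeometric) probability of a
    2xK table given its margins. Computed via log-gamma; safe for N up to at
    least 1e4."""
    sizes, pos = _validate_table(group_sizes, positives)
    N, T = sum(sizes), sum(pos)
    s = float(sum(_ln_choose(n, k) for n, k in zip(sizes, pos)))
    return s - float(_ln_choose(N, T))


def count_tables(group_sizes: Sequence[int], total_positives: int) -> int:
    """Exact number of non-negative integer vectors (k_1..k_K) with
    k_i <= n_i and sum k_i = total_positives — the size of the conditional
    table space the exact test sums over."""
    sizes, _ = _validate_table(group_sizes, [0] * len(group_sizes))
    T = int(total_positives)
    counts = np.zeros(T + 1, dtype=object)
    counts[0] = 1
    for n in sizes:
        new = np.zeros(T + 1, dtype=object)
        for r in range(T + 1):
            lo = max(0, r - n)
            new[r] = sum(counts[lo:r + 1])
        counts = new
    return int(counts[T])


@dataclass(frozen=True)
class FisherResult:
    """Two-sided exact p-value, reported both as a real and as log10."""

    p_value: float
    log10_p: float


def fisher_exact_2xk(group_sizes: Sequence[int], positives: Sequence[int],
                     tie_tol: float = DEFAULT_TIE_TOL,
                     max_tables: int = DEFAULT_MAX_TABLES) -> FisherResult:
    """Exact two-sided Fisher test on a 2xK table.

    p = sum of conditional probabilities of every table with the observed
    margins whose point probability is <= the observed point probability
    (within ``tie_tol`` relative on the log scale). For K = 1, or margins
    that admit a single table (no positives, or all samples positive), p = 1
    exactly.

    Raises
    ------
    EnumerationLimitError
        If the conditional table space exceeds ``max_tables``. No Monte Carlo
        fallback is attempted; callers should coarsen the grouping instead.
    """
    sizes, pos = _validate_table(group_sizes, positives)
    K = len(sizes)
    N, T = sum(sizes), sum(pos)
    if K == 1 or T == 0 or T == N:
        return FisherResult(1.0, 0.0)

    n_feasible = count_tables(sizes, T)
    if n_feasible > max_tables:
        raise EnumerationLimitError(
            f"{n_feasible} tables share the observed margins (guard: "
            f"{max_tables}); coarsen the grouping or raise max_tables")

    caps = [min(n, T) for n in sizes]
    lnc = [np.asarray(_ln_choose(n, np.arange(0, c + 1))) for n, c in zip(sizes, caps)]
    suffix_cap = [0] * (K + 1)
    suffix_n = [0] * (K + 1)
    for i in range(K - 1, -1, -1):
        suffix_cap[i] = suffix_cap[i + 1] + caps[i]
        suffix_n[i] = suffix_n[i + 1] + sizes[i]

    # Suffix DP: best / worst attainable sum of ln C(n_j, k_j) over groups
    # j >= i given r positives remain to be placed.
    NEG, POS = -math.inf, math.inf
    max_s = np.full((K + 1, T + 1), NEG)
    min_s = np.full((K + 1, T + 1), POS)
    max_s[K, 0] = min_s[K, 0] = 0.0
    for i in range(K - 1, -1, -1):
        for r in range(0, min(T, suffix_cap[i]) + 1):
            lo = max(0, r - suffix_cap[i + 1])
            hi = min(caps[i], r)
            if lo > hi:
                continue
            ks = np.arange(lo, hi + 1)
            max_s[i, r] = np.max(lnc[i][ks] + max_s[i + 1, r - ks])
            min_s[i, r] = np.min(lnc[i][ks] + min_s[i + 1, r - ks])

    ln_choose_NT = float(_ln_choose(N, T))
    s_obs = float(sum(lnc[i][pos[i]] for i in range(K)))
    logp_obs = s_obs - ln_choose_NT
    threshold = s_obs + tie_tol * abs(logp_obs) + 1e-12

    terms: list[float] = []
    stack: list[tuple[int, int, float]] = [(0, T, 0.0)]
    while stack:
        i, r, s = stack.pop()
        if s + max_s[i, r] <= threshold:
            # every completion of this branch is in the two-sided tail;
            # its total mass is C(sum of remaining sizes, r) (Vandermonde)
            terms.append(s + float(_ln_choose(suffix_n[i], r)))
            continue
        if s + min_s[i, r] > threshold:
            continue
        lo = max(0, r - suffix_cap[i + 1])
        hi = min(caps[i], r)
        for k in range(lo, hi + 1):
            stack.append((i + 1, r - k, s + float(lnc[i][k])))

    if not terms:  # the observed table itself always qualifies
        terms = [s_obs]
    ln_p = min(0.0, float(logsumexp(terms)) - ln_choose_NT)
    return FisherResult(math.exp(ln_p), ln_p / LN10)


@dataclass(frozen=True)
class SkewResult:
    """Clade-skew test for one HMM: the observed per-clade positive counts
    against clade sizes, with the exact two-sided p-value."""

    hmm_id: str
    clades: tuple[str, ...]
    group_sizes: tuple[int, ...]
    positives: tuple[int, ...]
    p_value: float
    log10_p: float


def skew_scan(matrix: PresenceMatrix, clades: CladeMap,
              max_tables: int = DEFAULT_MAX_TABLES) -> list[SkewResult]:
    """Exact clade-skew test for every HMM in the matrix, under the null that
    hits are distributed randomly across samples regardless of clade.

    Returns one result per HMM, sorted by ascending p-value (ties broken
    lexicographically by hmm_id). Clades with no samples in the matrix are
    dropped from the table.
    """
    unlabeled = [s for s in matrix.samples if s not in clades.mapping]
    if unlabeled:
        raise FormatError(f"samples missing from clade map: {unlabeled}")
    labels = [clades.mapping[s] for s in matrix.samples]
    active = [c for c in clades.order if c in set(labels)]
    sizes = tuple(labels.count(c) for c in active)
    results = []
    for hmm in matrix.hmms:
        col = matrix.calls[hmm]
        by_clade = {c: 0 for c in active}
        for sample, label in zip(matrix.samples, labels):
            by_clade[label] += int(col[sample])
        pos = tuple(by_clade[c] for c in active)
        if active:
            res = fisher_exact_2xk(sizes, pos, max_tables=max_tables)
        else:
            res = FisherResult(1.0, 0.0)
        results.append(SkewResult(hmm, tuple(active), sizes, pos,
                                  res.p_value, res.log10_p))
    results.sort(key=lambda r: (r.p_value, r.hmm_id))
    return results


@dataclass(frozen=True)
class ConcordanceResult:
    """Pairwise co-presence test for two HMMs (e.g. the two glyoxylate-shunt
    enzymes): the 2x2 of joint presence/absence across samples and its exact
    two-sided p-value."""

    hmm_a: str
    hmm_b: str
    n_both: int
    n_neither: int
    n_a_only: int
    n_b_only: int
    p_value: float
    log10_p: float

    @property
    def n_samples(self) -> int:
        return self.n_both + self.n_neither + self.n_a_only + self.n_b_only


def concordance_from_counts(n_both: int, n_neither: int, n_a_only: int,
                            n_b_only: int, hmm_a: str = "a",
                            hmm_b: str = "b") -> ConcordanceResult:
    """Concordance test directly from the four 2x2 cell counts: groups are
    the a-positive and a-negative samples, positives are the b-positive
    counts within each."""
    a_pos = n_both + n_a_only
    a_neg = n_b_only + n_neither
    sizes, pos = [], []
    if a_pos:
        sizes.append(a_pos)
        pos.append(n_both)
    if a_neg:
        sizes.append(a_neg)
        pos.append(n_b_only)
    res = fisher_exact_2xk(sizes, pos) if sizes else FisherResult(1.0, 0.0)
    return ConcordanceResult(hmm_a, hmm_b, n_both, n_neither, n_a_only,
                             n_b_only, res.p_value, res.log10_p)


def concordance_test(matrix: PresenceMatrix, hmm_a: str,
                     hmm_b: str) -> ConcordanceResult:
    """Test whether two HMMs co-occur across samples more than chance allows
    (conditioning on each HMM's marginal hit count)."""
    col_a = matrix.column(hmm_a)
    col_b = matrix.column(hmm_b)
    both = int(((col_a == 1) & (col_b == 1)).sum())
    neither = int(((col_a == 0) & (col_b == 0)).sum())
    a_only = int(((col_a == 1) & (col_b == 0)).sum())
    b_only = int(((col_a == 0) & (col_b == 1)).sum())
    return concordance_from_counts(both, neither, a_only, b_only, hmm_a, hmm_b)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (optional utility; the
    clade and tree scans report raw exact p-values by default)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in (0, 1]")
    return false_discovery_control(p, method="bh")
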