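"""Independent oracles used by the test suite.

Deliberately naive implementations (enumeration, closed forms) kept apart
from the library code they check.
"""

import itertools
import math

import numpy as np


def exact_expected_distinct(N, K, t):
    """E[distinct lineages] after t generations of single-deme clonal
    Wright-Fisher drift, by full enumeration of the multinomial transition
    over all count states, starting from iid-uniform labels."""
    states = [s for s in itertools.product(range(N + 1), repeat=K) if sum(s) == N]
    index = {s: i for i, s in enumerate(states)}

    def multinom_logp(counts, probs):
        lp = math.lgamma(N + 1)
        for c, p in zip(counts, probs):
            if c and p == 0:
                return -math.inf
            lp -= math.lgamma(c + 1)
            if c:
                lp += c * math.log(p)
        return lp

    dist = np.zeros(len(states))
    for s in states:
        dist[index[s]] = math.exp(multinom_logp(s, [1 / K] * K))
    T = np.zeros((len(states), len(states)))
    for s in states:
        probs = [c / N for c in s]
        for s2 in states:
            T[index[s], index[s2]] = math.exp(multinom_logp(s2, probs))
    for _ in range(t):
        dist = dist @ T
    distinct = np.array([sum(1 for c in s if c > 0) for s in states])
    return float(dist @ distinct)


def hypergeometric_expected_distinct(counts, n):
    """Closed-form E[distinct lineages] when sampling n without replacement."""
    N = sum(counts)
    return sum(1 - math.comb(N - c, n) / math.comb(N, n) for c in counts)


def brute_force_rx2_p(table):
    """Two-sided Freeman-Halton p by direct enumeration with math.comb."""
    rows = [tuple(r) for r in table]
    row_tot = [a + b for a, b in rows]
    c1 = sum(a for a, _ in rows)
    N = sum(row_tot)
    denom = math.comb(N, c1)

    def prob(first_col):
        num = 1
        for r, a in zip(row_tot, first_col):
            num *= math.comb(r, a)
        return num / denom

    p_obs = prob([a for a, _ in rows])
    total = 0.0
    for fc in itertools.product(*[range(r + 1) for r in row_tot]):
        if sum(fc) != c1:
            continue
        p = prob(fc)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total
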