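"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from first principles (Counter
tallies, itertools subset sums, math.log2) and shares no code with the
package's estimators.
"""

import itertools
import math
from collections import Counter


def oracle_entropy(counts) -> float:
    total = sum(counts)
    return -sum(c / total * math.log2(c / total) for c in counts if c > 0)


def oracle_pattern_counts(rows):
    """Counter of allele tuples over complete-case markers.

    ``rows`` is a list of per-spore allele sequences (ints, -1 = missing).
    """
    n_markers = len(rows[0])
    patterns = Counter()
    for m in range(n_markers):
        col = tuple(int(r[m]) for r in rows)
        if all(a >= 0 for a in col):
            patterns[col] += 1
    return patterns


def oracle_interaction_information(rows) -> float:
    """II by direct summation over all subset entropies."""
    patterns = oracle_pattern_counts(rows)
    k = len(rows)
    ii = 0.0
    for r in range(1, k + 1):
        for subset in itertools.combinations(range(k), r):
            marginal = Counter()
            for pattern, c in patterns.items():
                marginal[tuple(pattern[i] for i in subset)] += c
            ii += (-1) ** (r + 1) * oracle_entropy(marginal.values())
    return ii


def oracle_delta(rows) -> float:
    """Product of differential IIs, all subsets on the full group's
    complete-case markers."""
    patterns = oracle_pattern_counts(rows)
    k = len(rows)

    def ii_of(members):
        total = 0.0
        for r in range(1, len(members) + 1):
            for subset in itertools.combinations(members, r):
                marginal = Counter()
                for pattern, c in patterns.items():
                    marginal[tuple(pattern[i] for i in subset)] += c
                total += (-1) ** (r + 1) * oracle_entropy(marginal.values())
        return total

    full = ii_of(tuple(range(k)))
    out = 1.0
    for drop in range(k):
        rest = tuple(i for i in range(k) if i != drop)
        out *= full - ii_of(rest)
    return out
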