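"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: core numbers come from
literal iterative minimum-degree deletion, and exact-test tail
probabilities from full enumeration of all 2x2 tables with the observed
margins using exact rational arithmetic.
"""

from fractions import Fraction
from math import comb


def brute_core_numbers(graph):
    """Core numbers by iterative deletion of minimum-degree vertices."""
    adj = {v: set(graph[v]) for v in graph.nodes}
    core = {}
    k = 0
    while adj:
        while True:
            low = [v for v, nbrs in adj.items() if len(nbrs) <= k]
            if not low:
                break
            for v in low:
                core[v] = k
                for u in adj[v]:
                    adj[u].discard(v)
                del adj[v]
        k += 1
    return core


def _point_prob(x, row1, row2, col1):
    """P(a-cell = x) for fixed margins, as an exact rational."""
    n = row1 + row2
    return Fraction(comb(row1, x) * comb(row2, col1 - x), comb(n, col1))


def _support(row1, row2, col1):
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return range(lo, hi + 1)


def fisher_greater(a, b, c, d):
    """P(X >= a) over all tables with the observed margins (exact)."""
    row1, row2, col1 = a + b, c + d, a + c
    if row1 + row2 == 0 or col1 == 0 or col1 == row1 + row2:
        return Fraction(1)
    return sum((_point_prob(x, row1, row2, col1)
                for x in _support(row1, row2, col1) if x >= a),
               Fraction(0))


def fisher_two_sided(a, b, c, d):
    """Sum of point probabilities <= that of the observed table (exact)."""
    row1, row2, col1 = a + b, c + d, a + c
    if row1 + row2 == 0 or col1 == 0 or col1 == row1 + row2:
        return Fraction(1)
    observed = _point_prob(a, row1, row2, col1)
    return sum((p for x in _support(row1, row2, col1)
                if (p := _point_prob(x, row1, row2, col1)) <= observed),
               Fraction(0))


def hypergeom_upper(overlap, cluster_size, pathway_size, universe):
    """Upper tail via the equivalent 2x2 enumeration."""
    a = overlap
    b = cluster_size - overlap
    c = pathway_size - overlap
    d = universe - a - b - c
    return fisher_greater(a, b, c, d)
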