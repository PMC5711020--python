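"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration or a closed
form, deliberately avoiding the library's own code paths.
"""

from itertools import combinations, product

import numpy as np


def interval_set_members(pairs, lo=1, hi=1000) -> set[int]:
    """All integer base pairs covered by a list of inclusive intervals."""
    out = set()
    for s, e in pairs:
        out.update(range(max(s, lo), min(e, hi) + 1))
    return out


def members_to_pairs(members: set[int]) -> list[tuple[int, int]]:
    """Canonical disjoint inclusive intervals covering a bp set."""
    out = []
    for m in sorted(members):
        if out and m == out[-1][1] + 1:
            out[-1][1] = m
        else:
            out.append([m, m])
    return [tuple(p) for p in out]


def bh_qvalues(p):
    """Benjamini–Hochberg step-up computed from the definition."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = n - rank_from_top
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def minimum_spanning_weight(n_nodes: int, weight) -> float:
    """Exhaustive minimum total weight over all spanning trees.

    Enumerates every (n-1)-edge subset of the complete graph and keeps
    the cheapest connected, acyclic one. Feasible for n <= 7.
    """
    edges = list(combinations(range(n_nodes), 2))
    best = None
    for subset in combinations(edges, n_nodes - 1):
        parent = list(range(n_nodes))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if not ok:
            continue
        total = sum(weight(u, v) for u, v in subset)
        if best is None or total < best:
            best = total
    return best


def enumerate_minimal_qtl_assignments(n_bins, comparisons, max_active=6):
    """Brute-force search over {absent, +, -} per bin.

    ``comparisons`` is a list of (verdict, [(bin_index, orientation)])
    with verdict in {greater, less, equal}. Returns (k, assignments):
    the minimal number of active bins and the set of consistent
    assignments at that k, each a frozenset of (bin_index, sign).
    """

    def ok(assign: dict) -> bool:
        for verdict, touched in comparisons:
            oriented = [assign[b] * o for b, o in touched if b in assign]
            if verdict == "greater" and +1 not in oriented:
                return False
            if verdict == "less" and -1 not in oriented:
                return False
            if verdict == "equal" and oriented and not (
                +1 in oriented and -1 in oriented
            ):
                return False
        return True

    for k in range(0, min(n_bins, max_active) + 1):
        hits = set()
        for bins_ in combinations(range(n_bins), k):
            for signs in product((+1, -1), repeat=k):
                assign = dict(zip(bins_, signs))
                if ok(assign):
                    hits.add(frozenset(assign.items()))
        if hits:
            return k, hits
    return None, set()


def cohens_d_formula(a, h) -> float:
    a, h = np.asarray(a, float), np.asarray(h, float)
    na, nh = len(a), len(h)
    sp2 = ((na - 1) * a.var(ddof=1) + (nh - 1) * h.var(ddof=1)) / (na + nh - 2)
    return (h.mean() - a.mean()) / np.sqrt(sp2)
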