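"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — direct formula evaluation,
exhaustive enumeration — and shares no code with the package, so it can
serve as a second route against the implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def pearson_direct(x, y) -> float:
    """Pearson correlation straight from the definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def _find(parent, x):
    while parent[x] != x:
        parent[x] = parent[parent[x]]
        x = parent[x]
    return x


def n_components(n, edges) -> int:
    parent = list(range(n))
    for u, v, *_ in edges:
        ru, rv = _find(parent, u), _find(parent, v)
        if ru != rv:
            parent[rv] = ru
    return len({_find(parent, i) for i in range(n)})


def min_forest_weight(n, edges) -> float:
    """Exhaustive minimum spanning-forest weight.

    Enumerates all acyclic edge subsets of size n - C (C components of
    the full graph) and returns the minimal total weight.
    """
    k = n - n_components(n, edges)
    if k == 0:
        return 0.0
    best = None
    for subset in itertools.combinations(range(len(edges)), k):
        parent = list(range(n))
        ok = True
        total = 0.0
        for ei in subset:
            u, v, w = edges[ei]
            ru, rv = _find(parent, u), _find(parent, v)
            if ru == rv:
                ok = False
                break
            parent[rv] = ru
            total += w
        if ok and (best is None or total < best):
            best = total
    return best


def set_partitions(items):
    """All set partitions of a sequence (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield [[first]] + partial


def modularity_direct(n, edges, labels, resolution=1.0) -> float:
    """Weighted Newman–Girvan modularity from the definition."""
    W = sum(w for _, _, w in edges)
    if W == 0:
        return 0.0
    internal = {}
    strength = [0.0] * n
    for u, v, w in edges:
        strength[u] += w
        strength[v] += w
        if labels[u] == labels[v]:
            internal[labels[u]] = internal.get(labels[u], 0.0) + w
    q = 0.0
    for c in set(labels):
        s = sum(strength[i] for i in range(n) if labels[i] == c)
        q += internal.get(c, 0.0) / W - resolution * (s / (2.0 * W)) ** 2
    return q


def max_modularity(n, edges, resolution=1.0):
    """Exhaustive modularity maximum over all partitions of n vertices."""
    best_q, best_part = -np.inf, None
    for part in set_partitions(range(n)):
        labels = [0] * n
        for c, block in enumerate(part):
            for i in block:
                labels[i] = c
        q = modularity_direct(n, edges, labels, resolution)
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


def ari_direct(a, b) -> float:
    """Adjusted Rand index from the contingency-table formula."""
    a = list(a)
    b = list(b)
    n = len(a)
    contingency = {}
    for x, y in zip(a, b):
        contingency[(x, y)] = contingency.get((x, y), 0) + 1
    rows = {}
    cols = {}
    for (x, y), c in contingency.items():
        rows[x] = rows.get(x, 0) + c
        cols[y] = cols.get(y, 0) + c

    def comb2(k):
        return k * (k - 1) // 2

    sum_cells = sum(comb2(c) for c in contingency.values())
    sum_rows = sum(comb2(c) for c in rows.values())
    sum_cols = sum(comb2(c) for c in cols.values())
    expected = sum_rows * sum_cols / comb2(n)
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)
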