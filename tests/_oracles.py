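"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: window placement by
exhaustive enumeration, and tree topology selection by least-squares fits
over all unrooted topologies.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_placement(window_scores, widths, min_spacer):
    """Enumerate every ordered, non-overlapping five-window placement.

    Returns ``(starts, total)`` with the maximum total score; ties go to the
    lexicographically smallest start tuple.  Per-placement totals are folded
    right-to-left so float association matches a scan that accumulates
    continuations from the right.
    """
    S = [np.asarray(s, dtype=float) for s in window_scores]
    gaps = [widths[k] + min_spacer for k in range(4)]
    best_score = -np.inf
    best = None
    for a in range(S[0].size):
        for b in range(a + gaps[0], S[1].size):
            for c in range(b + gaps[1], S[2].size):
                for d in range(c + gaps[2], S[3].size):
                    e0 = d + gaps[3]
                    if e0 >= S[4].size:
                        continue
                    v = S[3][d] + S[4][e0:]
                    v = S[2][c] + v
                    v = S[1][b] + v
                    v = S[0][a] + v
                    k = int(np.argmax(v))
                    if v[k] > best_score:
                        best_score = float(v[k])
                        best = (a, b, c, d, e0 + k)
    if best is None:
        return None
    return best, best_score


# --- exhaustive unrooted topologies + least-squares branch lengths ----------

def enumerate_topologies(n_leaves):
    """Yield every unrooted binary topology on leaves 0..n-1 as an edge list.

    Internal nodes are numbered from ``n_leaves`` upward.  Built by inserting
    each leaf on every edge of every smaller topology (3, 15, 105, ...).
    """
    base_internal = n_leaves
    first = [(0, base_internal), (1, base_internal), (2, base_internal)]
    stack = [(first, 3, base_internal + 1)]
    while stack:
        edges, next_leaf, next_internal = stack.pop()
        if next_leaf == n_leaves:
            yield edges
            continue
        for i, (u, v) in enumerate(edges):
            w = next_internal
            new_edges = edges[:i] + edges[i + 1 :] + [(u, w), (w, v), (next_leaf, w)]
            stack.append((new_edges, next_leaf + 1, next_internal + 1))


def _adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _paths_matrix(edges, n_leaves):
    """0/1 design matrix: leaf pairs (i<j) x edges, 1 if the edge is on the path."""
    adj = _adjacency(edges)
    edge_index = {frozenset(e): k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (i, j) in enumerate(pairs):
        # BFS path i -> j
        prev = {i: None}
        queue = [i]
        while queue:
            x = queue.pop(0)
            if x == j:
                break
            for y in adj[x]:
                if y not in prev:
                    prev[y] = x
                    queue.append(y)
        node = j
        while prev[node] is not None:
            A[row, edge_index[frozenset((node, prev[node]))]] = 1
            node = prev[node]
    return A, pairs


def topology_splits(edges, n_leaves):
    """Non-trivial bipartitions of a topology as canonical leaf bitmasks."""
    adj = _adjacency(edges)
    full = (1 << n_leaves) - 1
    splits = set()
    for u, v in edges:
        # leaves on u's side when edge (u, v) is cut
        seen = {u, v}
        queue = [u]
        mask = 0
        while queue:
            x = queue.pop(0)
            if x < n_leaves:
                mask |= 1 << x
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    queue.append(y)
        size = bin(mask).count("1")
        if min(size, n_leaves - size) >= 2:
            splits.add(min(mask, full ^ mask))
    return splits


def least_squares_topology(D):
    """Best-fitting unrooted topology by least squares over all topologies.

    Returns ``(splits, residual, fitted_pairwise)`` of the winner.
    """
    n = D.shape[0]
    d = np.array([D[i, j] for i, j in itertools.combinations(range(n), 2)])
    best = None
    for edges in enumerate_topologies(n):
        A, _pairs = _paths_matrix(edges, n)
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = float(np.linalg.norm(A @ x - d))
        if best is None or resid < best[1]:
            best = (topology_splits(edges, n), resid, A @ x)
    return best


def random_additive_tree(n_leaves, rng):
    """Random topology with random positive branch lengths; returns (D, splits)."""
    topologies = None
    # draw a random topology by random sequential insertion
    base_internal = n_leaves
    edges = [(0, base_internal), (1, base_internal), (2, base_internal)]
    next_internal = base_internal + 1
    for leaf in range(3, n_leaves):
        i = int(rng.integers(0, len(edges)))
        u, v = edges.pop(i)
        w = next_internal
        next_internal += 1
        edges += [(u, w), (w, v), (leaf, w)]
    lengths = rng.uniform(0.5, 3.0, size=len(edges))
    A, pairs = _paths_matrix(edges, n_leaves)
    d = A @ lengths
    D = np.zeros((n_leaves, n_leaves))
    for (i, j), dist in zip(pairs, d):
        D[i, j] = D[j, i] = dist
    return D, topology_splits(edges, n_leaves)
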