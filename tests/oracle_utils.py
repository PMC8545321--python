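"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: simple paths
are enumerated by a hand-written DFS, components and diameters by a
hand-written BFS, and the CAR formula by exact rational arithmetic.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction

SCORE_TOL = 1e-9


def car_fraction(n_c: int, n_r: int, n_p: int) -> Fraction:
    """Exact CAR via rational arithmetic: mean of the one-sided ratios
    times the size-mismatch factor, clipped to [0, 1]."""
    car_r = Fraction(n_c, n_r)
    car_p = Fraction(n_c, n_p)
    car = (car_r + car_p) / 2 * (1 - abs(car_r - car_p))
    return min(Fraction(1), max(Fraction(0), car))


def enumerate_simple_paths(adjacency, source, target):
    """All loop-less source->target paths by depth-first search.

    ``adjacency``: dict node -> dict neighbor -> edge distance.
    Yields (node_tuple, score) with the score summed along the path in
    traversal order (matching how any path walker would accumulate it).
    """
    path = [source]
    on_path = {source}

    def walk(node, score):
        if node == target:
            yield tuple(path), score
            return
        for nbr in sorted(adjacency[node]):
            if nbr in on_path:
                continue
            path.append(nbr)
            on_path.add(nbr)
            yield from walk(nbr, score + adjacency[node][nbr])
            path.pop()
            on_path.remove(nbr)

    yield from walk(source, 0.0)


def sort_paths(records):
    """Order (nodes, score) records by score, breaking near-ties (within
    SCORE_TOL) by length then lexicographic node sequence."""
    records = sorted(records, key=lambda r: r[1])
    out = []
    i = 0
    while i < len(records):
        j = i
        while j + 1 < len(records) and records[j + 1][1] - records[j][1] <= SCORE_TOL:
            j += 1
        out.extend(sorted(records[i:j + 1], key=lambda r: (len(r[0]), r[0])))
        i = j + 1
    return out


def bfs_components(adjacency):
    """Connected components by breadth-first search."""
    seen = set()
    components = []
    for start in sorted(adjacency):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for nbr in adjacency[node]:
                if nbr not in comp:
                    comp.add(nbr)
                    queue.append(nbr)
        seen |= comp
        components.append(comp)
    return components


def bfs_eccentricity(adjacency, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nbr in adjacency[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                queue.append(nbr)
    return max(dist.values()), set(dist)


def bfs_diameter(adjacency):
    """Exact diameter of a connected graph by all-pairs BFS."""
    return max(bfs_eccentricity(adjacency, node)[0] for node in adjacency)


def graph_adjacency(pair_graph, weight="distance"):
    """Plain dict-of-dicts adjacency snapshot of a PairGraph."""
    adj = {}
    for node in pair_graph.graph.nodes:
        adj[node] = {}
    for a, b, data in pair_graph.graph.edges(data=True):
        adj[a][b] = data[weight]
        adj[b][a] = data[weight]
    return adj
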