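"""The 2–4-node graphlet taxonomy and its 15 automorphism orbits.

Everything here is derived by exhaustive enumeration at import time rather
than hardcoded: all connected simple graphs on 2, 3 and 4 nodes are generated
from edge subsets, deduplicated by isomorphism, and partitioned into
automorphism orbits by brute-force permutation search.  The canonical
numbering follows the graphlet literature — graphlets ordered by size, then
edge count, then maximum degree (edge; 3-path; triangle; 4-path; 3-star;
4-cycle; tailed triangle; diamond; 4-clique) — which yields orbits 0..14 with
orbit 0 the plain degree.  Within a graphlet, orbits are numbered by
ascending node degree (degrees are distinct across orbits for all graphlets
this small).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations


@dataclass(frozen=True)
class Graphlet:
    """One connected graph on 2-4 nodes with its automorphism-orbit labels."""

    index: int  # G0..G8
    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    node_orbits: tuple[int, ...]  # global orbit id of each node

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> tuple[int, ...]:
        deg = [0] * self.n_nodes
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return tuple(deg)

    @property
    def orbit_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.node_orbits)))


def _is_connected(n: int, edges: tuple[tuple[int, int], ...]) -> bool:
    adj = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


def _canonical(n: int, edges: frozenset[frozenset[int]]) -> frozenset:
    """Isomorphism-invariant canonical form: lexicographically minimal edge set."""
    best = None
    for perm in permutations(range(n)):
        mapped = frozenset(frozenset(perm[x] for x in e) for e in edges)
        key = tuple(sorted(tuple(sorted(e)) for e in mapped))
        if best is None or key < best[0]:
            best = (key, mapped)
    return best[1]


def _automorphism_orbits(n: int, edges: tuple[tuple[int, int], ...]) -> list[int]:
    """Partition nodes into automorphism orbits; returns orbit index per node."""
    eset = frozenset(frozenset(e) for e in edges)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for perm in permutations(range(n)):
        mapped = frozenset(frozenset(perm[x] for x in e) for e in eset)
        if mapped == eset:
            for x in range(n):
                rx, ry = find(x), find(perm[x])
                if rx != ry:
                    parent[rx] = ry
    return [find(x) for x in range(n)]


@lru_cache(maxsize=1)
def enumerate_graphlets() -> tuple[Graphlet, ...]:
    """All connected non-isomorphic graphs on 2-4 nodes, canonically ordered."""
    raw: list[tuple[int, tuple[tuple[int, int], ...]]] = []
    for n in (2, 3, 4):
        seen: set[frozenset] = set()
        all_pairs = list(combinations(range(n), 2))
        for r in range(1, len(all_pairs) + 1):
            for subset in combinations(all_pairs, r):
                if not _is_connected(n, subset):
                    continue
                canon = _canonical(n, frozenset(frozenset(e) for e in subset))
                if canon in seen:
                    continue
                seen.add(canon)
                raw.append((n, subset))

    def sort_key(item: tuple[int, tuple[tuple[int, int], ...]]):
        n, edges = item
        deg = [0] * n
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        return (n, len(edges), max(deg))

    raw.sort(key=sort_key)

    graphlets: list[Graphlet] = []
    next_orbit = 0
    for gi, (n, edges) in enumerate(raw):
        orbit_part = _automorphism_orbits(n, edges)
        deg = [0] * n
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        # number orbits within the graphlet by ascending degree
        classes = sorted(set(orbit_part), key=lambda c: deg[orbit_part.index(c)])
        local = {c: i for i, c in enumerate(classes)}
        node_orbits = tuple(next_orbit + local[orbit_part[x]] for x in range(n))
        next_orbit += len(classes)
        graphlets.append(
            Graphlet(index=gi, n_nodes=n, edges=tuple(edges), node_orbits=node_orbits)
        )
    return tuple(graphlets)


def n_orbits() -> int:
    """Total orbit count across all 2-4-node graphlets (15)."""
    return max(o for g in enumerate_graphlets() for o in g.node_orbits) + 1


@lru_cache(maxsize=1)
def orbit_lookup() -> dict[tuple[int, tuple[int, ...], int], int]:
    """Map (n_nodes, sorted degree sequence, node degree) -> global orbit id.

    For connected graphs on up to 4 nodes the degree sequence identifies the
    graph and a node's degree identifies its orbit, so this table classifies
    induced subgraphs without explicit isomorphism tests.  Disconnected
    degree sequences (e.g. (1,1,1,1)) are simply absent.
    """
    table: dict[tuple[int, tuple[int, ...], int], int] = {}
    for g in enumerate_graphlets():
        deg = g.degrees
        key_deg = tuple(sorted(deg))
        for x in range(g.n_nodes):
            key = (g.n_nodes, key_deg, deg[x])
            prev = table.get(key)
            assert prev is None or prev == g.node_orbits[x]
            table[key] = g.node_orbits[x]
    return table
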