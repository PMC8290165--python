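"""Independent brute-force implementations used as oracles.

Deliberately naive: triangle enumeration over neighbor pairs, pure-Python
breadth-first all-pairs hop distances, and a direct entropy sum. They share
no code with the package's metric implementations.
"""

from __future__ import annotations

import collections
import math


def adjacency_sets(graph) -> dict:
    """node → set of neighbors, from a networkx graph (self-loops dropped)."""
    adj = {n: set() for n in graph.nodes()}
    for u, v in graph.edges():
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def brute_clustering(graph) -> float:
    adj = adjacency_sets(graph)
    if not adj:
        raise ValueError("empty graph")
    total = 0.0
    for node, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            continue
        nbrs_list = sorted(nbrs)
        links = 0
        for i in range(len(nbrs_list)):
            for j in range(i + 1, len(nbrs_list)):
                if nbrs_list[j] in adj[nbrs_list[i]]:
                    links += 1
        total += 2.0 * links / (k * (k - 1))
    return total / len(adj)


def _bfs_distances(adj: dict, source):
    dist = {source: 0}
    queue = collections.deque([source])
    while queue:
        cur = queue.popleft()
        for nb in adj[cur]:
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                queue.append(nb)
    return dist


def brute_apl(graph, convention: str) -> float:
    adj = adjacency_sets(graph)
    nodes = sorted(adj)
    n = len(nodes)
    if n < 2:
        raise ValueError("need ≥ 2 nodes")
    total = 0.0
    reachable_pairs = 0
    for i, source in enumerate(nodes):
        dist = _bfs_distances(adj, source)
        for target in nodes[i + 1 :]:
            if target in dist:
                total += dist[target]
                reachable_pairs += 1
    if convention == "connected_pairs":
        if reachable_pairs == 0:
            raise ValueError("no reachable pairs")
        return total / reachable_pairs
    return total / (n * (n - 1) / 2)


def brute_entropy(graph) -> tuple[float, float]:
    adj = adjacency_sets(graph)
    degrees = [len(nbrs) for nbrs in adj.values() if len(nbrs) > 0]
    if not degrees:
        raise ValueError("edgeless graph")
    total = float(sum(degrees))
    e = 0.0
    for d in degrees:
        p = d / total
        e -= p * math.log(p)
    e_max = math.log(len(degrees))
    return e, (e / e_max if e_max > 0 else 1.0)
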