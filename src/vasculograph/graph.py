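"""Skeleton-to-graph conversion by the 26-neighbor rule.

Skeleton voxels are classified by how many of their 26 neighbors are also
skeleton voxels: one neighbor → terminal point, two → chain (edge interior),
more than two → junction. Because thinning can leave several junction voxels
at one bifurcation, 26-connected components of junction voxels are merged so
one bifurcation corresponds to one node. Edges are the maximal chains of
two-neighbor voxels linking node voxels; the result is encoded as an
undirected simple graph (parallel chains collapse with a multiplicity
attribute, chains returning to their own junction are recorded self-loops)
plus an adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import ndimage

from .skeletonization import neighbor_counts
from .volume import SkeletonVolume

__all__ = [
    "VoxelLabel",
    "classify_voxels",
    "merge_junction_clusters",
    "trace_edges",
    "build_graph",
    "to_adjacency",
    "save_adjacency",
    "VascularGraph",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STEP_LEN = {1: 1.0, 2: np.sqrt(2.0), 3: np.sqrt(3.0)}


class VoxelLabel:
    """Label codes for classified skeleton voxels."""

    BACKGROUND = 0
    TERMINAL = 1
    CHAIN = 2
    JUNCTION = 3
    SINGLETON = 4  # isolated voxel with no skeleton neighbor


@dataclass
class VascularGraph:
    """Undirected simple vascular graph with voxel-chain edges.

    ``graph`` holds the simple edge set (no parallel edges, no self-loops);
    parallel chains are collapsed with their count in the ``multiplicity``
    edge attribute, and chains closing on a single node are kept in
    ``self_loops``. Node attributes: representative voxel coordinate
    (z, y, x), ``kind`` and ``cluster_size``; coordinates are 0-based voxel
    indices, physical positions are × ``voxel_size``.
    """

    graph: nx.Graph
    voxel_size: float
    self_loops: list[tuple[int, int, float]] = field(default_factory=list)
    n_singletons: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_components(self) -> int:
        if self.n_nodes == 0:
            return 0
        return nx.number_connected_components(self.graph)

    def degree_sequence(self) -> list[int]:
        return sorted(d for _, d in self.graph.degree())

    def total_multiplicity(self) -> int:
        """Chain count including collapsed parallel chains (self-loops aside)."""
        return int(sum(d.get("multiplicity", 1) for _, _, d in self.graph.edges(data=True)))

    def cycle_rank(self) -> int:
        """Independent cycles: all traced chains (incl. parallels and
        self-loops) − nodes + components."""
        return self.total_multiplicity() + len(self.self_loops) - self.n_nodes + self.n_components

    def validate(self) -> None:
        for u, v in self.graph.edges():
            if u == v:
                raise ValueError("self-loop in the simple edge set")
        # handshake over traced chains
        deg_sum = sum(d for _, d in self.graph.degree())
        if deg_sum != 2 * self.n_edges:
            raise ValueError("handshake violated")
        for n, d in self.graph.degree():
            if self.graph.nodes[n]["kind"] == "terminal" and d < 1 and self.n_edges:
                raise ValueError(f"terminal node {n} has degree 0")

    # --- export -------------------------------------------------------
    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": n,
                "z": d["z"],
                "y": d["y"],
                "x": d["x"],
                "kind": d["kind"],
                "cluster_size": d["cluster_size"],
            }
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "u": u,
                "v": v,
                "chain_voxel_count": d["chain_voxel_count"],
                "length_um": d["length_um"],
                "multiplicity": d.get("multiplicity", 1),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        self.node_table().to_csv(nodes_path, index=False)
        self.edge_table().to_csv(edges_path, index=False)


def classify_voxels(skeleton: SkeletonVolume) -> np.ndarray:
    """Label every skeleton voxel by its 26-neighbor count.

    1 neighbor → terminal, 2 → chain, >2 → junction; isolated voxels
    (0 neighbors) are terminal singletons.
    """
    values = skeleton.values
    counts = neighbor_counts(values)
    labels = np.zeros(values.shape, dtype=np.uint8)
    labels[values & (counts == 1)] = VoxelLabel.TERMINAL
    labels[values & (counts == 2)] = VoxelLabel.CHAIN
    labels[values & (counts > 2)] = VoxelLabel.JUNCTION
    labels[values & (counts == 0)] = VoxelLabel.SINGLETON
    return labels


@dataclass
class NodeSet:
    """Nodes plus the voxel → node-id map used for edge tracing."""

    table: list[dict]
    voxel_to_node: dict[tuple[int, int, int], int]


def merge_junction_clusters(labels: np.ndarray) -> NodeSet:
    """One node per 26-connected junction-voxel component, one per terminal.

    The representative coordinate of a junction cluster is the member voxel
    nearest its centroid (ties broken by smallest (z, y, x)). Isolated
    voxels become nodes of kind ``terminal_singleton`` so they stay visible
    in the report without claiming a vessel connection.
    """
    nodes: list[dict] = []
    voxel_to_node: dict[tuple[int, int, int], int] = {}

    junction = labels == VoxelLabel.JUNCTION
    comp, n_comp = ndimage.label(junction, structure=_STRUCT26)
    for c in range(1, n_comp + 1):
        voxels = np.argwhere(comp == c)
        centroid = voxels.mean(axis=0)
        d2 = ((voxels - centroid) ** 2).sum(axis=1)
        order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0], d2))
        rep = tuple(int(v) for v in voxels[order[0]])
        nid = len(nodes)
        nodes.append(
            {"coord": rep, "kind": "bifurcation", "cluster_size": int(len(voxels))}
        )
        for v in map(tuple, voxels):
            voxel_to_node[v] = nid

    for kind_label, kind in (
        (VoxelLabel.TERMINAL, "terminal"),
        (VoxelLabel.SINGLETON, "terminal_singleton"),
    ):
        for v in map(tuple, np.argwhere(labels == kind_label)):
            nid = len(nodes)
            nodes.append({"coord": v, "kind": kind, "cluster_size": 1})
            voxel_to_node[v] = nid
    return NodeSet(nodes, voxel_to_node)


def _neighbors26(voxel, shape):
    z, y, x = voxel
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                n = (z + dz, y + dy, x + dx)
                if 0 <= n[0] < shape[0] and 0 <= n[1] < shape[1] and 0 <= n[2] < shape[2]:
                    yield n


def _step_um(a, b, voxel_size: float) -> float:
    k = abs(a[0] - b[0]) + abs(a[1] - b[1]) + abs(a[2] - b[2])
    return _STEP_LEN[k] * voxel_size


def trace_edges(
    labels: np.ndarray, nodes: NodeSet, voxel_size: float = 4.5
) -> VascularGraph:
    """Walk maximal 2-neighbor chains between nodes and emit the graph.

    Each chain gives one edge with its voxel count and physical length
    (steps of 1/√2/√3 × voxel size, measured node voxel → chain → node
    voxel). Parallel chains collapse onto one simple edge with multiplicity;
    chains joining one node to itself are recorded self-loops; two directly
    adjacent node voxels of different nodes give a chain of length 0.
    Chain cycles touching no node voxel (e.g. a torus skeleton) get one
    anchor node of kind ``cycle`` carrying a self-loop.
    """
    shape = labels.shape
    is_node_voxel = nodes.voxel_to_node
    g = nx.Graph()
    singleton_count = 0
    for nid, n in enumerate(nodes.table):
        g.add_node(
            nid,
            z=int(n["coord"][0]),
            y=int(n["coord"][1]),
            x=int(n["coord"][2]),
            kind=n["kind"],
            cluster_size=n["cluster_size"],
        )
    self_loops: list[tuple[int, int, float]] = []

    def add_edge(u: int, v: int, chain_count: int, length: float) -> None:
        if u == v:
            self_loops.append((u, chain_count, length))
            return
        if g.has_edge(u, v):
            d = g[u][v]
            d["multiplicity"] = d.get("multiplicity", 1) + 1
            # keep the shortest chain as the representative
            if length < d["length_um"]:
                d["length_um"] = length
                d["chain_voxel_count"] = chain_count
        else:
            g.add_edge(u, v, chain_voxel_count=chain_count, length_um=length, multiplicity=1)

    chain_mask = labels == VoxelLabel.CHAIN
    visited = np.zeros(shape, dtype=bool)

    # 1) chains starting next to a node voxel
    for start_voxel, start_node in sorted(is_node_voxel.items()):
        for nb in _neighbors26(start_voxel, shape):
            if chain_mask[nb] and not visited[nb]:
                chain = [nb]
                visited[nb] = True
                prev, cur = start_voxel, nb
                end_node = None
                while True:
                    nxt = None
                    for cand in _neighbors26(cur, shape):
                        if cand == prev:
                            continue
                        if cand in is_node_voxel:
                            end_node = is_node_voxel[cand]
                            nxt = cand
                            break
                        if chain_mask[cand] and not visited[cand]:
                            nxt = cand
                            break
                    if nxt is None:
                        # dead-ends against an already-visited voxel can only
                        # happen for a chain closing on its own start voxel
                        end_node = start_node
                        end_voxel = start_voxel
                        break
                    if end_node is not None:
                        end_voxel = nxt
                        break
                    visited[nxt] = True
                    chain.append(nxt)
                    prev, cur = cur, nxt
                length = _step_um(start_voxel, chain[0], voxel_size)
                for a, b in zip(chain[:-1], chain[1:]):
                    length += _step_um(a, b, voxel_size)
                length += _step_um(chain[-1], end_voxel, voxel_size)
                add_edge(start_node, end_node, len(chain), length)

    # 2) node voxels directly 26-adjacent (no chain voxels between them)
    for voxel, nid in sorted(is_node_voxel.items()):
        for nb in _neighbors26(voxel, shape):
            if nb in is_node_voxel:
                other = is_node_voxel[nb]
                if other > nid or (other == nid):
                    continue
            else:
                continue
            if other != nid and not g.has_edge(nid, other):
                add_edge(nid, other, 0, _step_um(voxel, nb, voxel_size))

    # 3) pure chain cycles never reached from any node (e.g. torus)
    remaining = chain_mask & ~visited
    comp, n_comp = ndimage.label(remaining, structure=_STRUCT26)
    for c in range(1, n_comp + 1):
        voxels = sorted(map(tuple, np.argwhere(comp == c)))
        anchor = voxels[0]
        nid = g.number_of_nodes()
        g.add_node(
            nid,
            z=int(anchor[0]),
            y=int(anchor[1]),
            x=int(anchor[2]),
            kind="cycle",
            cluster_size=1,
        )
        # cycle length: every voxel contributes one step around the loop
        length = 0.0
        # order the cycle by walking it
        walk = [anchor]
        seen = {anchor}
        cur = anchor
        while True:
            nxt = next(
                (n for n in _neighbors26(cur, shape) if comp[n] == c and n not in seen),
                None,
            )
            if nxt is None:
                break
            length += _step_um(cur, nxt, voxel_size)
            seen.add(nxt)
            walk.append(nxt)
            cur = nxt
        length += _step_um(walk[-1], anchor, voxel_size)
        self_loops.append((nid, len(voxels), length))

    vg = VascularGraph(
        graph=g,
        voxel_size=voxel_size,
        self_loops=self_loops,
        n_singletons=int((labels == VoxelLabel.SINGLETON).sum()),
    )
    vg.validate()
    return vg


def build_graph(skeleton: SkeletonVolume) -> VascularGraph:
    """classify → merge junction clusters → trace edges, in one call."""
    labels = classify_voxels(skeleton)
    nodes = merge_junction_clusters(labels)
    return trace_edges(labels, nodes, skeleton.voxel_size)


def save_adjacency(
    graph: VascularGraph | nx.Graph,
    mtx_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> sp.csr_matrix:
    """Write the adjacency matrix as MatrixMarket and/or dense CSV."""
    a = to_adjacency(graph)
    if mtx_path is not None:
        from scipy.io import mmwrite

        mmwrite(str(mtx_path), a)
    if csv_path is not None:
        np.savetxt(str(csv_path), a.toarray(), fmt="%d", delimiter=",")
    return a


def to_adjacency(graph: VascularGraph | nx.Graph) -> sp.csr_matrix:
    """Symmetric 0/1 adjacency over the simple edge set, zero diagonal."""
    g = graph.graph if isinstance(graph, VascularGraph) else graph
    a = nx.to_scipy_sparse_array(g, nodelist=sorted(g.nodes()), dtype=np.int8, format="csr")
    a.setdiag(0)
    a.eliminate_zeros()
    a.data[:] = 1
    return sp.csr_matrix(a)
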