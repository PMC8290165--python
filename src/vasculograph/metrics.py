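"""Topological metrics of vascular graphs: clustering coefficient, average
path length, and network structure entropy.

All three are hop-count metrics on the undirected simple graph:

* ``CC = (1/N) Σ_i 2 e_i / (k_i (k_i − 1))`` — e_i counts edges among the
  neighbors of node i; nodes of degree < 2 contribute 0 and the average runs
  over all N nodes, so 0 ≤ CC ≤ 1.
* ``APL`` — mean shortest hop distance d_ij over node pairs. Two conventions
  for disconnected graphs: ``connected_pairs`` averages over reachable pairs
  only; ``zero_fill`` divides the same sum by all N(N−1)/2 pairs, so
  unreachable pairs pull the mean down (this is how sub-1 values arise in
  heavily fragmented networks). The convention is always recorded.
* ``E = −Σ_i I_i ln I_i`` with degree importance ``I_i = D_i / Σ D_i``, and
  the normalization ``NSE = (E − E_min)/(E_max − E_min)`` with
  ``E_max = ln N′``, ``E_min = 0`` (N′ = number of degree-positive nodes),
  so NSE ∈ [0, 1], natural logarithms throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path
from scipy.stats import linregress

from .graph import VascularGraph, to_adjacency
from .volume import BinaryMask, warn

__all__ = [
    "clustering_coefficient",
    "average_path_length",
    "network_structure_entropy",
    "summarize",
    "volume_node_regression",
    "MetricsReport",
]


def _as_adjacency(graph: VascularGraph | nx.Graph) -> sp.csr_matrix:
    if isinstance(graph, VascularGraph):
        if graph.n_nodes == 0:
            raise ValueError("empty graph")
        return to_adjacency(graph)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    a = nx.to_scipy_sparse_array(graph, nodelist=sorted(graph.nodes()), format="csr")
    a.setdiag(0)
    a.eliminate_zeros()
    a = a.astype(np.int8)
    a.data[:] = 1
    return sp.csr_matrix(a)


def clustering_coefficient(graph: VascularGraph | nx.Graph) -> float:
    """Mean local clustering over all nodes (degree < 2 contributes 0)."""
    a = _as_adjacency(graph)
    n = a.shape[0]
    if n < 1:
        raise ValueError("clustering coefficient undefined on an empty graph")
    a = a.astype(np.int64)
    k = np.asarray(a.sum(axis=1)).ravel()
    # e_i = edges among neighbors of i = (A³)_ii / 2
    tri2 = np.asarray((a @ a @ a).diagonal(), dtype=float)  # = 2 e_i
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(k >= 2, tri2 / (k * (k - 1.0)), 0.0)
    return float(local.sum() / n)


def average_path_length(
    graph: VascularGraph | nx.Graph, convention: str = "zero_fill"
) -> float:
    """Mean shortest hop distance between node pairs.

    ``connected_pairs``: average over reachable unordered pairs only
    (raises if none exist). ``zero_fill``: divide the reachable-pair sum by
    all N(N−1)/2 unordered pairs, unreachable pairs contributing 0.
    """
    if convention not in ("connected_pairs", "zero_fill"):
        raise ValueError(f"unknown APL convention {convention!r}")
    a = _as_adjacency(graph)
    n = a.shape[0]
    if n < 2:
        raise ValueError("average path length needs at least 2 nodes")
    d = shortest_path(a, method="auto", directed=False, unweighted=True)
    iu = np.triu_indices(n, k=1)
    dists = d[iu]
    finite = np.isfinite(dists)
    total = float(dists[finite].sum())
    if convention == "connected_pairs":
        n_pairs = int(finite.sum())
        if n_pairs == 0:
            raise ValueError("no reachable node pair; connected_pairs APL undefined")
        return total / n_pairs
    return total / (n * (n - 1) / 2.0)


def network_structure_entropy(graph: VascularGraph | nx.Graph) -> tuple[float, float]:
    """Degree-importance Shannon entropy E (nats) and its normalization NSE.

    Degree-0 nodes carry no importance mass (0·ln 0 := 0) and are excluded
    from N′ in ``E_max = ln N′`` with a warning.
    """
    a = _as_adjacency(graph)
    n = a.shape[0]
    if n < 2:
        raise ValueError("entropy needs at least 2 nodes")
    deg = np.asarray(a.sum(axis=1)).ravel().astype(float)
    if deg.sum() == 0:
        raise ValueError("entropy undefined on an edgeless graph")
    if (deg == 0).any():
        warn(f"{int((deg == 0).sum())} degree-0 nodes excluded from the entropy sum")
    d = deg[deg > 0]
    i = d / d.sum()
    e = float(-(i * np.log(i)).sum())
    n_pos = len(d)
    e_max = float(np.log(n_pos))
    nse = e / e_max if e_max > 0 else 1.0
    return e, min(nse, 1.0)


@dataclass
class MetricsReport:
    """Per-specimen topology and scale summary."""

    cc: float
    apl: float
    apl_convention: str
    entropy: float
    nse: float
    n_nodes: int
    n_edges: int
    n_components: int
    n_self_loops: int
    segmented_vascular_volume_um3: float
    specimen_id: str = ""
    group: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MetricsReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    def to_row(self) -> pd.Series:
        return pd.Series(dataclasses.asdict(self))


def summarize(
    graph: VascularGraph,
    mask: BinaryMask | None = None,
    apl_convention: str = "zero_fill",
    specimen_id: str = "",
    group: str = "",
) -> MetricsReport:
    """Fill a MetricsReport for one specimen (graph + its vessel mask)."""
    e, nse = network_structure_entropy(graph)
    return MetricsReport(
        cc=clustering_coefficient(graph),
        apl=average_path_length(graph, apl_convention),
        apl_convention=apl_convention,
        entropy=e,
        nse=nse,
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        n_components=graph.n_components,
        n_self_loops=len(graph.self_loops),
        segmented_vascular_volume_um3=float(mask.volume_um3()) if mask is not None else float("nan"),
        specimen_id=specimen_id,
        group=group,
    )


def reports_table(reports: list[MetricsReport]) -> pd.DataFrame:
    """Tidy one-row-per-specimen table ready for group comparison."""
    return pd.DataFrame([dataclasses.asdict(r) for r in reports])


def volume_node_regression(
    reports: list[MetricsReport],
) -> tuple[float, float, float]:
    """OLS of node count on segmented vascular volume → (slope, intercept, r)."""
    if len(reports) < 3:
        raise ValueError("need at least 3 specimens for the regression")
    vol = np.array([r.segmented_vascular_volume_um3 for r in reports], float)
    nodes = np.array([r.n_nodes for r in reports], float)
    if np.ptp(vol) < 1e-12:
        raise ValueError("constant predictor: segmented volumes are all equal")
    fit = linregress(vol, nodes)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
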