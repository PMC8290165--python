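"""Synthetic vascular phantoms with paired ground truth.

Generates parametric 3D vascular trees (dichotomous branching, per-level
radius taper, optional tortuosity, subtree dropout and sibling anastomoses),
rasterizes them into grayscale micro-CT-like volumes, and returns the exact
geometric network used, so every downstream stage — segmentation,
skeletonization, graph building, metrics — can be validated against a known
answer without any acquired data.

Two documented phenotype presets emulate contrast-cast hepatic vasculature:

``normal``
    even hierarchical branching, low tortuosity, no dropout, a moderate rate
    of sibling anastomoses (capillary-like cross-links between daughter
    branches, the source of triangles in real vascular graphs).
``tumor_like``
    deeper but sparser trees (random subtree dropout emulating necrotic,
    unperfused regions), high tortuosity, dilated and irregular calibers,
    and almost no anastomoses — sparse, tortuous, disorganized vessels.

All lengths are in μm; grids are (z, y, x) with isotropic ``voxel_size``.
Every stochastic draw flows from a single ``numpy`` generator seeded by
``spec.seed`` (or an explicit ``seed`` argument), so identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .volume import BinaryMask, VolumeImage

__all__ = [
    "PhantomSpec",
    "GroundTruthNetwork",
    "GroundTruthNode",
    "GroundTruthEdge",
    "generate_tree",
    "rasterize",
    "add_noise",
    "normal_spec",
    "tumor_like_spec",
    "make_torus_mask",
]

#: foreground (contrast-filled lumen) intensity of noise-free phantoms
FOREGROUND_INTENSITY = 200.0
#: minimum rasterized tube radius, in voxels; below ~1.2 a discrete capsule
#: around an oblique centerline can lose 26-connectivity
MIN_RADIUS_VOX = 1.25


class GridTooSmallError(ValueError):
    """The grid cannot contain the requested root vessel."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic vascular specimen.

    ``n_levels`` counts bifurcation generations below the root segment:
    ``n_levels=0`` is a single unbranched vessel; with ``dropout_prob=0`` the
    tree is a full binary tree with ``2**(n_levels+1)`` nodes.
    ``dropout_prob`` deletes each branch (with its whole subtree)
    independently; the first three generations are protected so a specimen
    always retains its major vessels. ``tortuosity_amplitude`` is the lateral bow of each branch
    relative to its length. ``anastomosis_rate`` adds, per bifurcation, a
    cross-link between its two daughter endpoints with that probability.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 4.5  # μm
    root_position: tuple[float, float, float] | None = None  # μm (z, y, x)
    n_levels: int = 5
    branch_length_mean: float = 65.0  # μm
    branch_length_sd: float = 13.0
    root_radius: float = 11.0  # μm
    radius_taper: float = 0.80
    bifurcation_angle_mean: float = 40.0  # degrees, daughter vs parent axis
    tortuosity_amplitude: float = 0.05
    dropout_prob: float = 0.0
    anastomosis_rate: float = 0.0
    radius_jitter: float = 0.0  # lognormal sd of per-branch caliber factor
    phenotype_label: str = "normal"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        object.__setattr__(self, "grid_shape", shape)
        if len(shape) != 3 or any(s < 16 for s in shape):
            raise ValueError(f"grid_shape must be 3 dimensions, all ≥ 16; got {shape}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not self.root_radius > 0:
            raise ValueError("root_radius must be positive")
        if not 0 < self.radius_taper <= 1:
            raise ValueError("radius_taper must lie in (0, 1]")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if not 0 <= self.anastomosis_rate <= 1:
            raise ValueError("anastomosis_rate must lie in [0, 1]")
        if self.n_levels < 0:
            raise ValueError("n_levels must be ≥ 0")
        if self.branch_length_mean <= 0 or self.branch_length_sd < 0:
            raise ValueError("branch lengths must be positive, sd non-negative")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity_amplitude must be ≥ 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.phenotype_label not in ("normal", "tumor_like"):
            raise ValueError("phenotype_label must be 'normal' or 'tumor_like'")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * self.voxel_size

    def default_root(self) -> np.ndarray:
        """Root sits near the low-z face, centered in (y, x)."""
        ez, ey, ex = self.extent_um
        margin = max(3 * self.voxel_size, 1.5 * self.root_radius)
        return np.array([margin, ey / 2.0, ex / 2.0])


def normal_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Default 'normal' hepatic phenotype preset: even hierarchical tree
    with capillary-like cross-links."""
    base = PhantomSpec(
        phenotype_label="normal", n_levels=6, anastomosis_rate=0.25, seed=seed
    )
    return dataclasses.replace(base, **overrides) if overrides else base


def tumor_like_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Default 'tumor-like' phenotype preset: sparse, deep, tortuous, dilated."""
    base = PhantomSpec(
        phenotype_label="tumor_like",
        n_levels=10,
        branch_length_mean=55.0,
        branch_length_sd=14.0,
        root_radius=14.0,
        radius_taper=0.85,
        bifurcation_angle_mean=45.0,
        tortuosity_amplitude=0.35,
        dropout_prob=0.30,
        anastomosis_rate=0.0,
        radius_jitter=0.30,
        seed=seed,
    )
    return dataclasses.replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# ground-truth network containers
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthNode:
    id: int
    position: np.ndarray  # μm, (z, y, x)
    radius: float  # μm
    kind: str  # root | bifurcation | terminal


@dataclass
class GroundTruthEdge:
    u: int
    v: int
    polyline: np.ndarray  # (n, 3) μm
    radius: float  # μm
    length_um: float


@dataclass
class GroundTruthNetwork:
    nodes: list[GroundTruthNode]
    edges: list[GroundTruthEdge]
    n_anastomoses: int = 0
    spec: PhantomSpec | None = field(default=None, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node(self, node_id: int) -> GroundTruthNode:
        return self._index()[node_id]

    def _index(self) -> dict[int, GroundTruthNode]:
        return {n.id: n for n in self.nodes}

    def terminal_count(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "terminal")

    def degree_sequence(self) -> list[int]:
        deg: dict[int, int] = {n.id: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        return sorted(deg.values())

    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def mean_tortuosity(self) -> float:
        """Mean arc length / chord length over edges (≥ 1)."""
        ratios = []
        for e in self.edges:
            chord = float(np.linalg.norm(e.polyline[-1] - e.polyline[0]))
            if chord > 1e-9:
                ratios.append(e.length_um / chord)
        return float(np.mean(ratios)) if ratios else 1.0

    def validate(self) -> None:
        idx = self._index()
        if len(idx) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for n in self.nodes:
            if not n.radius > 0:
                raise ValueError(f"node {n.id} has non-positive radius")
        for e in self.edges:
            for end, nid in ((e.polyline[0], e.u), (e.polyline[-1], e.v)):
                if not np.allclose(end, idx[nid].position, atol=1e-6):
                    raise ValueError(
                        f"edge ({e.u},{e.v}) polyline does not start/end at its nodes"
                    )
        # tree bookkeeping: a forest plus any deliberately added cross-links
        g = self.to_networkx()
        expected = g.number_of_nodes() - nx.number_connected_components(g) + self.n_anastomoses
        if g.number_of_edges() != expected:
            raise ValueError(
                f"edge count {g.number_of_edges()} != nodes − components "
                f"+ anastomoses = {expected}"
            )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            z, y, x = (float(c) for c in n.position)
            g.add_node(n.id, z=z, y=y, x=x, radius=float(n.radius), kind=n.kind)
        for e in self.edges:
            g.add_edge(e.u, e.v, length_um=float(e.length_um))
        return g

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [n.id for n in self.nodes],
                "z_um": [n.position[0] for n in self.nodes],
                "y_um": [n.position[1] for n in self.nodes],
                "x_um": [n.position[2] for n in self.nodes],
                "radius_um": [n.radius for n in self.nodes],
                "kind": [n.kind for n in self.nodes],
            }
        )

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "u": [e.u for e in self.edges],
                "v": [e.v for e in self.edges],
                "radius_um": [e.radius for e in self.edges],
                "length_um": [e.length_um for e in self.edges],
            }
        )

    def to_csv(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        self.node_table().to_csv(nodes_path, index=False)
        self.edge_table().to_csv(edges_path, index=False)


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _perpendicular(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector perpendicular to d."""
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, d) * d
        n = np.linalg.norm(p)
        if n > 1e-6:
            return p / n


def _branch_polyline(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Straight segment bent by a sinusoidal bow plus small jitter."""
    step = 1.5 * spec.voxel_size
    n_pts = max(2, int(math.ceil(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n_pts)
    pts = start[None, :] + np.outer(t * length, direction)
    amp = spec.tortuosity_amplitude
    if amp > 0 and n_pts > 2:
        p1 = _perpendicular(direction, rng)
        p2 = _unit(np.cross(direction, p1))
        phase = rng.uniform(0, 2 * np.pi)
        bow = amp * length * np.sin(np.pi * t)
        pts = pts + np.outer(bow * np.cos(phase), p1) + np.outer(bow * np.sin(phase), p2)
        jitter = 0.15 * amp * length
        mid = rng.normal(0.0, jitter, size=(n_pts, 3))
        mid[0] = mid[-1] = 0.0
        pts = pts + mid * np.sin(np.pi * t)[:, None]
    return pts


def _clip_polyline(pts: np.ndarray, radius: float, spec: PhantomSpec) -> tuple[np.ndarray, bool]:
    """Truncate a polyline before it leaves the grid (tube margin included)."""
    lo = np.full(3, radius)
    hi = spec.extent_um - radius - spec.voxel_size
    inside = np.all((pts >= lo) & (pts <= hi), axis=1)
    if inside.all():
        return pts, False
    k = int(np.argmin(inside))  # first outside point
    return pts[: max(k, 1)], True


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


#: dropout never removes branches of the first three generations, so a
#: specimen always retains its major vessels (necrosis hits downstream branches)
_DROPOUT_PROTECTED_LEVELS = 3


def generate_tree(spec: PhantomSpec, seed: int | None = None) -> GroundTruthNetwork:
    """Grow one vascular tree per ``spec``; deterministic given the seed.

    Returns the contracted network: pass-through points left by subtree
    dropout are merged into their parent branch, so every internal node is a
    true bifurcation (or higher) and terminals/root are endpoints.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    extent = spec.extent_um
    if 2.0 * spec.root_radius >= float(extent.min()) / 2.0:
        raise GridTooSmallError(
            f"root radius {spec.root_radius} μm does not fit grid extent {extent} μm"
        )
    root_pos = (
        np.asarray(spec.root_position, dtype=float)
        if spec.root_position is not None
        else spec.default_root()
    )
    if np.any(root_pos < 0) or np.any(root_pos >= extent):
        raise GridTooSmallError("root_position lies outside the grid")

    nodes: dict[int, GroundTruthNode] = {}
    edges: list[GroundTruthEdge] = []
    children: dict[int, list[int]] = {}
    parent_edge: dict[int, int] = {}
    next_id = 0

    def new_node(pos: np.ndarray, radius: float, kind: str) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        nodes[nid] = GroundTruthNode(nid, np.asarray(pos, float), float(radius), kind)
        children[nid] = []
        return nid

    root_id = new_node(root_pos, spec.root_radius, "root")
    root_dir = _unit(np.array([1.0, 0.0, 0.0]))  # grow along +z

    # depth-first growth with an explicit stack; order is deterministic
    stack = [(root_id, root_dir, spec.root_radius, 0)]
    while stack:
        parent_id, direction, radius, level = stack.pop()
        length = max(
            float(rng.normal(spec.branch_length_mean, spec.branch_length_sd)),
            0.3 * spec.branch_length_mean,
        )
        pts = _branch_polyline(nodes[parent_id].position, direction, length, spec, rng)
        pts, clipped = _clip_polyline(pts, radius, spec)
        if len(pts) < 2:  # no room to grow: parent stays an endpoint
            continue
        end_id = new_node(pts[-1], radius, "terminal")
        eid = len(edges)
        edges.append(
            GroundTruthEdge(parent_id, end_id, pts, float(radius), _polyline_length(pts))
        )
        children[parent_id].append(end_id)
        parent_edge[end_id] = eid
        if clipped or level >= spec.n_levels:
            continue
        # dichotomous branching
        end_dir = _unit(pts[-1] - pts[-2])
        p = _perpendicular(end_dir, rng)
        spawned = []
        for sign in (+1.0, -1.0):
            if level + 1 >= _DROPOUT_PROTECTED_LEVELS and rng.random() < spec.dropout_prob:
                continue
            theta = math.radians(
                max(rng.normal(spec.bifurcation_angle_mean, 8.0), 5.0)
            )
            child_dir = _unit(math.cos(theta) * end_dir + sign * math.sin(theta) * p)
            child_radius = radius * spec.radius_taper
            if spec.radius_jitter > 0:
                child_radius *= float(rng.lognormal(0.0, spec.radius_jitter))
            child_radius = max(child_radius, MIN_RADIUS_VOX * spec.voxel_size)
            spawned.append((end_id, child_dir, child_radius, level + 1))
        if spawned:
            nodes[end_id].kind = "bifurcation"
            stack.extend(reversed(spawned))

    net = _contract_passthrough(nodes, edges)

    # sibling anastomoses: cross-link the two daughters of a bifurcation
    n_anast = 0
    if spec.anastomosis_rate > 0:
        n_anast = _add_anastomoses(net, spec, rng)
    net.n_anastomoses = n_anast
    net.spec = spec
    net.validate()
    return net


def _contract_passthrough(
    nodes: dict[int, GroundTruthNode],
    edges: list[GroundTruthEdge],
) -> GroundTruthNetwork:
    """Merge degree-2 pass-through nodes (single surviving child) into one edge."""
    incident: dict[int, list[int]] = {nid: [] for nid in nodes}
    for i, e in enumerate(edges):
        incident[e.u].append(i)
        incident[e.v].append(i)
    removed_edges: set[int] = set()
    removed_nodes: set[int] = set()
    live_edges = {i: e for i, e in enumerate(edges)}

    # repeatedly merge any non-root node left with exactly 2 incident edges
    # (a pass-through created by dropping one of the two daughters)
    changed = True
    while changed:
        changed = False
        for nid in list(nodes):
            if nid in removed_nodes or nodes[nid].kind == "root":
                continue
            inc = [i for i in incident[nid] if i not in removed_edges]
            if len(inc) != 2:
                continue
            e1, e2 = live_edges[inc[0]], live_edges[inc[1]]
            # orient e1 ending at nid and e2 starting at nid
            p1 = e1.polyline if e1.v == nid else e1.polyline[::-1]
            a = e1.u if e1.v == nid else e1.v
            p2 = e2.polyline if e2.u == nid else e2.polyline[::-1]
            b = e2.v if e2.u == nid else e2.u
            merged = GroundTruthEdge(
                a,
                b,
                np.vstack([p1, p2[1:]]),
                max(e1.radius, e2.radius),
                e1.length_um + e2.length_um,
            )
            new_idx = max(live_edges) + 1
            live_edges[new_idx] = merged
            removed_edges.update(inc)
            removed_nodes.add(nid)
            incident[a] = [i for i in incident[a] if i not in removed_edges] + [new_idx]
            incident[b] = [i for i in incident[b] if i not in removed_edges] + [new_idx]
            changed = True

    keep_nodes = [n for nid, n in sorted(nodes.items()) if nid not in removed_nodes]
    keep_edges = [e for i, e in sorted(live_edges.items()) if i not in removed_edges]
    # relabel ids densely, preserving order
    relabel = {n.id: k for k, n in enumerate(keep_nodes)}
    for n in keep_nodes:
        n.id = relabel[n.id]
    out_edges = []
    for e in keep_edges:
        out_edges.append(
            GroundTruthEdge(relabel[e.u], relabel[e.v], e.polyline, e.radius, e.length_um)
        )
    # endpoints with a single incident edge are terminals (root keeps its kind)
    deg: dict[int, int] = {n.id: 0 for n in keep_nodes}
    for e in out_edges:
        deg[e.u] += 1
        deg[e.v] += 1
    for n in keep_nodes:
        if n.kind != "root":
            n.kind = "terminal" if deg[n.id] <= 1 else "bifurcation"
    return GroundTruthNetwork(keep_nodes, out_edges)


def _add_anastomoses(
    net: GroundTruthNetwork, spec: PhantomSpec, rng: np.random.Generator
) -> int:
    """Capillary-like cross-links of two kinds, both governed by
    ``anastomosis_rate``: sibling arcs between the daughters of a bifurcation
    (these create the triangles real vascular graphs contain) and longer
    shortcut arcs between spatially close but graph-distant nodes (these give
    the normal phenotype its short, efficient path structure)."""
    idx = net._index()
    adj: dict[int, list[int]] = {n.id: [] for n in net.nodes}
    for e in net.edges:
        adj[e.u].append(e.v)
        adj[e.v].append(e.u)
    added = 0

    def try_arc(c1: int, c2: int, apex_away_from: np.ndarray) -> bool:
        nonlocal added
        pa, pb = idx[c1].position, idx[c2].position
        mid = 0.5 * (pa + pb)
        away = _unit(mid - apex_away_from)
        bow = mid + 0.25 * np.linalg.norm(pb - pa) * away
        t = np.linspace(0.0, 1.0, max(5, int(np.linalg.norm(pb - pa) / spec.voxel_size)))
        arc = (
            np.outer((1 - t) ** 2, pa) + np.outer(2 * (1 - t) * t, bow) + np.outer(t**2, pb)
        )
        radius = max(
            0.6 * min(idx[c1].radius, idx[c2].radius), MIN_RADIUS_VOX * spec.voxel_size
        )
        lo = np.full(3, radius)
        hi = spec.extent_um - radius - spec.voxel_size
        if np.any(arc < lo) or np.any(arc > hi):
            return False  # arc would leave the grid
        net.edges.append(
            GroundTruthEdge(c1, c2, arc, float(radius), _polyline_length(arc))
        )
        adj[c1].append(c2)
        adj[c2].append(c1)
        added += 1
        return True

    # sibling arcs (triangles)
    for n in sorted(net.nodes, key=lambda n: n.id):
        nbrs = sorted(adj[n.id])
        if len(nbrs) < 3:  # need a parent and two daughters
            continue
        if rng.random() >= spec.anastomosis_rate:
            continue
        c1, c2 = (int(c) for c in rng.choice(nbrs, size=2, replace=False))
        if c2 not in adj[c1]:
            try_arc(c1, c2, n.position)

    # shortcut arcs: spatially near (≲ 2.5 branch lengths), ≥ 4 hops apart
    g = nx.Graph((e.u, e.v) for e in net.edges)
    g.add_nodes_from(n.id for n in net.nodes)
    pos = {n.id: n.position for n in net.nodes}
    ids = sorted(pos)
    d_max = 2.5 * spec.branch_length_mean
    for i, a in enumerate(ids):
        hops = nx.single_source_shortest_path_length(g, a, cutoff=None)
        for b in ids[i + 1 :]:
            if b in adj[a] or hops.get(b, 99) < 4:
                continue
            if np.linalg.norm(pos[a] - pos[b]) > d_max:
                continue
            if rng.random() < spec.anastomosis_rate:
                center = 0.5 * (pos[a] + pos[b]) - np.array([0.0, 0.0, 1e-3])
                if try_arc(a, b, center):
                    g.add_edge(a, b)
    return added


# ---------------------------------------------------------------------------
# rasterization and noise
# ---------------------------------------------------------------------------


def rasterize(
    network: GroundTruthNetwork,
    spec: PhantomSpec,
    foreground: float = FOREGROUND_INTENSITY,
) -> tuple[VolumeImage, BinaryMask]:
    """Draw every edge as a discrete tube; the mask is the exact tube union.

    A voxel belongs to the mask iff its center lies within the edge radius of
    the centerline polyline (hard inclusion, no antialiasing), so the mask is
    usable as a segmentation oracle. The volume is ``foreground`` on the mask
    and 0 elsewhere, before any noise.
    """
    shape = spec.grid_shape
    mask = np.zeros(shape, dtype=bool)
    vs = spec.voxel_size
    for e in network.edges:
        pts = np.asarray(e.polyline, dtype=float) / vs  # voxel units
        r = max(e.radius / vs, MIN_RADIUS_VOX)
        for p, q in zip(pts[:-1], pts[1:]):
            _paint_capsule(mask, p, q, r)
    volume = VolumeImage(mask.astype(np.float32) * foreground, vs)
    return volume, BinaryMask(mask, vs)


def _paint_capsule(mask: np.ndarray, p: np.ndarray, q: np.ndarray, r: float) -> None:
    lo = np.maximum(np.floor(np.minimum(p, q) - r).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p, q) + r).astype(int) + 1, mask.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = q - p
    dd = float(np.dot(d, d))
    if dd < 1e-12:
        dist = np.linalg.norm(pts - p, axis=-1)
    else:
        t = np.clip(np.einsum("...k,k->...", pts - p, d) / dd, 0.0, 1.0)
        proj = p + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= dist <= r


def add_noise(
    volume: VolumeImage,
    noise_sd: float,
    seed: int,
    intensity_range: tuple[float, float] | None = None,
) -> VolumeImage:
    """Additive Gaussian noise, optionally clipped to an intensity range.

    Float phantom volumes carry no hard dynamic range, so no clip is applied
    unless one is requested (8-bit export clips to (0, 255) at write time).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    if noise_sd == 0:
        return VolumeImage(volume.values.copy(), volume.voxel_size)
    rng = np.random.default_rng(seed)
    out = volume.values + rng.normal(0.0, noise_sd, size=volume.shape).astype(np.float32)
    if intensity_range is not None:
        out = np.clip(out, intensity_range[0], intensity_range[1])
    return VolumeImage(out, volume.voxel_size)


def make_torus_mask(
    shape: tuple[int, int, int] = (48, 64, 64),
    major_radius_vox: float = 18.0,
    minor_radius_vox: float = 3.0,
    voxel_size: float = 4.5,
) -> BinaryMask:
    """Analytic solid torus (one loop) in the z-midplane; a cycle phantom."""
    zc, yc, xc = (s / 2.0 for s in shape)
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    ring = np.sqrt((yy - yc) ** 2 + (xx - xc) ** 2) - major_radius_vox
    dist = np.sqrt(ring**2 + (zz - zc) ** 2)
    return BinaryMask(dist <= minor_radius_vox, voxel_size)
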