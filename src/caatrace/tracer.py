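"""Voxel-scooping tracer with content-aware gap bridging.

Normal tracing runs voxel scooping (VS) on the initial segmentation: starting
from a seed, each step collects the unvisited foreground voxels within the
*scooping distance* of the current node, splits them into 26-connected
sub-clusters (branch handling), and collapses each to a skeleton node at its
centroid.  When scooping exhausts, the content-aware adaptive step (CAAT)
searches nearby *other* components for a place to jump to, scoring each
candidate link by

``link_score = d_score * c_score * dpc_score``

where ``d_score`` decays with the Chebyshev distance beyond ``d_t``,
``c_score`` is 1 only across distinct 26-connected components, and
``dpc_score`` rewards residual probability along the straight corridor
between the closest voxel pair.  A link with score above 0.5 creates a
bridging node and tracing continues inside the linked component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import Volume
from .probmap import Segmentation, low_threshold

__all__ = [
    "TracingParams",
    "VoxelCluster",
    "TraceNode",
    "LinkAssessment",
    "TraceGraph",
    "scooping_distance",
    "scoop_step",
    "distance_score",
    "connectivity_score",
    "line_voxels",
    "continuity_probability",
    "dpc_score",
    "caat_search",
    "trace_all",
]

Vox = tuple[int, int, int]

_NEIGHBORS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


@dataclass
class TracingParams:
    """Tuning knobs of the tracer.

    ``d_t`` (voxels, default 5, sensible range 4-5) is the only genuinely
    free parameter: the distance at which the link score starts decaying.
    ``link_threshold`` accepts a bridge when the combined score exceeds it.
    ``search_radius`` (default ``2 * d_t``) bounds the candidate window; the
    score cannot clear 0.5 beyond ``d_t + 3 ln 2 ≈ d_t + 2.1``, so the
    default window provably contains every acceptable candidate.  ``l_num``
    is the branch-pruning length used downstream.  ``refine_seeds`` snaps
    each seed to a local maximum of the distance transform before tracing so
    the root node starts on the medial axis rather than the surface.
    ``smooth_centers`` applies one radius-weighted averaging pass over each
    node and its tree neighbours after tracing: interior nodes on the medial
    axis are left in place while terminal residue clusters (single surface
    voxels scooped at a tube's end cap) are pulled back toward the axis.
    """

    d_t: float = 5.0
    link_threshold: float = 0.5
    lam: float = 3.0
    t_l: float | None = None
    search_radius: float | None = None
    l_num: int = 6
    refine_seeds: bool = True
    smooth_centers: bool = True

    def __post_init__(self) -> None:
        if self.d_t < 1:
            raise ValueError("d_t must be >= 1 voxel")
        if not (0.0 < self.link_threshold < 1.0):
            raise ValueError("link_threshold must lie in (0, 1)")
        if self.search_radius is None:
            self.search_radius = 2.0 * self.d_t
        if self.search_radius < self.d_t:
            raise ValueError("search_radius must be >= d_t")


@dataclass
class VoxelCluster:
    """A set of integer (z, y, x) voxels, all in one labelled component."""

    voxels: frozenset[Vox]
    component_id: int = 0

    def __post_init__(self) -> None:
        if not self.voxels:
            raise ValueError("cluster must be non-empty")

    def centroid(self) -> tuple[float, float, float]:
        arr = np.asarray(sorted(self.voxels), dtype=float)
        return tuple(arr.mean(axis=0))  # type: ignore[return-value]


@dataclass
class TraceNode:
    """One skeleton node: centroid of its scooped cluster, with a radius."""

    node_id: int
    center: tuple[float, float, float]
    radius: float
    parent_id: int  # -1 for the seed node
    cluster: VoxelCluster


@dataclass(frozen=True)
class LinkAssessment:
    """Scored candidate bridge between two broken fragments."""

    c_p: Vox
    s_p: Vox
    d: float
    d_score: float
    c_score: float
    dpc_score: float
    link_score: float
    candidate_component: int


@dataclass
class TraceGraph:
    """Rooted skeleton produced by one seed (plus any bridged components)."""

    nodes: dict[int, TraceNode] = field(default_factory=dict)
    root_id: int = -1
    components: set[int] = field(default_factory=set)
    links: list[LinkAssessment] = field(default_factory=list)

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id != -1:
                out[node.parent_id].append(node.node_id)
        return out


# ---------------------------------------------------------------------------
# scoring primitives
# ---------------------------------------------------------------------------

def distance_score(c_p: Vox, s_p: Vox, d_t: float) -> tuple[float, float]:
    """Chebyshev distance between the pair and its decayed score.

    Score is 1 up to ``d_t`` (inclusive) and ``exp(-(d - d_t) / 3)`` beyond,
    continuous at the boundary.
    """
    d = float(max(abs(a - b) for a, b in zip(c_p, s_p)))
    score = 1.0 if d <= d_t else math.exp(-(d - d_t) / 3.0)
    return d, score


def connectivity_score(comp_c: int, comp_s: int) -> float:
    """0 within one 26-connected component (no self-links), 1 across two."""
    return 0.0 if comp_c == comp_s else 1.0


def line_voxels(c_p: Vox, s_p: Vox) -> list[Vox]:
    """26-connected voxel chain strictly between two voxels.

    Symmetric integer rasterization: the segment is sampled at the Chebyshev
    distance's worth of evenly spaced points and rounded; endpoints are
    excluded (they belong to the fragments, not the gap).
    """
    if c_p == s_p:
        raise ValueError("line endpoints must differ")
    n = max(abs(a - b) for a, b in zip(c_p, s_p))
    c = np.asarray(c_p, dtype=float)
    s = np.asarray(s_p, dtype=float)
    out: list[Vox] = []
    for k in range(1, n):
        pt = c + (s - c) * (k / n)
        out.append(tuple(int(v) for v in np.floor(pt + 0.5)))
    return out


def continuity_probability(p: float, t_l: float) -> float:
    """CP(p): full credit (1) above the low threshold, raw probability below."""
    return 1.0 if p > t_l else float(p)


def dpc_score(c_p: Vox, s_p: Vox, prob: Volume, t_l: float) -> float:
    """Direction-probability-continuity term along the corridor c_p -> s_p.

    With interior chain M (length d_ps) the score is
    ``exp(-(d_ps - sum CP) / d_ps)``: 1 for a corridor fully above ``t_l``,
    ``exp(-1)`` for a dead (zero-probability) one.  Adjacent voxels score 1.
    """
    chain = line_voxels(c_p, s_p)
    d_ps = len(chain)
    if d_ps == 0:
        return 1.0
    vals = prob.values
    total = sum(continuity_probability(float(vals[v]), t_l) for v in chain)
    return math.exp(-(d_ps - total) / d_ps)


# ---------------------------------------------------------------------------
# voxel scooping
# ---------------------------------------------------------------------------

def _frontier_neighbors(
    frontier: VoxelCluster, visited: np.ndarray, labels: np.ndarray
) -> list[Vox]:
    """Unvisited foreground voxels 26-adjacent to the frontier."""
    shape = labels.shape
    out: set[Vox] = set()
    for z, y, x in frontier.voxels:
        for dz, dy, dx in _NEIGHBORS_26:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                if labels[nz, ny, nx] > 0 and not visited[nz, ny, nx]:
                    out.add((nz, ny, nx))
    return sorted(out)


def scooping_distance(
    node: TraceNode, frontier: VoxelCluster, visited: np.ndarray, seg: Segmentation
) -> float:
    """Max Euclidean distance from the node center to unvisited foreground
    voxels 26-adjacent to the frontier; 0 when the frontier is sealed off."""
    neigh = _frontier_neighbors(frontier, visited, seg.labels.values)
    if not neigh:
        return 0.0
    c = np.asarray(node.center)
    return float(max(np.linalg.norm(np.asarray(v, dtype=float) - c) for v in neigh))


def _split_26(voxels: set[Vox]) -> list[set[Vox]]:
    """Split a voxel set into its 26-connected pieces (deterministic order)."""
    remaining = set(voxels)
    pieces: list[set[Vox]] = []
    while remaining:
        start = min(remaining)
        comp = {start}
        stack = [start]
        remaining.discard(start)
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in _NEIGHBORS_26:
                nb = (z + dz, y + dy, x + dx)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        pieces.append(comp)
    pieces.sort(key=min)
    return pieces


def scoop_step(
    node: TraceNode,
    frontier: VoxelCluster,
    visited: np.ndarray,
    seg: Segmentation,
) -> list[VoxelCluster]:
    """One scooping step: the next point set(s) around the current node.

    Collects every unvisited foreground voxel inside the Euclidean ball of
    the scooping distance around the node center that is 26-connected to the
    frontier through unvisited foreground within the ball, then splits the
    collection into 26-connected sub-clusters (one per branch direction).
    Marks the returned voxels visited.  An empty list signals VS termination.
    """
    labels = seg.labels.values
    radius = scooping_distance(node, frontier, visited, seg)
    if radius == 0.0:
        return []
    c = np.asarray(node.center)
    shape = labels.shape
    lo = np.maximum(np.floor(c - radius).astype(int), 0)
    hi = np.minimum(np.ceil(c + radius).astype(int) + 1, shape)
    sub = np.s_[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    cand = (labels[sub] > 0) & ~visited[sub]
    if cand.any():
        zz, yy, xx = np.nonzero(cand)
        pts = np.stack([zz, yy, xx], axis=1) + lo
        inside = np.linalg.norm(pts - c, axis=1) <= radius + 1e-9
        ball = {tuple(int(v) for v in p) for p in pts[inside]}
    else:
        ball = set()
    # flood from the frontier through the in-ball candidates
    collected: set[Vox] = set()
    stack: list[Vox] = []
    for z, y, x in frontier.voxels:
        for dz, dy, dx in _NEIGHBORS_26:
            nb = (z + dz, y + dy, x + dx)
            if nb in ball and nb not in collected:
                collected.add(nb)
                stack.append(nb)
    while stack:
        z, y, x = stack.pop()
        for dz, dy, dx in _NEIGHBORS_26:
            nb = (z + dz, y + dy, x + dx)
            if nb in ball and nb not in collected:
                collected.add(nb)
                stack.append(nb)
    if not collected:
        return []
    for v in collected:
        visited[v] = True
    clusters = []
    for piece in _split_26(collected):
        lab = int(labels[min(piece)])
        clusters.append(VoxelCluster(frozenset(piece), component_id=lab))
    return clusters


# ---------------------------------------------------------------------------
# CAAT
# ---------------------------------------------------------------------------

def caat_search(
    node: TraceNode,
    frontier: VoxelCluster,
    seg: Segmentation,
    prob: Volume,
    visited: np.ndarray,
    params: TracingParams,
) -> LinkAssessment | None:
    """Search nearby components for an acceptable bridge from a dead end.

    Candidates are the unvisited foreground voxels inside a cube of half-width
    ``search_radius`` around the node center, excluding the frontier's own
    component, grouped by component.  Per component the Chebyshev-closest
    frontier/candidate pair is scored; the best assessment with
    ``link_score > link_threshold`` is returned, else ``None``.  Ties break by
    smaller distance, then smaller component label.
    """
    labels = seg.labels.values
    shape = labels.shape
    t_l = params.t_l if params.t_l is not None else low_threshold(prob)
    own = frontier.component_id
    c = np.asarray(node.center)
    w = float(params.search_radius)
    lo = np.maximum(np.floor(c - w).astype(int), 0)
    hi = np.minimum(np.ceil(c + w).astype(int) + 1, shape)
    sub = np.s_[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    window = labels[sub]
    cand = (window > 0) & (window != own) & ~visited[sub]
    if not cand.any():
        return None
    zz, yy, xx = np.nonzero(cand)
    pts = np.stack([zz, yy, xx], axis=1) + lo
    labs = window[cand]

    fvox = np.asarray(sorted(frontier.voxels))
    best: LinkAssessment | None = None
    for lab in sorted(int(v) for v in np.unique(labs)):
        cpts = pts[labs == lab]
        # pairwise Chebyshev distances frontier x candidates
        diff = np.abs(fvox[:, None, :] - cpts[None, :, :]).max(axis=2)
        dmin = diff.min()
        fi, ci = np.nonzero(diff == dmin)
        # deterministic tie-break: lexicographically smallest s_p, then c_p
        pairs = sorted(
            (tuple(int(v) for v in cpts[j]), tuple(int(v) for v in fvox[i]))
            for i, j in zip(fi, ci)
        )
        s_p, c_p = pairs[0]
        d, d_sc = distance_score(c_p, s_p, params.d_t)
        c_sc = connectivity_score(own, lab)
        dpc = dpc_score(c_p, s_p, prob, t_l)
        link = d_sc * c_sc * dpc
        assessment = LinkAssessment(c_p, s_p, d, d_sc, c_sc, dpc, link, lab)
        if best is None or (
            (link, -d, -lab) > (best.link_score, -best.d, -best.candidate_component)
        ):
            best = assessment
    if best is not None and best.link_score > params.link_threshold:
        return best
    return None


# ---------------------------------------------------------------------------
# full trace
# ---------------------------------------------------------------------------

def _refine_seed(seed: Vox, labels: np.ndarray, edt: np.ndarray) -> Vox:
    """Greedy ascent on the distance transform within the seed's component."""
    lab = labels[seed]
    cur = seed
    shape = labels.shape
    while True:
        best = cur
        best_val = (edt[cur], ())  # prefer larger EDT; stable tie-break
        z, y, x = cur
        for dz, dy, dx in _NEIGHBORS_26:
            nb = (z + dz, y + dy, x + dx)
            if 0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]:
                if labels[nb] == lab and edt[nb] > best_val[0]:
                    best, best_val = nb, (edt[nb], ())
        if best == cur:
            return cur
        cur = best


def _node_radius(center: tuple[float, float, float], edt: np.ndarray) -> float:
    idx = tuple(
        int(np.clip(round(c), 0, s - 1)) for c, s in zip(center, edt.shape)
    )
    return max(1.0, float(edt[idx]))


def trace_all(
    prob: Volume, seg: Segmentation, params: TracingParams | None = None
) -> list[TraceGraph]:
    """Trace every component: voxel scooping plus gap bridging.

    Seeds are processed in ascending component-label order.  Each graph
    alternates scooping (on the segmentation) with the adaptive bridge search
    (on the probability map); a successful bridge absorbs the linked
    component, removing it from the pending seed queue.  A global visited
    mask guarantees each voxel is traced at most once, so the tracer halts on
    any finite volume.  Returns one rooted ``TraceGraph`` per remaining seed.
    """
    params = params or TracingParams()
    if params.t_l is None:
        params.t_l = low_threshold(prob)
    labels = seg.labels.values
    visited = np.zeros(labels.shape, dtype=bool)
    edt = ndimage.distance_transform_edt(labels > 0)
    graphs: list[TraceGraph] = []
    consumed: set[int] = set()
    next_id = 0
    for lab in sorted(seg.seeds):
        if lab in consumed:
            continue
        consumed.add(lab)
        seed = seg.seeds[lab]
        if params.refine_seeds:
            seed = _refine_seed(seed, labels, edt)
        graph = TraceGraph(root_id=next_id, components={lab})
        root_cluster = VoxelCluster(frozenset([seed]), component_id=lab)
        root = TraceNode(next_id, tuple(float(v) for v in seed), _node_radius(seed, edt), -1, root_cluster)
        next_id += 1
        visited[seed] = True
        graph.nodes[root.node_id] = root
        stack = [root.node_id]
        while stack:
            nid = stack.pop()
            node = graph.nodes[nid]
            clusters = scoop_step(node, node.cluster, visited, seg)
            if not clusters:
                link = caat_search(node, node.cluster, seg, prob, visited, params)
                if link is None:
                    continue
                graph.links.append(link)
                lab_new = link.candidate_component
                consumed.add(lab_new)
                graph.components.add(lab_new)
                # bridging cluster: winning-component voxels within Chebyshev
                # radius 1 of s_p (the landing site)
                sz, sy, sx = link.s_p
                cluster_vox = set()
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            nb = (sz + dz, sy + dy, sx + dx)
                            if (
                                0 <= nb[0] < labels.shape[0]
                                and 0 <= nb[1] < labels.shape[1]
                                and 0 <= nb[2] < labels.shape[2]
                                and labels[nb] == lab_new
                                and not visited[nb]
                            ):
                                cluster_vox.add(nb)
                if not cluster_vox:
                    continue
                for v in cluster_vox:
                    visited[v] = True
                bridge_cluster = VoxelCluster(frozenset(cluster_vox), component_id=lab_new)
                bridge = TraceNode(
                    next_id,
                    tuple(float(v) for v in link.s_p),
                    _node_radius(link.s_p, edt),
                    nid,
                    bridge_cluster,
                )
                next_id += 1
                graph.nodes[bridge.node_id] = bridge
                stack.append(bridge.node_id)
                continue
            for cluster in clusters:
                center = cluster.centroid()
                child = TraceNode(next_id, center, _node_radius(center, edt), nid, cluster)
                next_id += 1
                graph.nodes[child.node_id] = child
                stack.append(child.node_id)
        if params.smooth_centers:
            _smooth_graph(graph)
        graphs.append(graph)
    return graphs


def _smooth_graph(graph: TraceGraph) -> None:
    """One radius-weighted smoothing pass over node centers (in place)."""
    neighbors: dict[int, list[int]] = {nid: [] for nid in graph.nodes}
    for node in graph.nodes.values():
        if node.parent_id != -1:
            neighbors[node.node_id].append(node.parent_id)
            neighbors[node.parent_id].append(node.node_id)
    old = {nid: np.asarray(n.center) for nid, n in graph.nodes.items()}
    for nid, node in graph.nodes.items():
        total = node.radius * old[nid]
        weight = node.radius
        for nb in neighbors[nid]:
            w = graph.nodes[nb].radius
            total = total + w * old[nb]
            weight += w
        node.center = tuple(float(v) for v in total / weight)
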