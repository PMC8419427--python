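"""Typed neuron trees: length-first stem selection, branch pruning, SWC
serialization, and block-wise assembly of large-volume tracings."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SwcRecord
from .tracer import TraceGraph, TraceNode, VoxelCluster

__all__ = [
    "NeuronTree",
    "build_tree_length_first",
    "prune_short_branches",
    "to_swc",
    "stitch_blocks",
]


@dataclass
class NeuronTree:
    """Rooted, typed neuron morphology.

    ``node_types`` maps node id to one of root/leaf/path/branch (leaf: one
    neighbour; path: two; branch: more than two).  ``stem`` is the longest
    geodesic root-to-leaf path; ``branches`` are the remaining paths, each
    stored from its branch (attachment) node to a leaf inclusive.
    """

    nodes: dict[int, TraceNode]
    root_id: int
    node_types: dict[int, str] = field(default_factory=dict)
    stem: list[int] = field(default_factory=list)
    branches: list[list[int]] = field(default_factory=list)

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id != -1 and node.parent_id in self.nodes:
                out[node.parent_id].append(node.node_id)
        for lst in out.values():
            lst.sort()
        return out

    def degree(self, nid: int) -> int:
        node = self.nodes[nid]
        deg = len(self.children()[nid])
        if node.parent_id != -1 and node.parent_id in self.nodes:
            deg += 1
        return deg


def _edge_length(a: TraceNode, b: TraceNode) -> float:
    return math.dist(a.center, b.center)


def _assign_types(tree: NeuronTree) -> None:
    children = tree.children()
    for nid, node in tree.nodes.items():
        deg = len(children[nid]) + (0 if node.parent_id == -1 else 1)
        if nid == tree.root_id:
            tree.node_types[nid] = "root"
        elif deg == 1:
            tree.node_types[nid] = "leaf"
        elif deg == 2:
            tree.node_types[nid] = "path"
        else:
            tree.node_types[nid] = "branch"
    # drop stale entries after pruning
    for nid in list(tree.node_types):
        if nid not in tree.nodes:
            del tree.node_types[nid]


def _decompose(tree: NeuronTree) -> None:
    """Recompute stem and branches from the current node set."""
    children = tree.children()
    # geodesic distance from root to every node
    dist: dict[int, float] = {tree.root_id: 0.0}
    order = [tree.root_id]
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        for ch in children[nid]:
            dist[ch] = dist[nid] + _edge_length(tree.nodes[nid], tree.nodes[ch])
            order.append(ch)
            stack.append(ch)
    leaves = [nid for nid in tree.nodes if not children[nid] and nid != tree.root_id]
    if not leaves:
        tree.stem = [tree.root_id]
        tree.branches = []
        return
    # longest geodesic root-to-leaf path; ties -> smaller leaf id
    stem_leaf = max(leaves, key=lambda nid: (dist[nid], -nid))
    path = [stem_leaf]
    while path[-1] != tree.root_id:
        path.append(tree.nodes[path[-1]].parent_id)
    tree.stem = path[::-1]
    claimed = set(tree.stem)
    branches: list[list[int]] = []
    for leaf in sorted(leaves, key=lambda nid: (-dist[nid], nid)):
        if leaf in claimed:
            continue
        branch = [leaf]
        cur = tree.nodes[leaf].parent_id
        while cur not in claimed:
            branch.append(cur)
            cur = tree.nodes[cur].parent_id
        branch.append(cur)  # the attachment (branch) node, already claimed
        claimed.update(branch)
        branches.append(branch[::-1])  # branch node -> leaf
    tree.branches = branches


def build_tree_length_first(graph: TraceGraph) -> NeuronTree:
    """Type a trace graph and pick its stem by the length-first criterion.

    The stem is the geodesically longest root-to-leaf path (cumulative
    Euclidean node-to-node length), starting from the seed node; every other
    root-to-leaf path contributes a branch.  Ties break to the smaller leaf
    node id.
    """
    # connectivity check: every node must reach the root via parents
    for nid, node in graph.nodes.items():
        cur = nid
        hops = 0
        while graph.nodes[cur].parent_id != -1:
            cur = graph.nodes[cur].parent_id
            if cur not in graph.nodes:
                raise ValueError(f"node {nid} has a parent outside the graph")
            hops += 1
            if hops > len(graph.nodes):
                raise ValueError("cycle detected in trace graph")
        if cur != graph.root_id:
            raise ValueError("graph is disconnected: multiple roots")
    tree = NeuronTree(nodes=dict(graph.nodes), root_id=graph.root_id)
    _decompose(tree)
    _assign_types(tree)
    return tree


def prune_short_branches(tree: NeuronTree, l_num: int = 6) -> NeuronTree:
    """Remove spurious short branches, iterated to a fixpoint.

    A branch is pruned when the number of skeleton nodes from its leaf up to
    (excluding) its branch node is below ``l_num`` (default 6, sensible range
    5-10).  Pruning can demote a branch node to a path node and expose new
    short stubs, so the pass repeats until stable.  The stem is never pruned.
    """
    nodes = dict(tree.nodes)
    work = NeuronTree(nodes=nodes, root_id=tree.root_id)
    _decompose(work)
    while True:
        removed = False
        stem_set = set(work.stem)
        for branch in work.branches:
            body = [nid for nid in branch[1:] if nid not in stem_set]
            if len(body) < l_num and body:
                for nid in body:
                    work.nodes.pop(nid, None)
                removed = True
        if not removed:
            break
        _decompose(work)
    _assign_types(work)
    return work


def to_swc(tree: NeuronTree, type_code: int = 2, root_code: int = 1) -> list[SwcRecord]:
    """Serialize a neuron tree to SWC records (depth-first ids from 1).

    Node centers (z, y, x) are emitted as SWC (x, y, z) voxel coordinates;
    radii come from the tracer.
    """
    children = tree.children()
    order: list[int] = []
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        for ch in reversed(children[nid]):
            stack.append(ch)
    new_ids = {nid: i + 1 for i, nid in enumerate(order)}
    records = []
    for nid in order:
        node = tree.nodes[nid]
        parent = -1 if node.parent_id == -1 or node.parent_id not in tree.nodes else new_ids[node.parent_id]
        z, y, x = node.center
        records.append(
            SwcRecord(
                new_ids[nid],
                root_code if parent == -1 else type_code,
                float(x), float(y), float(z),
                float(node.radius),
                parent,
            )
        )
    return records


# ---------------------------------------------------------------------------
# block stitching
# ---------------------------------------------------------------------------

def _shift_tree(tree: NeuronTree, offset: tuple[float, float, float]) -> NeuronTree:
    nodes = {
        nid: TraceNode(
            nid,
            tuple(c + o for c, o in zip(n.center, offset)),
            n.radius,
            n.parent_id,
            n.cluster,
        )
        for nid, n in tree.nodes.items()
    }
    out = NeuronTree(nodes=nodes, root_id=tree.root_id)
    _decompose(out)
    _assign_types(out)
    return out


def _segments(tree: NeuronTree) -> np.ndarray:
    """Edge endpoint array of shape (n_edges, 2, 3)."""
    segs = []
    for node in tree.nodes.values():
        if node.parent_id != -1 and node.parent_id in tree.nodes:
            segs.append((tree.nodes[node.parent_id].center, node.center))
    if not segs:
        c = tree.nodes[tree.root_id].center
        segs = [(c, c)]
    return np.asarray(segs, dtype=float)


def _point_to_segments_dist(points: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Min distance of each point to any segment (brute force)."""
    a, b = segs[:, 0, :], segs[:, 1, :]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    out = np.empty(len(points))
    for i, p in enumerate(points):
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        out[i] = np.sqrt(((p - proj) ** 2).sum(axis=1)).min()
    return out


def _renumber(tree: NeuronTree, start: int) -> NeuronTree:
    mapping = {nid: start + i for i, nid in enumerate(sorted(tree.nodes))}
    nodes = {
        mapping[nid]: TraceNode(
            mapping[nid],
            n.center,
            n.radius,
            -1 if n.parent_id == -1 else mapping[n.parent_id],
            n.cluster,
        )
        for nid, n in tree.nodes.items()
    }
    out = NeuronTree(nodes=nodes, root_id=mapping[tree.root_id])
    _decompose(out)
    _assign_types(out)
    return out


def _merge_pair(kept: NeuronTree, other: NeuronTree, merge_tol: float) -> NeuronTree:
    """Absorb ``other`` into ``kept``: drop duplicated nodes, reattach the rest.

    After deduplication the surviving nodes of ``other`` form fragments; each
    fragment is re-rooted at its node closest to the kept tree and attached
    there by a single edge, so no long detour edge is introduced.
    """
    segs = _segments(kept)
    ids = sorted(other.nodes)
    pts = np.asarray([other.nodes[nid].center for nid in ids])
    dup = _point_to_segments_dist(pts, segs) <= merge_tol
    survivors = {nid for nid, d in zip(ids, dup) if not d}
    kept_pts = np.asarray([n.center for n in kept.nodes.values()])
    kept_ids = list(kept.nodes)
    max_id = max(kept.nodes) + 1
    mapping = {nid: max_id + i for i, nid in enumerate(sorted(survivors))}
    new_nodes = dict(kept.nodes)

    # undirected adjacency among survivors, then fragment-wise re-rooting
    adj: dict[int, list[int]] = {nid: [] for nid in survivors}
    for nid in survivors:
        parent = other.nodes[nid].parent_id
        if parent in survivors:
            adj[nid].append(parent)
            adj[parent].append(nid)
    unseen = set(survivors)
    while unseen:
        start = min(unseen)
        frag = [start]
        stack = [start]
        unseen.discard(start)
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb in unseen:
                    unseen.discard(nb)
                    frag.append(nb)
                    stack.append(nb)
        # attach at the fragment node nearest to the kept tree
        frag_pts = np.asarray([other.nodes[nid].center for nid in frag])
        dists = np.linalg.norm(frag_pts[:, None, :] - kept_pts[None, :, :], axis=2)
        fi, ki = np.unravel_index(int(dists.argmin()), dists.shape)
        attach, anchor = frag[fi], kept_ids[ki]
        parent_of = {attach: None}
        order = [attach]
        stack = [attach]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in parent_of:
                    parent_of[nb] = cur
                    order.append(nb)
                    stack.append(nb)
        for nid in order:
            n = other.nodes[nid]
            par = parent_of[nid]
            new_parent = anchor if par is None else mapping[par]
            new_nodes[mapping[nid]] = TraceNode(
                mapping[nid], n.center, n.radius, new_parent, n.cluster
            )
    out = NeuronTree(nodes=new_nodes, root_id=kept.root_id)
    _decompose(out)
    _assign_types(out)
    return out


def stitch_blocks(
    tracings: list[tuple[list[NeuronTree], tuple[float, float, float]]],
    overlap: int = 15,
    merge_tol: float = 2.0,
) -> list[NeuronTree]:
    """Assemble per-block tracings of a large volume into one forest.

    Each entry is ``(forest, block offset)`` with the offset in global
    (z, y, x) voxels; blocks are expected to overlap by ``overlap`` voxels.
    Trees from different blocks merge when one tree has a node within
    ``merge_tol`` of the other's polyline; the duplicated overlap skeleton is
    deduplicated and the remainder reattached at the nearest kept node.
    """
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    entries: list[tuple[int, NeuronTree]] = []
    for block_idx, (forest, offset) in enumerate(tracings):
        for tree in forest:
            entries.append((block_idx, _shift_tree(tree, tuple(float(o) for o in offset))))
    if len(entries) <= 1:
        return [t for _, t in entries]

    # union-find over trees; trees in the same block never merge
    parent = list(range(len(entries)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    seg_cache = [_segments(t) for _, t in entries]
    pts_cache = [np.asarray([n.center for n in t.nodes.values()]) for _, t in entries]
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if entries[i][0] == entries[j][0]:
                continue
            close = (
                _point_to_segments_dist(pts_cache[j], seg_cache[i]).min() <= merge_tol
                or _point_to_segments_dist(pts_cache[i], seg_cache[j]).min() <= merge_tol
            )
            if close:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(entries)):
        groups.setdefault(find(i), []).append(i)
    out: list[NeuronTree] = []
    next_base = 0
    for members in groups.values():
        members.sort(key=lambda i: -len(entries[i][1].nodes))
        merged = entries[members[0]][1]
        for i in members[1:]:
            merged = _merge_pair(merged, entries[i][1], merge_tol)
        merged = _renumber(merged, next_base)
        next_base += len(merged.nodes)
        out.append(merged)
    return out
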