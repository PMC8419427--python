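"""Tracing evaluation: skeleton resampling, distance-tolerance
precision/recall against a gold standard, and basic morphometrics."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import SwcRecord
from .treegraph import NeuronTree

__all__ = [
    "EvalReport",
    "resample_skeleton",
    "precision_recall",
    "morphometrics",
]


@dataclass(frozen=True)
class EvalReport:
    """Distance-tolerance matching result.

    A traced skeleton point is a true positive when its nearest gold-standard
    point lies strictly within ``tolerance``; precision is the TP fraction of
    traced points, recall the matched fraction of gold points (the two sides
    use their own denominators).
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    tolerance: float
    degenerate: bool = False


def _tree_paths(records: list[SwcRecord]) -> list[np.ndarray]:
    """Maximal unbranched segments of an SWC tree as (z, y, x) polylines."""
    by_id = {r.id: r for r in records}
    children: dict[int, list[int]] = {r.id: [] for r in records}
    root = None
    for r in records:
        if r.parent_id == -1 or r.parent_id not in by_id:
            root = r.id
        else:
            children[r.parent_id].append(r.id)
    if root is None:
        raise ValueError("SWC tree has no root")
    deg = {
        rid: len(children[rid]) + (0 if by_id[rid].parent_id not in by_id else 1)
        for rid in by_id
    }
    paths: list[np.ndarray] = []
    # walk from every junction/root down each child until the next junction/leaf
    stack = [root]
    while stack:
        start = stack.pop()
        for ch in sorted(children[start]):
            seg = [start, ch]
            while deg[seg[-1]] == 2 and children[seg[-1]]:
                seg.append(children[seg[-1]][0])
            stack.append(seg[-1])
            paths.append(
                np.asarray([(by_id[i].z, by_id[i].y, by_id[i].x) for i in seg], dtype=float)
            )
    if not paths:  # single node
        r = by_id[root]
        paths = [np.asarray([(r.z, r.y, r.x)], dtype=float)]
    return paths


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    if len(points) < 2:
        return points.copy()
    deltas = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(deltas)])
    total = arc[-1]
    if total == 0:
        return points[:1].copy()
    targets = np.arange(0.0, total, spacing)
    targets = np.concatenate([targets, [total]])  # keep the endpoint
    out = np.empty((len(targets), 3))
    for ax in range(3):
        out[:, ax] = np.interp(targets, arc, points[:, ax])
    return out


def resample_skeleton(
    trees: list[list[SwcRecord]], spacing: float = 1.0
) -> list[np.ndarray]:
    """Resample each tree's skeleton to evenly spaced points (default 1 voxel).

    Every maximal unbranched segment is re-parameterized by arc length so
    consecutive points sit exactly ``spacing`` apart (the final step of a
    segment may be shorter); junction points are retained and duplicated
    junctions removed.  Returns one (n, 3) point array in (z, y, x) per tree.
    """
    out = []
    for records in trees:
        pts = np.concatenate([_resample_polyline(p, spacing) for p in _tree_paths(records)])
        out.append(np.unique(np.round(pts, 9), axis=0))
    return out


def precision_recall(
    traced: np.ndarray, gold: np.ndarray, tol: float = 6.0
) -> EvalReport:
    """Match traced skeleton points to gold-standard points within ``tol``.

    Both point sets must be resampled at the same spacing.  Matching is by
    nearest neighbour with a strict ``< tol`` Euclidean cutoff (default 6
    voxels).  Empty inputs give a flagged degenerate report with the
    undefined rate reported as 0.
    """
    traced = np.asarray(traced, dtype=float).reshape(-1, 3)
    gold = np.asarray(gold, dtype=float).reshape(-1, 3)
    if len(traced) == 0 or len(gold) == 0:
        tp = 0
        return EvalReport(
            tp=0, fp=len(traced), fn=len(gold),
            precision=0.0, recall=0.0, tolerance=tol, degenerate=True,
        )
    d_traced, _ = cKDTree(gold).query(traced, workers=1)
    tp = int((d_traced < tol).sum())
    fp = len(traced) - tp
    d_gold, _ = cKDTree(traced).query(gold, workers=1)
    matched = int((d_gold < tol).sum())
    fn = len(gold) - matched
    precision = tp / (tp + fp)
    recall = matched / (matched + fn)
    return EvalReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, tolerance=tol)


def morphometrics(
    tree: NeuronTree | list[SwcRecord], spacing: float = 1.0
) -> tuple[float, int]:
    """Total path length and branch-point count of a morphology.

    Path length is the sum of Euclidean edge lengths (times ``spacing``);
    branch points are nodes with more than two neighbours.
    """
    if isinstance(tree, NeuronTree):
        length = 0.0
        children = tree.children()
        for node in tree.nodes.values():
            if node.parent_id != -1 and node.parent_id in tree.nodes:
                length += math.dist(node.center, tree.nodes[node.parent_id].center)
        n_branch = sum(
            1
            for nid, node in tree.nodes.items()
            if len(children[nid]) + (0 if node.parent_id == -1 else 1) > 2
        )
        return length * spacing, n_branch
    records = tree
    by_id = {r.id: r for r in records}
    deg: dict[int, int] = {r.id: 0 for r in records}
    length = 0.0
    for r in records:
        if r.parent_id != -1 and r.parent_id in by_id:
            p = by_id[r.parent_id]
            length += math.dist((r.z, r.y, r.x), (p.z, p.y, p.x))
            deg[r.id] += 1
            deg[r.parent_id] += 1
    return length * spacing, sum(1 for v in deg.values() if v > 2)
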