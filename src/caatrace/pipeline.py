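"""High-level entry points: probability map in, pruned SWC morphology out."""

from __future__ import annotations

import numpy as np

from .io_formats import SwcRecord, Volume
from .probmap import initial_segmentation
from .tracer import TraceGraph, TracingParams, trace_all
from .treegraph import NeuronTree, build_tree_length_first, prune_short_branches, stitch_blocks

__all__ = ["trace_volume", "trace_volume_swc", "trace_large_volume"]


def trace_volume(
    prob: Volume, params: TracingParams | None = None
) -> tuple[list[NeuronTree], list[TraceGraph]]:
    """Segment, trace, build and prune: the full single-block pipeline."""
    params = params or TracingParams()
    seg = initial_segmentation(prob, lam=params.lam)
    graphs = trace_all(prob, seg, params)
    trees = [
        prune_short_branches(build_tree_length_first(g), l_num=params.l_num)
        for g in graphs
    ]
    return trees, graphs


def trace_volume_swc(
    prob: Volume, params: TracingParams | None = None
) -> list[list[SwcRecord]]:
    """Like :func:`trace_volume` but returning SWC record trees."""
    from .treegraph import to_swc

    trees, _ = trace_volume(prob, params)
    return [to_swc(t) for t in trees]


def trace_large_volume(
    prob: Volume,
    params: TracingParams | None = None,
    block: int = 512,
    overlap: int = 15,
    merge_tol: float = 2.0,
) -> list[NeuronTree]:
    """Blockwise tracing of a large volume with overlap-based assembly.

    The volume is tiled into cubes of edge ``block`` whose interiors overlap
    by ``overlap`` voxels; each block is traced independently and the
    per-block forests are stitched by skeleton proximity in the overlap
    regions.
    """
    params = params or TracingParams()
    shape = np.asarray(prob.shape)
    step = block - overlap
    if step <= 0:
        raise ValueError("block must exceed overlap")
    starts = [
        [0] if s <= block else list(range(0, int(s) - overlap, step)) for s in shape
    ]
    tracings = []
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                lo = np.array([z0, y0, x0])
                hi = np.minimum(lo + block, shape)
                sub = Volume(
                    prob.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
                    spacing=prob.spacing,
                    kind="probability",
                )
                try:
                    trees, _ = trace_volume(sub, params)
                except ValueError:
                    continue  # block without background or foreground
                if trees:
                    tracings.append((trees, tuple(float(v) for v in lo)))
    return stitch_blocks(tracings, overlap=overlap, merge_tol=merge_tol)
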