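import numpy as np
import pytest
from scipy import ndimage

from caatrace.io_formats import Volume
from caatrace.probmap import STRUCTURE_26, Segmentation, select_seeds

# background noise tail clamp used by the phantom model (multiples of sd)
BG_CLAMP = 2.0


def make_tube_prob(
    shape=(24, 24, 100),
    center=(12, 12),
    x_range=(4, 95),
    radius=3.0,
    seed=0,
    gap=None,
    gap_level=None,
    bg_sd=0.03,
    fg_level=0.9,
    fg_sd=0.03,
):
    """Straight x-aligned tube probability map with an optional gap.

    ``gap=(a, g)`` blanks the open interval a < x < a+g, leaving fragment
    voxels g apart.  Returns (Volume, gold centerline points (z,y,x)).
    """
    z0, y0 = center
    zz, yy, xx = np.indices(shape)
    mask = ((zz - z0) ** 2 + (yy - y0) ** 2 <= radius**2) & (xx >= x_range[0]) & (xx <= x_range[1])
    rng = np.random.default_rng(seed)
    prob = np.minimum(np.abs(rng.normal(0, bg_sd, shape)), BG_CLAMP * bg_sd)
    fg = mask.copy()
    if gap is not None:
        a, g = gap
        in_gap = (xx > a) & (xx < a + g)
        fg &= ~in_gap
        if gap_level is not None:
            prob[mask & in_gap] = gap_level
    prob[fg] = np.clip(fg_level + rng.normal(0, fg_sd, int(fg.sum())), 0, 1)
    gold_x = np.arange(x_range[0], x_range[1] + 1)
    gold = np.stack([np.full_like(gold_x, z0), np.full_like(gold_x, y0), gold_x], axis=1).astype(float)
    return Volume(np.clip(prob, 0, 1), kind="probability"), gold


def segmentation_from_mask(mask: np.ndarray) -> Segmentation:
    """Build a Segmentation directly from a boolean mask (26-connectivity)."""
    mask = np.asarray(mask).astype(bool)
    labels, _ = ndimage.label(mask, structure=STRUCTURE_26)
    seg = Segmentation(
        mask=Volume(mask.astype(np.uint8), kind="mask"),
        labels=Volume(labels.astype(np.int32), kind="labels"),
        threshold_used=0.5,
    )
    seg.seeds = select_seeds(seg)
    return seg


def bfs_label_26(mask: np.ndarray) -> np.ndarray:
    """Brute-force 26-connected labeling oracle (scan-order label assignment)."""
    mask = np.asarray(mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    shape = mask.shape
    nxt = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if mask[z, y, x] and labels[z, y, x] == 0:
                    nxt += 1
                    stack = [(z, y, x)]
                    labels[z, y, x] = nxt
                    while stack:
                        cz, cy, cx = stack.pop()
                        for dz, dy, dx in offsets:
                            nz, ny, nx = cz + dz, cy + dy, cx + dx
                            if (
                                0 <= nz < shape[0]
                                and 0 <= ny < shape[1]
                                and 0 <= nx < shape[2]
                                and mask[nz, ny, nx]
                                and labels[nz, ny, nx] == 0
                            ):
                                labels[nz, ny, nx] = nxt
                                stack.append((nz, ny, nx))
    return labels


@pytest.fixture
def straight_tube():
    return make_tube_prob()
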