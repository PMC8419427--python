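"""Synthetic tubular phantoms with controlled gaps.

Generates smooth 3D centerline forests, rasterizes them into tubes of radius
2-4 voxels, and synthesizes a CNN-like probability map: near-1 values with
mild noise on the tubes, half-normal noise on the background, and optional
low/zero-probability *gaps* interrupting the tubes — the discontinuous
prediction failure mode that gap bridging has to repair.  Ground truth
(centerlines, radii, gap intervals, SWC trees) is carried alongside so tracing
accuracy can be measured without microscopy data.

Gap semantics: a gap of length ``g`` removes the interior centerline samples
of an open arc interval of length ``g``, so the two surviving fragment
endpoints sit ``g`` voxels apart — gap length equals the unsupported span the
tracer must bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import SwcRecord, Volume

__all__ = [
    "PhantomSpec",
    "Polyline",
    "PhantomTruth",
    "sample_centerline_forest",
    "rasterize_tubes",
    "synthesize_probability",
    "generate_phantom",
]

_MARGIN_EXTRA = 2.0
_MIN_CURVE_LEN = 20.0
# Background noise is half-normal with its tail clamped at this multiple of
# bg_noise_sd.  CNN backgrounds are confidently low: unlike raw microscopy
# noise they carry no isolated super-threshold speckles.  The clamp sits
# below mu_bg + 3*sigma_bg of the clamped population (~2.45 sd), so no pure
# background voxel can ever cross the adaptive segmentation threshold and a
# gap filled with this model is guaranteed to break the initial segmentation.
_BG_CLAMP_SD = 2.0
# max turn of 60 degrees per 10-voxel arc step
_MAX_TURN_PER_VOXEL = np.deg2rad(60.0) / 10.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``gap_specs`` is a list of ``(count, length_voxels)`` pairs applied per
    tree.  ``gap_level`` of ``None`` fills gaps with the background noise
    model; a number paints a constant dim plateau instead (a weak but present
    prediction, which the corridor term can exploit).
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    n_trees: int = 2
    radius_range: tuple[float, float] = (2.0, 4.0)
    branch_prob: float = 0.0
    gap_specs: Sequence[tuple[int, int]] = ()
    fg_level: float = 0.9
    fg_noise_sd: float = 0.03
    bg_noise_sd: float = 0.03
    blur_sigma: float = 0.0
    tree_length: float = 100.0
    seed: int = 0
    gap_level: float | None = None

    def __post_init__(self) -> None:
        if self.radius_range[0] < 1:
            raise ValueError("minimum radius must be >= 1 voxel")
        if any(length < 1 for _, length in self.gap_specs):
            raise ValueError("gap length must be >= 1 voxel")
        if self.fg_level - 3 * self.fg_noise_sd <= self.bg_noise_sd * 3:
            raise ValueError("foreground level too close to background: untraceable spec")
        margin = self.radius_range[1] + _MARGIN_EXTRA
        if min(self.shape) <= 2 * margin + 4 or self.tree_length < _MIN_CURVE_LEN:
            raise ValueError(
                f"shape {self.shape} too small for a {_MIN_CURVE_LEN:.0f}-voxel curve "
                f"at radius {self.radius_range[1]}"
            )


@dataclass
class Polyline:
    """One unbranched centerline: points at ~1-voxel arc spacing, (z, y, x)."""

    points: np.ndarray  # (n, 3) float
    radii: np.ndarray  # (n,) float
    parent: tuple[int, int] | None = None  # (polyline index, point index) attachment
    gap_ranges: list[tuple[int, int]] = field(default_factory=list)  # half-open index ranges

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class PhantomTruth:
    """Ground truth of a phantom: per-tree polylines and their SWC rendering."""

    trees: list[list[Polyline]]
    shape: tuple[int, int, int]

    def swc_trees(self) -> list[list[SwcRecord]]:
        """Render the full (ungapped) centerline forest as SWC record trees."""
        out = []
        for tree in self.trees:
            records: list[SwcRecord] = []
            next_id = 1
            point_ids: list[list[int]] = []
            for line in tree:
                ids = []
                for i, (pt, r) in enumerate(zip(line.points, line.radii)):
                    if i == 0:
                        if line.parent is None:
                            parent = -1
                        else:
                            pl, pi = line.parent
                            parent = point_ids[pl][pi]
                    else:
                        parent = ids[-1]
                    z, y, x = (float(v) for v in pt)
                    records.append(
                        SwcRecord(next_id, 1 if parent == -1 else 2, x, y, z, max(float(r), 0.1), parent)
                    )
                    ids.append(next_id)
                    next_id += 1
                point_ids.append(ids)
            out.append(records)
        return out


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _rotate_towards(d: np.ndarray, target: np.ndarray, max_angle: float) -> np.ndarray:
    """Rotate unit vector d towards target by at most max_angle."""
    cosang = float(np.clip(d @ target, -1.0, 1.0))
    ang = np.arccos(cosang)
    if ang <= max_angle or ang == 0.0:
        return _unit(target) if ang <= max_angle else d
    # slerp a fraction of the way
    t = max_angle / ang
    sin_ang = np.sin(ang)
    return _unit((np.sin((1 - t) * ang) * d + np.sin(t * ang) * target) / sin_ang)


_WALL_RANGE = 12.0


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
) -> np.ndarray:
    """Unit-step random walk with bounded per-step turning.

    Walls repel the heading smoothly within the same turning budget; if the
    walk still reaches a bound it stops early rather than kink, so the
    emitted polyline satisfies the turning bound everywhere.
    """
    pts = [start.copy()]
    d = direction.copy()
    n_steps = int(round(length))
    for _ in range(n_steps):
        p = pts[-1]
        repulsion = np.zeros(3)
        for ax in range(3):
            if p[ax] < bounds_lo[ax] + _WALL_RANGE:
                repulsion[ax] += 0.5 * (bounds_lo[ax] + _WALL_RANGE - p[ax]) / _WALL_RANGE
            if p[ax] > bounds_hi[ax] - _WALL_RANGE:
                repulsion[ax] -= 0.5 * (p[ax] - (bounds_hi[ax] - _WALL_RANGE)) / _WALL_RANGE
        target = _unit(d + rng.normal(scale=0.12, size=3) + repulsion)
        d = _rotate_towards(d, target, _MAX_TURN_PER_VOXEL)
        nxt = p + d
        if (nxt < bounds_lo).any() or (nxt > bounds_hi).any():
            break
        pts.append(nxt)
    return np.asarray(pts)


def sample_centerline_forest(spec: PhantomSpec) -> PhantomTruth:
    """Sample smooth centerline trees (geometry only, no gaps placed yet).

    Each tree is a unit-step random walk whose direction turns by at most 60
    degrees per 10 voxels of arc; with ``branch_prob`` per 10-voxel segment a
    Y-branch walks off at ~45 degrees.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    margin = spec.radius_range[1] + _MARGIN_EXTRA
    lo = np.full(3, margin)
    hi = np.asarray(spec.shape, dtype=float) - 1 - margin
    trees: list[list[Polyline]] = []
    placed_pts: list[np.ndarray] = []
    placed_radii: list[float] = []
    for _ in range(spec.n_trees):
        radius = float(rng.uniform(*spec.radius_range))
        # rejection-sample the walk so distinct trees stay well separated:
        # keeps tube components disjoint and bridging decisions unambiguous
        main = None
        best, best_key = None, (-1.0, -1.0)
        full = int(round(spec.tree_length)) + 1
        for _attempt in range(60):
            start = rng.uniform(lo + 2, hi - 2)
            cand = _walk(rng, start, _random_unit(rng), spec.tree_length, lo, hi)
            if len(cand) < _MIN_CURVE_LEN + 1:
                continue
            min_sep = np.inf
            target = 0.0
            for pts, r_other in zip(placed_pts, placed_radii):
                target = max(target, radius + r_other + 8.0)
                min_sep = min(min_sep, float(cKDTree(pts).query(cand, workers=1)[0].min()))
            if len(cand) == full and min_sep >= target:
                main = cand
                break
            key = (float(len(cand)), min(min_sep, target))
            if key > best_key:
                best, best_key = cand, key
        if main is None:
            # fall back to the longest, best-separated candidate (small volumes)
            if best is None:
                raise ValueError("shape too small to fit the requested curves")
            main = best
        placed_pts.append(main)
        placed_radii.append(radius)
        lines = [Polyline(main, np.full(len(main), radius))]
        # branch decisions per 10-voxel segment of the main line
        n_segments = max(1, (len(main) - 1) // 10)
        for seg in range(1, n_segments):
            if rng.uniform() < spec.branch_prob:
                at = seg * 10
                base_dir = _unit(main[at] - main[at - 1])
                # kick off at ~45 degrees from the parent direction
                perp = _unit(np.cross(base_dir, _random_unit(rng)))
                branch_dir = _unit(base_dir + perp)
                blen = max(_MIN_CURVE_LEN, spec.tree_length / 3)
                bpts = _walk(rng, main[at].copy(), branch_dir, blen, lo, hi)
                lines.append(Polyline(bpts[1:], np.full(len(bpts) - 1, radius), parent=(0, at)))
        trees.append(lines)
    return PhantomTruth(trees=trees, shape=spec.shape)


def place_gaps(truth: PhantomTruth, spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Assign disjoint gap intervals per tree, >= 5 voxels from tips and forks."""
    keepout = 5
    for tree in truth.trees:
        blocked: dict[int, set[int]] = {i: set() for i in range(len(tree))}
        for line in tree:
            if line.parent is not None:
                pl, pi = line.parent
                blocked[pl].update(range(pi - keepout, pi + keepout + 1))
        for count, length in spec.gap_specs:
            for _ in range(count):
                placed = False
                for _attempt in range(200):
                    li = int(rng.integers(len(tree)))
                    line = tree[li]
                    # removed samples are a+1 .. a+length-1; endpoints a, a+length survive
                    if line.n_points < length + 2 * keepout + 2:
                        continue
                    a = int(rng.integers(keepout, line.n_points - length - keepout))
                    rng_new = set(range(a, a + length + 1))
                    taken = blocked[li]
                    if rng_new & taken:
                        continue
                    line.gap_ranges.append((a + 1, a + length))
                    taken.update(range(a - keepout, a + length + keepout + 1))
                    placed = True
                    break
                if not placed:
                    raise ValueError(
                        f"could not place a gap of length {length}: host segments too short"
                    )


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    rng_ = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(rng_, rng_, rng_, indexing="ij")
    keep = dz**2 + dy**2 + dx**2 <= radius**2 + 1e-9
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def _stamp(shape: tuple[int, int, int], points: np.ndarray, radii: np.ndarray) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    cache: dict[float, np.ndarray] = {}
    for pt, r in zip(points, radii):
        r = round(float(r), 3)
        offs = cache.setdefault(r, _ball_offsets(r))
        vox = np.rint(pt).astype(int) + offs
        np.clip(vox, 0, np.asarray(shape) - 1, out=vox)
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return mask


def _all_points(truth: PhantomTruth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate all centerline points; returns (points, radii, is_gap)."""
    pts, radii, gap = [], [], []
    for tree in truth.trees:
        for line in tree:
            flag = np.zeros(line.n_points, dtype=bool)
            for a, b in line.gap_ranges:
                flag[a:b] = True
            pts.append(line.points)
            radii.append(line.radii)
            gap.append(flag)
    if not pts:
        return np.empty((0, 3)), np.empty(0), np.empty(0, dtype=bool)
    return np.concatenate(pts), np.concatenate(radii), np.concatenate(gap)


def rasterize_tubes(truth: PhantomTruth, shape: tuple[int, int, int] | None = None) -> Volume:
    """Rasterize the centerline forest into a binary tube mask.

    A voxel is foreground iff its Euclidean distance to the nearest centerline
    sample is within the local radius.  Gaps do not affect the mask — the mask
    is the intact anatomy; gaps live in the probability model.
    """
    shape = shape or truth.shape
    pts, radii, _ = _all_points(truth)
    if (pts < -0.5).any() or (pts > np.asarray(shape) - 0.5).any():
        raise ValueError("centerline leaves the volume bounds")
    mask = _stamp(shape, pts, radii)
    return Volume(mask.astype(np.uint8), kind="mask")


def synthesize_probability(
    mask: Volume, truth: PhantomTruth, spec: PhantomSpec
) -> Volume:
    """Paint a CNN-like probability map over a tube mask.

    Foreground ~ clip(fg_level + N(0, fg_noise_sd), 0, 1); background ~
    clip(|N(0, bg_noise_sd)|, 0, 1).  Voxels whose nearest centerline sample
    falls in a gap interval get the background model (or the constant
    ``gap_level`` plateau), emulating a broken prediction.  Optional Gaussian
    blur of ``blur_sigma`` voxels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    m = mask.values.astype(bool)
    clamp = _BG_CLAMP_SD * spec.bg_noise_sd
    prob = np.minimum(np.abs(rng.normal(0.0, spec.bg_noise_sd, size=m.shape)), clamp)
    fg_vals = spec.fg_level + rng.normal(0.0, spec.fg_noise_sd, size=int(m.sum()))
    prob[m] = fg_vals

    pts, _, is_gap = _all_points(truth)
    if is_gap.any():
        vox = np.argwhere(m)
        _, nearest = cKDTree(pts).query(vox, workers=1)
        gap_vox = vox[is_gap[nearest]]
        idx = tuple(gap_vox.T)
        if spec.gap_level is None:
            prob[idx] = np.minimum(
                np.abs(rng.normal(0.0, spec.bg_noise_sd, size=len(gap_vox))), clamp
            )
        else:
            prob[idx] = spec.gap_level
    if spec.blur_sigma > 0:
        prob = ndimage.gaussian_filter(prob, spec.blur_sigma)
    np.clip(prob, 0.0, 1.0, out=prob)
    return Volume(prob, kind="probability")


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Volume, PhantomTruth]:
    """Full pipeline: sample geometry, place gaps, rasterize, paint probability.

    Returns ``(probability, mask, truth)``; byte-identical output for an
    identical spec (a single seeded RNG stream drives everything).
    """
    truth = sample_centerline_forest(spec)
    gap_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    place_gaps(truth, spec, gap_rng)
    mask = rasterize_tubes(truth)
    prob = synthesize_probability(mask, truth, spec)
    return prob, mask, truth
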