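"""From probability map to traceable segmentation.

A CNN-style neurite probability map is thresholded adaptively: background
statistics are estimated from the sub-population of voxels with probability
below 0.5, the foreground threshold is ``mu_bg + lambda * sigma_bg``, and the
resulting mask is labelled into 26-connected components, one seed voxel per
component.  The module also provides the hybrid Dice + weighted cross-entropy
training loss as a pure function, and the low threshold ``t_l`` used by the
gap-bridging corridor term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import Volume

__all__ = [
    "BackgroundStats",
    "Segmentation",
    "LossInputs",
    "hybrid_loss",
    "background_stats",
    "initial_segmentation",
    "select_seeds",
    "low_threshold",
    "STRUCTURE_26",
]

# full 3x3x3 neighbourhood: face, edge and corner adjacency
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)

_LOG_CLIP = 1e-7


@dataclass(frozen=True)
class BackgroundStats:
    """Moments of the background probability sub-population (values < 0.5)."""

    mu_bg: float
    sigma_bg: float
    n_bg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_bg < 0.5):
            raise ValueError(f"mu_bg must lie in [0, 0.5), got {self.mu_bg}")
        if self.sigma_bg < 0:
            raise ValueError("sigma_bg must be non-negative")


@dataclass
class Segmentation:
    """Initial foreground segmentation of a probability map.

    ``labels`` holds 26-connected component ids 1..K (0 = background), and
    ``seeds`` one voxel per component, keyed by label.
    """

    mask: Volume
    labels: Volume
    threshold_used: float
    seeds: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.seeds)


@dataclass
class LossInputs:
    """Inputs to the hybrid segmentation loss.

    ``p`` are predicted probabilities, ``g`` binary ground-truth labels over
    the same m voxels.  ``epsilon`` smooths the Dice term; ``sigma_w`` weights
    the cross-entropy term (default 0.5).
    """

    p: np.ndarray
    g: np.ndarray
    epsilon: float = 1e-5
    sigma_w: float = 0.5

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).ravel()
        self.g = np.asarray(self.g, dtype=float).ravel()
        if self.p.shape != self.g.shape:
            raise ValueError(
                f"p and g must have the same length, got {self.p.size} vs {self.g.size}"
            )
        if self.p.size < 1:
            raise ValueError("need at least one voxel")
        if self.p.min() < 0 or self.p.max() > 1:
            raise ValueError("p must lie in [0, 1]")
        if not np.isin(self.g, (0.0, 1.0)).all():
            raise ValueError("g must be binary")


def hybrid_loss(inputs: LossInputs) -> float:
    """Dice loss plus foreground-weighted cross-entropy.

    ``loss = (1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + 1))
    + sigma_w * sum_i[(sum(g)/m) * g_i * (-log p_i)]``

    The log is clamped by clipping p to [1e-7, 1], so the loss is finite for
    any valid input.
    """
    p, g = inputs.p, inputs.g
    m = p.size
    dice = 1.0 - (2.0 * float(p @ g) + inputs.epsilon) / (float(p.sum()) + float(g.sum()) + 1.0)
    w = float(g.sum()) / m
    ce = float(np.sum(-w * g * np.log(np.clip(p, _LOG_CLIP, 1.0))))
    return dice + inputs.sigma_w * ce


def background_stats(prob: Volume) -> BackgroundStats:
    """Estimate background mean/SD from voxels with probability < 0.5.

    Uses the sample moments of the sub-population directly (population SD,
    ddof=0) — for a Gaussian background this matches a Gaussian fit to the
    sub-0.5 histogram in expectation, without binning.
    """
    values = np.asarray(prob.values, dtype=float)
    bg = values[values < 0.5]
    if bg.size == 0:
        raise ValueError("no background voxels (all probabilities >= 0.5)")
    return BackgroundStats(float(bg.mean()), float(bg.std()), int(bg.size))


def initial_segmentation(prob: Volume, lam: float = 3.0) -> Segmentation:
    """Threshold a probability map at ``mu_bg + lam * sigma_bg`` and label it.

    Components are labelled with 26-connectivity; the seed of each component
    is its first foreground voxel in lexicographic (z, y, x) scan order.  An
    above-maximum threshold yields an empty segmentation with a warning, not
    an error.
    """
    stats = background_stats(prob)
    threshold = stats.mu_bg + lam * stats.sigma_bg
    values = np.asarray(prob.values, dtype=float)
    mask = values > threshold
    if not mask.any():
        warnings.warn(
            f"threshold {threshold:.4g} >= max probability {values.max():.4g}: "
            "empty segmentation",
            stacklevel=2,
        )
    labels, _ = ndimage.label(mask, structure=STRUCTURE_26)
    seg = Segmentation(
        mask=Volume(mask.astype(np.uint8), spacing=prob.spacing, kind="mask"),
        labels=Volume(labels.astype(np.int32), spacing=prob.spacing, kind="labels"),
        threshold_used=float(threshold),
    )
    seg.seeds = select_seeds(seg)
    return seg


def select_seeds(seg: Segmentation) -> dict[int, tuple[int, int, int]]:
    """First foreground voxel of each component in (z, y, x) scan order."""
    labels = seg.labels.values
    flat = labels.ravel()  # C order == lexicographic (z, y, x)
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return {}
    uniq, first = np.unique(flat[nz], return_index=True)
    seeds: dict[int, tuple[int, int, int]] = {}
    for lab, idx in zip(uniq, nz[first]):
        z, y, x = np.unravel_index(idx, labels.shape)
        seeds[int(lab)] = (int(z), int(y), int(x))
    return seeds


def low_threshold(prob: Volume, cap: float = 0.1) -> float:
    """Corridor threshold ``t_l``: median of the sub-0.5 population, capped.

    ``t_l`` is the smallest probability value t such that at least half of the
    voxels with probability <= 0.5 satisfy v <= t, then refined as
    ``min(cap, t_l)`` (cap defaults to 0.1).  Excludes at least 50% of
    background noise from being counted as neurite by the corridor term.
    """
    values = np.asarray(prob.values, dtype=float).ravel()
    sub = np.sort(values[values <= 0.5])
    if sub.size == 0:
        raise ValueError("no voxels with probability <= 0.5")
    t = float(sub[int(np.ceil(sub.size / 2)) - 1])
    return min(cap, t)
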