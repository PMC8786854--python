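"""Whole-image inference and post-processing.

An image is processed as overlapping tiles (default 512 px, stride 64):
every tile is histogram-equalized, run through the network and argmaxed;
each pixel's final class is the plurality of the hard labels predicted
by the tiles covering it, so an interior pixel receives up to
``(t/s)**2 = 64`` votes.  Vote ties are broken toward
border > fiber > background, preserving instance separation at junctions.

The class map becomes an instance map in four steps: border pixels are
reassigned to background (keeping them as fiber would merge touching
fibers); 8-connected fiber components are labeled; components smaller
than ``min_instance_px`` (strictly, so an area of exactly 50 survives
the default) are dropped; and every instance is grown back over its
removed border by up to ``max_dilation`` simultaneous 1-px dilation
rounds, reverting a round's growth for any instance that would become
8-adjacent to another instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BACKGROUND, BORDER, FIBER, STRUCT8, ClassMap, GrayImage, InstanceMap
from .labels import equalize_tile


@dataclass
class InferenceConfig:
    tile_size: int = 512
    stride: int = 64
    min_instance_px: int = 50
    max_dilation: int = 5

    def validate(self) -> None:
        if not (1 <= self.stride <= self.tile_size):
            raise ValueError("stride must satisfy 1 <= s <= t")
        if self.min_instance_px < 0 or self.max_dilation < 0:
            raise ValueError("min_instance_px and max_dilation must be >= 0")


def tile_grid(image_shape, tile_size: int, stride: int) -> list[tuple[int, int]]:
    """Origins of the overlapping tile windows covering an image.

    Origins advance by ``stride``; the last row/column of tiles is
    clamped to end exactly at the image edge, so every pixel is covered.
    """
    h, w = image_shape
    if tile_size > h or tile_size > w:
        raise ValueError(f"tile size {tile_size} exceeds image shape {image_shape}")

    def axis_origins(n):
        origins = list(range(0, n - tile_size + 1, stride))
        if origins[-1] != n - tile_size:
            origins.append(n - tile_size)
        return origins

    return [(r, c) for r in axis_origins(h) for c in axis_origins(w)]


def predict_image(model, image: GrayImage, cfg: InferenceConfig) -> ClassMap:
    """Tile-by-tile prediction with per-pixel majority voting.

    ``model`` maps a float tile of shape (t, t) scaled to [0, 1] to a
    (3, t, t) class-probability array (any callable with that contract
    works, including the stub predictors used in tests).
    """
    cfg.validate()
    t = cfg.tile_size
    votes = np.zeros((3,) + image.shape, dtype=np.int32)
    for r, c in tile_grid(image.shape, t, cfg.stride):
        tile = equalize_tile(image.pixels[r:r + t, c:c + t])
        probs = model(tile.astype(np.float64) / 255.0)
        hard = np.argmax(probs, axis=0)
        for cls in (BACKGROUND, FIBER, BORDER):
            votes[cls, r:r + t, c:c + t] += hard == cls
    return ClassMap(majority_vote(votes))


def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Per-pixel plurality over per-class vote counts.

    ``votes`` has shape (3, H, W).  Ties are resolved by the priority
    border > fiber > background.
    """
    best = np.full(votes.shape[1:], BACKGROUND, dtype=np.uint8)
    best_count = votes[BACKGROUND].copy()
    for cls in (FIBER, BORDER):  # later classes win ties
        take = votes[cls] >= best_count
        best[take] = cls
        best_count[take] = votes[cls][take]
    return best


def postprocess(classmap: ClassMap, cfg: InferenceConfig) -> InstanceMap:
    """Class map -> instance map: border removal, components, size filter,
    touch-reverting dilation."""
    cfg.validate()
    fiber = classmap.classes == FIBER  # border pixels fall to background
    labels, _ = ndimage.label(fiber, structure=STRUCT8)
    labels = _remove_small(labels, cfg.min_instance_px)
    labels = _relabel_sequential(labels)
    labels = dilate_instances(labels, cfg.max_dilation)
    return InstanceMap(labels)


def _remove_small(labels: np.ndarray, min_px: int) -> np.ndarray:
    if min_px <= 0 or labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    kill = counts < min_px  # strict: area == min_px survives
    kill[0] = False
    out = labels.copy()
    out[kill[labels]] = 0
    return out


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1)
    return lut[labels]


def dilate_instances(labels: np.ndarray, max_rounds: int) -> np.ndarray:
    """Simultaneous touch-reverting dilation, one pixel per round.

    Each round every instance is dilated by one pixel (8-connectivity);
    the round's growth is then reverted for every instance that would be
    8-adjacent to (or overlap) another instance, re-checking until the
    set of accepted growths is stable.  Reverting only shrinks masks, so
    the inner loop terminates and the result is order-independent.
    """
    labels = labels.astype(np.int32, copy=True)
    n = labels.max()
    if n == 0 or max_rounds <= 0:
        return labels
    boxes = ndimage.find_objects(labels)
    masks = {}
    for lab, sl in enumerate(boxes, start=1):
        if sl is not None:
            masks[lab] = [labels[sl] == lab, sl]

    h, w = labels.shape
    for _ in range(max_rounds):
        cand = {}
        for lab, (mask, sl) in masks.items():
            r0 = max(0, sl[0].start - 1)
            r1 = min(h, sl[0].stop + 1)
            c0 = max(0, sl[1].start - 1)
            c1 = min(w, sl[1].stop + 1)
            nsl = (slice(r0, r1), slice(c0, c1))
            big = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            big[sl[0].start - r0:sl[0].stop - r0, sl[1].start - c0:sl[1].stop - c0] = mask
            cand[lab] = [ndimage.binary_dilation(big, STRUCT8), nsl]

        # offenders are found at the full simultaneous-growth state and all
        # reverted at once; a reverted mask is a subset of its grown mask, so
        # it cannot touch any accepted growth (that growth would itself have
        # been offending) and the result is order-independent.
        ids = sorted(masks)
        offenders = set()
        for i, lab in enumerate(ids):
            for other in ids[i + 1:]:
                if _adjacent(*cand[lab], *cand[other]):
                    offenders.add(lab)
                    offenders.add(other)

        grown = [lab for lab in ids if lab not in offenders]
        if not grown:
            break
        for lab in grown:
            masks[lab] = cand[lab]

    out = np.zeros_like(labels)
    for lab, (mask, sl) in masks.items():
        out[sl][mask] = lab
    return out


def _adjacent(mask_a, sl_a, mask_b, sl_b) -> bool:
    """True when the two masks overlap or are 8-adjacent."""
    # bounding-box prefilter with a 1-px guard band
    if (
        sl_a[0].start > sl_b[0].stop
        or sl_b[0].start > sl_a[0].stop
        or sl_a[1].start > sl_b[1].stop
        or sl_b[1].start > sl_a[1].stop
    ):
        return False
    r0 = min(sl_a[0].start, sl_b[0].start)
    r1 = max(sl_a[0].stop, sl_b[0].stop)
    c0 = min(sl_a[1].start, sl_b[1].start)
    c1 = max(sl_a[1].stop, sl_b[1].stop)
    a = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    b = np.zeros_like(a)
    a[sl_a[0].start - r0:sl_a[0].stop - r0, sl_a[1].start - c0:sl_a[1].stop - c0] = mask_a
    b[sl_b[0].start - r0:sl_b[0].stop - r0, sl_b[1].start - c0:sl_b[1].stop - c0] = mask_b
    if (a & b).any():
        return True
    return (ndimage.binary_dilation(a, STRUCT8) & b).any()
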