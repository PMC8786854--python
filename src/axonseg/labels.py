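"""Training-label preparation: three-class maps, shape scores, tile sampling.

The network is trained on a three-class target — background, fiber, and a
*border* band around each fiber's outer edge — so that merge errors
between touching fibers are explicitly penalized.  Training tiles are
drawn by one of four strategies; the default biases sampling toward
large and elongated fibers through the area-circularity score
``s = A * C`` with ``C = 4*pi*A / P**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import BORDER, FIBER, STRUCT8, ClassMap, GrayImage, InstanceMap

STRATEGIES = ("random", "fiber_centered", "proportional", "area_based")
FLIPS = ("none", "horizontal", "vertical", "both")


@dataclass(frozen=True)
class TileSpec:
    """One training-tile window: center, size, flip variant, source fiber."""

    center_row: int
    center_col: int
    size: int
    flips: str = "none"
    source_label: int | None = None
    augmented: bool = False


@dataclass(frozen=True)
class FiberShape:
    """Area, perimeter, circularity and sampling score of one instance."""

    label_id: int
    area: float
    perimeter: float
    circularity: float
    score: float


# ---------------------------------------------------------------------------
# class maps


def instance_to_classmap(mask: InstanceMap, border_width: int = 2) -> ClassMap:
    """Convert an instance map to the {background, fiber, border} raster.

    The border band is the outward 8-connectivity dilation of the fiber
    support by ``border_width`` pixels, clipped at image edges and at
    other fibers' interiors; fiber pixels keep the fiber class.
    """
    if border_width < 1:
        raise ValueError("border_width must be >= 1")
    fiber = mask.labels > 0
    grown = ndimage.binary_dilation(fiber, STRUCT8, iterations=border_width)
    classes = np.zeros(mask.shape, dtype=np.uint8)
    classes[grown] = BORDER
    classes[fiber] = FIBER
    return ClassMap(classes)


def classmap_no_border(mask: InstanceMap) -> ClassMap:
    """Two-class variant used by the no-border ablation: border merged into fiber."""
    classes = np.zeros(mask.shape, dtype=np.uint8)
    classes[mask.labels > 0] = FIBER
    return ClassMap(classes)


# ---------------------------------------------------------------------------
# shape scores


def shape_score(mask: InstanceMap, label_id: int) -> FiberShape:
    """Area, Crofton perimeter, circularity C = 4*pi*A/P^2 and score s = A*C.

    The perimeter estimator is the 4-direction Crofton formula
    (``skimage.measure.perimeter_crofton``): it is asymptotically exact
    for disks, which keeps the circularity of rasterized round fibers at
    ~1, at the price of a known upward bias of C for axis-aligned
    rectangles.
    """
    support = mask.labels == label_id
    if label_id <= 0 or not support.any():
        raise ValueError(f"label {label_id} not present in the instance map")
    area = float(support.sum())
    perimeter = float(measure.perimeter_crofton(support, directions=4))
    circ = 4.0 * np.pi * area / perimeter**2
    return FiberShape(label_id, area, perimeter, circ, area * circ)


def shape_scores(mask: InstanceMap) -> list[FiberShape]:
    return [shape_score(mask, int(lab)) for lab in mask.ids]


# ---------------------------------------------------------------------------
# tile sampling


def _clamp_center(center_row, center_col, size, shape):
    half_lo = size // 2
    half_hi = size - half_lo  # window rows [c-half_lo, c+half_hi)
    r = int(np.clip(center_row, half_lo, shape[0] - half_hi))
    c = int(np.clip(center_col, half_lo, shape[1] - half_hi))
    return r, c


def tile_window(spec: TileSpec, shape) -> tuple[slice, slice]:
    """The t-by-t slices of a spec's window after boundary clamping."""
    r, c = _clamp_center(spec.center_row, spec.center_col, spec.size, shape)
    lo = spec.size // 2
    return slice(r - lo, r - lo + spec.size), slice(c - lo, c - lo + spec.size)


def _centroids_px(mask: InstanceMap) -> dict[int, tuple[float, float]]:
    ids = mask.ids
    if ids.size == 0:
        return {}
    coms = ndimage.center_of_mass(mask.labels > 0, mask.labels, ids)
    return {int(lab): com for lab, com in zip(ids, coms)}


def sample_tiles(
    image: GrayImage,
    mask: InstanceMap,
    strategy: str,
    n_tiles: int,
    tile_size: int = 512,
    seed: int = 0,
) -> list[TileSpec]:
    """Draw ``n_tiles`` tile windows by the requested strategy.

    ``random`` places windows uniformly; ``fiber_centered`` (and
    ``proportional``, whose proportionality acts at the per-image
    allocation level, see :func:`proportional_allocation`) centers tiles
    on uniformly chosen instances; ``area_based`` draws instances from a
    multinomial with probabilities ``s_i / sum(s_j)`` and flags repeated
    draws for augmentation.  All windows are clamped inside the image.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    h, w = image.shape
    if tile_size > min(h, w):
        raise ValueError("tile_size exceeds image dimensions")
    rng = np.random.default_rng(seed)

    if strategy == "random":
        rows = rng.integers(0, h, size=n_tiles)
        cols = rng.integers(0, w, size=n_tiles)
        return [
            TileSpec(*_clamp_center(r, c, tile_size, (h, w)), tile_size)
            for r, c in zip(rows, cols)
        ]

    centroids = _centroids_px(mask)
    if not centroids:
        raise ValueError("no annotated instances for instance-centered sampling")
    ids = np.array(sorted(centroids))

    if strategy in ("fiber_centered", "proportional"):
        chosen = rng.choice(ids, size=n_tiles, replace=True)
    else:  # area_based
        scores = np.array([shape_score(mask, int(i)).score for i in ids])
        probs = scores / scores.sum()
        counts = rng.multinomial(n_tiles, probs)
        chosen = np.repeat(ids, counts)

    seen: dict[int, int] = {}
    specs = []
    for lab in chosen:
        lab = int(lab)
        reps = seen.get(lab, 0)
        seen[lab] = reps + 1
        r, c = _clamp_center(*centroids[lab], tile_size, (h, w))
        specs.append(
            TileSpec(r, c, tile_size, source_label=lab, augmented=reps > 0)
        )
    return specs


def proportional_allocation(image_areas, total_tiles, cap=None):
    """Per-image tile counts scaled by image area, then capped.

    This is the allocation rule of the ``proportional`` strategy: tiles
    are split across images in proportion to pixel area, each image's
    share truncated at ``cap`` when given.
    """
    areas = np.asarray(image_areas, dtype=float)
    counts = np.floor(total_tiles * areas / areas.sum()).astype(int)
    if cap is not None:
        counts = np.minimum(counts, cap)
    return counts


# ---------------------------------------------------------------------------
# augmentation


def augment_tile(
    spec: TileSpec, mask: InstanceMap, policy: str, seed: int = 0
) -> list[TileSpec]:
    """Expand one tile spec by jitter or flips.

    ``center_jitter`` emits exactly 10 specs whose centers are uniformly
    drawn pixels of the source instance (valid only when the instance's
    bounding box exceeds the tile size); ``flips`` emits the 4 flip
    variants of the spec.
    """
    if policy == "flips":
        return [replace(spec, flips=f) for f in FLIPS]
    if policy != "center_jitter":
        raise ValueError(f"unknown augmentation policy {policy!r}")
    if spec.source_label is None:
        raise ValueError("center_jitter requires a source instance")
    support = mask.labels == spec.source_label
    if not support.any():
        raise ValueError(f"label {spec.source_label} not present in the mask")
    sl = ndimage.find_objects(support.astype(np.int8))[0]
    bbox_h = sl[0].stop - sl[0].start
    bbox_w = sl[1].stop - sl[1].start
    if max(bbox_h, bbox_w) <= spec.size:
        raise ValueError(
            "center_jitter is reserved for fibers whose bounding box exceeds "
            f"the tile size ({spec.size}); got bbox {bbox_h}x{bbox_w}"
        )
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(support)
    idx = rng.integers(0, rows.size, size=10)
    return [
        replace(
            spec,
            center_row=_clamp_center(rows[i], cols[i], spec.size, mask.shape)[0],
            center_col=_clamp_center(rows[i], cols[i], spec.size, mask.shape)[1],
            augmented=True,
        )
        for i in idx
    ]


def apply_flip(tile: np.ndarray, flips: str) -> np.ndarray:
    if flips == "none":
        return tile
    if flips == "horizontal":
        return tile[:, ::-1]
    if flips == "vertical":
        return tile[::-1, :]
    if flips == "both":
        return tile[::-1, ::-1]
    raise ValueError(f"unknown flip variant {flips!r}")


# ---------------------------------------------------------------------------
# equalization and class weights


def equalize_tile(tile: np.ndarray) -> np.ndarray:
    """Standard 8-bit CDF histogram equalization of one tile.

    Maps intensity v to ``round(cdf(v) * 255)``; a constant tile is
    returned unchanged (its CDF inverse is undefined and equalizing it
    would inject contrast that is not in the data).
    """
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValueError("empty tile")
    if tile.dtype != np.uint8:
        raise ValueError("equalize_tile expects 8-bit input")
    if tile.min() == tile.max():
        return tile.copy()
    hist = np.bincount(tile.ravel(), minlength=256)
    cdf = np.cumsum(hist) / tile.size
    lut = np.round(cdf * 255.0).astype(np.uint8)
    return lut[tile]


def class_weights(classmaps) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    Aggregates pixel counts over all maps; fails naming the class if one
    of {background, fiber, border} never occurs.  With its small
    footprint the border class receives the largest weight.
    """
    counts = np.zeros(3, dtype=np.int64)
    for cm in classmaps:
        counts += np.bincount(np.asarray(cm.classes).ravel(), minlength=3)[:3]
    names = ("background", "fiber", "border")
    for c, name in zip(counts, names):
        if c == 0:
            raise ValueError(f"class {name!r} absent from all maps")
    freq = counts / counts.sum()
    w = 1.0 / freq
    return w / w.mean()
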