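"""Seeded synthetic TEM-like fixtures with ground-truth instance maps.

Real TEM mosaics of peripheral nerve cross-sections show unmyelinated
fibers (UMFs) of widely varying size, shape and contrast: round to
elongated profiles, fibers clumped into Remak-bundle-like islands with
only thin separating gaps, myelinated-fiber and vesicle look-alikes, and
stitching-seam intensity steps between mosaic tiles.  This module renders
those failure modes deterministically so the whole pipeline can be
exercised and tested without microscope data.

Fibers are filled superellipses with a smooth radial intensity gradient
toward a 1-2 px rim of opposite polarity, mimicking the plasma-membrane
contour that makes fiber/background boundaries ambiguous.  Distractors
(myelinated rings, nuclei, vesicle clusters) are drawn into the intensity
image only and never receive an instance label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import STRUCT8, GrayImage, InstanceMap

CONTRAST_MODES = ("dark_fibers", "light_fibers", "low_contrast")

#: background / fiber mean intensity per contrast mode (8-bit units)
_CONTRAST_LEVELS = {
    "dark_fibers": (185.0, 95.0),
    "light_fibers": (75.0, 170.0),
    "low_contrast": (150.0, 122.0),
}


@dataclass
class FixtureConfig:
    """Parameters of one synthetic image/instance-map pair.

    Attributes
    ----------
    image_height, image_width : int
        Raster size in pixels.
    n_fibers : int
        Number of fibers to attempt to place.
    radius_range : (float, float)
        Semi-major axis range in pixels.
    elongation_range : (float, float)
        Axis-ratio range (>= 1); 1 is a circle.
    clump_fraction : float
        Share of fibers packed into islands separated by 1-3 px gaps.
    n_distractors : int
        Count of myelinated-ring / nucleus / vesicle mimics.
    contrast_mode : str
        One of ``dark_fibers``, ``light_fibers``, ``low_contrast``.
    seam_artifacts : bool
        Add a mosaic-seam intensity step along one vertical line.
    noise_sd : float
        Standard deviation of additive Gaussian intensity noise.
    resolution_nm_per_px : float
        Physical scale attached to the output image.
    seed : int
        RNG seed; identical configs give bit-identical outputs.
    """

    image_height: int = 512
    image_width: int = 512
    n_fibers: int = 40
    radius_range: tuple[float, float] = (5.0, 18.0)
    elongation_range: tuple[float, float] = (1.0, 2.5)
    clump_fraction: float = 0.3
    n_distractors: int = 5
    contrast_mode: str = "dark_fibers"
    seam_artifacts: bool = False
    noise_sd: float = 6.0
    resolution_nm_per_px: float = 11.9
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("radius_range must be positive and ordered")
        if 2 * hi >= min(self.image_height, self.image_width):
            raise ValueError(
                f"largest fiber (diameter {2 * hi:.0f} px) does not fit in a "
                f"{self.image_height}x{self.image_width} image"
            )
        elo, ehi = self.elongation_range
        if not (1.0 <= elo <= ehi):
            raise ValueError("elongation_range must be >= 1 and ordered")
        if not (0.0 <= self.clump_fraction <= 1.0):
            raise ValueError("clump_fraction must lie in [0, 1]")
        if self.n_distractors < 0:
            raise ValueError("n_distractors must be non-negative")
        if self.contrast_mode not in CONTRAST_MODES:
            raise ValueError(f"unknown contrast_mode {self.contrast_mode!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _superellipse_mask(shape, center, a, b, theta, exponent):
    """Boolean mask of a rotated superellipse |x/a|^m + |y/b|^m <= 1."""
    h, w = shape
    r0 = int(max(0, np.floor(center[0] - a - 2)))
    r1 = int(min(h, np.ceil(center[0] + a + 3)))
    c0 = int(max(0, np.floor(center[1] - a - 2)))
    c1 = int(min(w, np.ceil(center[1] + a + 3)))
    if r0 >= r1 or c0 >= c1:
        return None, None
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - center[0]
    dx = cc - center[1]
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    inside = (np.abs(u / a) ** exponent + np.abs(v / b) ** exponent) <= 1.0
    return inside, (slice(r0, r1), slice(c0, c1))


def _sample_shape(rng, config):
    a = rng.uniform(*config.radius_range)
    elong = rng.uniform(*config.elongation_range)
    b = max(1.5, a / elong)
    theta = rng.uniform(0, np.pi)
    exponent = rng.uniform(1.8, 3.5)
    return a, b, theta, exponent


def _try_place(labels, blocked, rng, config, center_sampler, gap):
    """Dart-throwing placement of one fiber; returns its mask slices or None."""
    h, w = labels.shape
    for _ in range(100):
        a, b, theta, exponent = _sample_shape(rng, config)
        center = center_sampler(a)
        if not (a <= center[0] <= h - 1 - a and a <= center[1] <= w - 1 - a):
            continue
        mask, sl = _superellipse_mask(labels.shape, center, a, b, theta, exponent)
        if mask is None or not mask.any():
            continue
        if blocked[sl][mask].any():
            continue
        return mask, sl, gap
    return None


def generate_fiber_field(config: FixtureConfig) -> tuple[GrayImage, InstanceMap]:
    """Render one synthetic TEM-like image and its instance map.

    Fibers are placed by dart-throwing with at most 100 retries each; a
    configurable share is packed into clump islands whose members are
    separated by 1-3 px background gaps.  Distractors appear in the image
    but never in the instance map.  Returns fewer instances than
    ``config.n_fibers`` (with a warning) when placement saturates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    labels = np.zeros((h, w), dtype=np.int32)
    # pixels no new fiber may touch: existing fibers dilated by their gap
    blocked = np.zeros((h, w), dtype=bool)

    n_clumped = int(round(config.clump_fraction * config.n_fibers))
    n_free = config.n_fibers - n_clumped

    placements = []  # (mask, slices)
    next_id = 1

    def commit(mask, sl, gap):
        nonlocal next_id
        labels[sl][mask] = next_id
        canvas = np.zeros((h, w), dtype=bool)
        canvas[sl] = mask
        blocked[:] |= ndimage.binary_dilation(canvas, STRUCT8, iterations=gap)
        placements.append((mask, sl))
        next_id += 1

    r_hi = config.radius_range[1]
    placed = 0

    # clump islands: groups of fibers packed around a common center
    remaining = n_clumped
    while remaining > 0:
        island_n = int(min(remaining, rng.integers(3, 9)))
        island_r = r_hi * (1.2 + 0.55 * island_n)
        ic = (
            rng.uniform(island_r, max(island_r + 1, h - island_r)),
            rng.uniform(island_r, max(island_r + 1, w - island_r)),
        )

        def island_sampler(a, ic=ic, island_r=island_r):
            ang = rng.uniform(0, 2 * np.pi)
            rad = island_r * np.sqrt(rng.uniform())
            return (ic[0] + rad * np.sin(ang), ic[1] + rad * np.cos(ang))

        for _ in range(island_n):
            gap = int(rng.integers(1, 4))
            hit = _try_place(labels, blocked, rng, config, island_sampler, gap)
            if hit is not None:
                commit(*hit)
                placed += 1
        remaining -= island_n

    # free fibers anywhere in the frame
    def free_sampler(a):
        return (rng.uniform(a, h - 1 - a), rng.uniform(a, w - 1 - a))

    for _ in range(n_free):
        gap = int(rng.integers(1, 4))
        hit = _try_place(labels, blocked, rng, config, free_sampler, gap)
        if hit is not None:
            commit(*hit)
            placed += 1

    if placed < config.n_fibers:
        warnings.warn(
            f"placement saturated: {placed}/{config.n_fibers} fibers placed",
            stacklevel=2,
        )

    image = _render_intensity(labels, placements, rng, config)
    return GrayImage(image, config.resolution_nm_per_px), InstanceMap(labels)


def _render_intensity(labels, placements, rng, config):
    h, w = labels.shape
    bg_level, fiber_level = _CONTRAST_LEVELS[config.contrast_mode]

    # correlated background texture so random tiles are non-trivial
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0)
    sd = texture.std()
    if sd > 0:
        texture /= sd
    img = bg_level + 9.0 * texture

    rim_sign = 1.0 if fiber_level < bg_level else -1.0  # rim darker than fill

    for k, (mask, sl) in enumerate(placements, start=1):
        dist = ndimage.distance_transform_edt(mask)
        dmax = max(dist.max(), 1.0)
        level = fiber_level + rng.uniform(-18.0, 18.0)
        rim_w = rng.uniform(1.0, 2.0)
        rim = mask & (dist <= rim_w)
        interior = level + 14.0 * (dist / dmax - 0.5)  # center/edge gradient
        patch = img[sl]
        patch[mask] = interior[mask]
        patch[rim] = level - rim_sign * rng.uniform(25.0, 45.0)
        img[sl] = patch

    _draw_distractors(img, labels, rng, config)

    if config.seam_artifacts:
        col = int(rng.integers(w // 4, 3 * w // 4))
        img[:, col:] += rng.uniform(12.0, 25.0) * rng.choice([-1.0, 1.0])

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _draw_distractors(img, labels, rng, config):
    """Myelinated-ring / nucleus / vesicle mimics, image-only (never labeled)."""
    h, w = img.shape
    occupied = ndimage.binary_dilation(labels > 0, STRUCT8, iterations=2)
    kinds = rng.choice(["ring", "nucleus", "vesicles"], size=config.n_distractors)
    for kind in kinds:
        for _ in range(50):
            r = rng.uniform(*config.radius_range) * (1.4 if kind != "vesicles" else 0.8)
            cy = rng.uniform(r + 1, h - r - 2)
            cx = rng.uniform(r + 1, w - r - 2)
            mask, sl = _superellipse_mask(img.shape, (cy, cx), r, r * 0.9, 0.0, 2.0)
            if mask is None or occupied[sl][mask].any():
                continue
            patch = img[sl]
            if kind == "ring":
                # myelinated fiber: bright axoplasm in a thick dark sheath
                dist = ndimage.distance_transform_edt(mask)
                sheath = mask & (dist <= max(2.0, 0.35 * r))
                patch[mask] = 205.0
                patch[sheath] = 25.0
            elif kind == "nucleus":
                dist = ndimage.distance_transform_edt(mask)
                tex = ndimage.gaussian_filter(
                    rng.standard_normal(patch.shape), 1.5
                )
                patch[mask] = 110.0 + 22.0 * tex[mask] - 10.0 * (
                    dist[mask] / max(dist.max(), 1.0)
                )
            else:  # vesicle cluster: a handful of small dark dots
                n_dots = int(rng.integers(3, 8))
                for _ in range(n_dots):
                    dr = rng.uniform(1.5, 3.0)
                    oy = rng.uniform(-r * 0.6, r * 0.6)
                    ox = rng.uniform(-r * 0.6, r * 0.6)
                    dm, dsl = _superellipse_mask(
                        img.shape, (cy + oy, cx + ox), dr, dr, 0.0, 2.0
                    )
                    if dm is not None:
                        img[dsl][dm] = 60.0
            img[sl] = patch
            break


def standard_suite_configs(seed: int = 0) -> dict[str, FixtureConfig]:
    """The five canonical fixture conditions used across the test-bench.

    One image per contrast mode, one heavily clumped image, and one image
    with a mosaic-seam artifact; seeds are derived from ``seed``.
    """
    base = dict(image_height=512, image_width=512, n_fibers=40)
    return {
        "dark_fibers": FixtureConfig(**base, contrast_mode="dark_fibers", seed=seed),
        "light_fibers": FixtureConfig(**base, contrast_mode="light_fibers", seed=seed + 1),
        "low_contrast": FixtureConfig(**base, contrast_mode="low_contrast", seed=seed + 2),
        "clumped": FixtureConfig(
            **base, contrast_mode="dark_fibers", clump_fraction=0.9, seed=seed + 3
        ),
        "seam": FixtureConfig(
            **base, contrast_mode="dark_fibers", seam_artifacts=True, seed=seed + 4
        ),
    }


def make_fixture_suite(out_dir, seed: int = 0):
    """Write the standard fixture suite to ``out_dir``; returns the manifest.

    Writes one 8-bit image and one 16-bit instance map per condition plus
    ``manifest.csv`` with columns (name, image_path, mask_path, seed,
    n_fibers, resolution_nm_per_px).
    """
    import pandas as pd

    from . import fileio

    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, cfg in standard_suite_configs(seed).items():
        image, mask = generate_fiber_field(cfg)
        img_path = out / f"{name}.png"
        mask_path = out / f"{name}_mask.png"
        fileio.write_image(img_path, image)
        fileio.write_instance_map(mask_path, mask)
        rows.append(
            {
                "name": name,
                "image_path": str(img_path),
                "mask_path": str(mask_path),
                "seed": cfg.seed,
                "n_fibers": mask.n_instances,
                "resolution_nm_per_px": cfg.resolution_nm_per_px,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
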