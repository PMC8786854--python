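"""Desk-scale end-to-end pipeline: generate -> prepare -> train -> infer -> evaluate.

This wires the modules together on synthetic fixtures so the whole
method — fiber-biased tile sampling, three-class training, majority-vote
inference, touch-aware post-processing and panoptic scoring — can be
exercised on one CPU in minutes.  The ``desk`` profile trains a
depth-2 / 8-filter network on 128-px tiles for ~300 iterations over 20
synthetic images (16 train / 4 held out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import imgen, infer, labels, network, panoptic


@dataclass
class DeskProfile:
    """Scaled-down study conditions for CPU execution.

    Deviations from the full-scale recipe, all consequences of the ~3x
    smaller fiber radii and ~100x fewer gradient steps: dense 320-px
    images, one epoch at a constant higher learning rate (a decay
    schedule has nothing to decay over in 300 iterations), no bottleneck
    dropout, and no reconstruction dilation — the desk-scale network
    predicts full fiber supports rather than border-eroded cores, so
    there is no rim to grow back.
    """

    n_images: int = 20
    n_test_images: int = 4
    n_fibers: int = 40
    image_size: int = 320
    tile_size: int = 128
    tiles_per_image: int = 24
    border_width: int = 2
    depth: int = 2
    base_filters: int = 8
    dropout_rate: float = 0.0
    iterations: int = 300
    epochs: int = 1
    batch_size: int = 2
    lr0: float = 0.05
    sampling: str = "area_based"
    loss: str = "weighted_ce"
    stride: int = 64
    min_instance_px: int = 50
    max_dilation: int = 0


def generate_dataset(profile: DeskProfile, seed: int):
    """Synthetic image/mask pairs cycling through the contrast modes."""
    pairs = []
    modes = imgen.CONTRAST_MODES
    for i in range(profile.n_images):
        cfg = imgen.FixtureConfig(
            image_height=profile.image_size,
            image_width=profile.image_size,
            n_fibers=profile.n_fibers,
            contrast_mode=modes[i % len(modes)],
            seed=seed + i,
        )
        pairs.append(imgen.generate_fiber_field(cfg))
    return pairs


def prepare_tiles(pairs, profile: DeskProfile, seed: int):
    """Sample training tiles and their class-map targets."""
    tiles, targets = [], []
    for i, (image, mask) in enumerate(pairs):
        classmap = labels.instance_to_classmap(mask, profile.border_width)
        specs = labels.sample_tiles(
            image,
            mask,
            profile.sampling,
            profile.tiles_per_image,
            profile.tile_size,
            seed=seed + 1000 + i,
        )
        for spec in specs:
            win = labels.tile_window(spec, image.shape)
            tiles.append(image.pixels[win])
            targets.append(classmap.classes[win].astype(np.int64))
    return tiles, targets


def train_model(tiles, targets, profile: DeskProfile, seed: int):
    spec = network.ModelSpec(
        depth=profile.depth,
        base_filters=profile.base_filters,
        tile_size=profile.tile_size,
        dropout_rate=profile.dropout_rate,
    )
    model = network.build_model(spec, seed=seed)
    cfg = network.TrainConfig(
        epochs=profile.epochs,
        iterations_total=profile.iterations,
        batch_size=profile.batch_size,
        lr0=profile.lr0,
        loss=profile.loss,
        seed=seed,
    )
    from .core import ClassMap

    weights = labels.class_weights([ClassMap(t.astype(np.uint8)) for t in targets])
    history = network.train(model, tiles, targets, cfg, weights=weights)
    return model, history


def evaluate_model(model, test_pairs, profile: DeskProfile):
    """Infer, post-process and panoptic-score each held-out image."""
    icfg = infer.InferenceConfig(
        tile_size=profile.tile_size,
        stride=profile.stride,
        min_instance_px=profile.min_instance_px,
        max_dilation=profile.max_dilation,
    )
    scores = []
    for image, gt in test_pairs:
        classmap = infer.predict_image(model, image, icfg)
        pred = infer.postprocess(classmap, icfg)
        scores.append(panoptic.evaluate(pred, gt))
    return scores


def run_end2end(profile: DeskProfile | None = None, seed: int = 7):
    """Full pipeline run; returns (per-image PQScores, loss history, model)."""
    profile = profile or DeskProfile()
    pairs = generate_dataset(profile, seed)
    train_pairs = pairs[: profile.n_images - profile.n_test_images]
    test_pairs = pairs[profile.n_images - profile.n_test_images:]
    tiles, targets = prepare_tiles(train_pairs, profile, seed)
    model, history = train_model(tiles, targets, profile, seed)
    scores = evaluate_model(model, test_pairs, profile)
    return scores, history, model
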