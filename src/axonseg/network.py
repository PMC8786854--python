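"""Encoder-decoder segmentation network, losses, and SGD training.

The model is a classic U-Net: ``depth`` encoder stages of two 3x3
convolutions (batch normalization before every ReLU) followed by 2x2
max-pooling, a bottleneck with dropout between its convolutions, and a
mirrored decoder of 2x2 up-convolutions with skip concatenations, closed
by a 1x1 convolution and a per-pixel softmax over the three classes.
Channel counts double per stage from ``base_filters``.

Everything — forward, backward, and the SGD-with-momentum loop — is
implemented directly on numpy arrays (im2col convolutions), sized for
CPU execution on desk-scale tiles.  Three losses are provided: weighted
cross-entropy (the default; inverse-class-frequency weights computed
from the training tiles), generalized Dice, and focal loss with
``gamma = 0.25``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .labels import equalize_tile

# ---------------------------------------------------------------------------
# specs


@dataclass
class ModelSpec:
    depth: int = 4
    base_filters: int = 64
    tile_size: int = 512
    n_classes: int = 3
    dropout_rate: float = 0.5
    padding_mode: str = "same"  # or "valid"

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.padding_mode not in ("same", "valid"):
            raise ValueError("padding_mode must be 'same' or 'valid'")
        if self.padding_mode == "same" and self.tile_size % (2**self.depth):
            raise ValueError(
                f"tile_size {self.tile_size} must be divisible by "
                f"2**depth = {2**self.depth} with same-padding"
            )
        if self.padding_mode == "valid":
            if output_size(self.tile_size, self.depth) < 1:
                raise ValueError(
                    f"tile_size {self.tile_size} too small for depth "
                    f"{self.depth} with valid padding"
                )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


def output_size(tile_size: int, depth: int) -> int:
    """Output raster side for valid-padding convolutions (e.g. 524 -> 340)."""
    s = tile_size
    for _ in range(depth):  # encoder: two 3x3 convs then 2x2 pool
        s = (s - 4)
        if s < 2 or s % 2:
            return -1
        s //= 2
    s -= 4  # bottleneck
    for _ in range(depth):  # decoder: 2x2 up-conv then two 3x3 convs
        s = 2 * s - 4
    return s


@dataclass
class TrainConfig:
    epochs: int = 4
    iterations_total: int | None = None
    batch_size: int = 2
    lr0: float = 0.01
    lr_decay: float = 0.1
    momentum: float = 0.9
    loss: str = "weighted_ce"
    gamma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.loss not in ("weighted_ce", "generalized_dice", "focal",
                             "weighted_ce_no_border"):
            raise ValueError(f"unknown loss {self.loss!r}")


# ---------------------------------------------------------------------------
# layers (numpy, NCHW)


class Conv2d:
    def __init__(self, cin, cout, k=3, padding="same", rng=None):
        fan_in = cin * k * k
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.b = np.zeros(cout)
        self.k, self.pad = k, (k // 2 if padding == "same" else 0)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train):
        k, p = self.k, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, h, w = x.shape
        ho, wo = h - k + 1, w - k + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        wmat = self.w.reshape(self.w.shape[0], -1)
        y = cols @ wmat.T + self.b
        self._cache = (cols, x.shape)
        return y.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, gy):
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.pad
        cout = self.w.shape[0]
        ho, wo = h - k + 1, w - k + 1
        gy2 = gy.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.gw += (gy2.T @ cols).reshape(self.w.shape)
        self.gb += gy2.sum(axis=0)
        gcols = (gy2 @ self.w.reshape(cout, -1)).reshape(n, ho, wo, c, k, k)
        gx = np.zeros(xshape)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + ho, j:j + wo] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        if p:
            gx = gx[:, :, p:-p, p:-p]
        return gx


class BatchNorm2d:
    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.gg = np.zeros(c)
        self.gb = np.zeros(c)
        self.rmean = np.zeros(c)
        self.rvar = np.ones(c)
        self.eps, self.mom = eps, momentum

    def params(self):
        return [(self.gamma, self.gg), (self.beta, self.gb)]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.rmean = (1 - self.mom) * self.rmean + self.mom * mu
            self.rvar = (1 - self.mom) * self.rvar + self.mom * var
        else:
            mu, var = self.rmean, self.rvar
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * inv[:, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, gy):
        xhat, inv, train = self._cache
        self.gg += (gy * xhat).sum(axis=(0, 2, 3))
        self.gb += gy.sum(axis=(0, 2, 3))
        g = self.gamma[:, None, None] * inv[:, None, None]
        if not train:
            return gy * g
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        mean_gy = gy.mean(axis=(0, 2, 3))[:, None, None]
        mean_gy_xhat = (gy * xhat).mean(axis=(0, 2, 3))[:, None, None]
        return g * (gy - mean_gy - xhat * mean_gy_xhat)


class ReLU:
    def params(self):
        return []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Dropout:
    def __init__(self, rate):
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def params(self):
        return []

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = self.rng.random(x.shape) < keep
        return x * self._mask / keep

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask / (1.0 - self.rate)


class MaxPool2:
    def params(self):
        return []

    def forward(self, x, train):
        n, c, h, w = x.shape
        xb = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xb.reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, gy):
        n, c, h, w = self._shape
        gflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(gflat, self._arg[..., None], gy[..., None], axis=-1)
        return (
            gflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class UpConv2x2:
    """Transposed 2x2 convolution with stride 2 (exact spatial doubling)."""

    def __init__(self, cin, cout, rng):
        self.w = rng.normal(0.0, math.sqrt(2.0 / cin), size=(cin, cout, 2, 2))
        self.b = np.zeros(cout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x, train):
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("nchw,coab->nohawb", x, self.w)
        cout = self.w.shape[1]
        return y.reshape(n, cout, 2 * h, 2 * w) + self.b[:, None, None]

    def backward(self, gy):
        x = self._x
        n, c, h, w = x.shape
        cout = self.w.shape[1]
        gyb = gy.reshape(n, cout, h, 2, w, 2)
        self.gw += np.einsum("nchw,nohawb->coab", x, gyb)
        self.gb += gy.sum(axis=(0, 2, 3))
        return np.einsum("nohawb,coab->nchw", gyb, self.w)


def _center_crop(x, h, w):
    dh = (x.shape[2] - h) // 2
    dw = (x.shape[3] - w) // 2
    return x[:, :, dh:dh + h, dw:dw + w]


# ---------------------------------------------------------------------------
# the U-Net


class UNet:
    """U-shaped encoder-decoder over 1-channel tiles; softmax class output."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        pad = spec.padding_mode
        f = spec.base_filters
        d = spec.depth

        def block(cin, cout, dropout=False):
            layers = [Conv2d(cin, cout, 3, pad, rng), BatchNorm2d(cout), ReLU()]
            if dropout:
                layers.append(Dropout(spec.dropout_rate))
            layers += [Conv2d(cout, cout, 3, pad, rng), BatchNorm2d(cout), ReLU()]
            if dropout:
                layers.append(Dropout(spec.dropout_rate))
            return layers

        self.enc = [block(1 if i == 0 else f * 2 ** (i - 1), f * 2**i) for i in range(d)]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = block(f * 2 ** (d - 1), f * 2**d, dropout=True)
        self.ups = [UpConv2x2(f * 2 ** (i + 1), f * 2**i, rng) for i in reversed(range(d))]
        self.dec = [block(f * 2 ** (i + 1), f * 2**i) for i in reversed(range(d))]
        self.head = Conv2d(f, spec.n_classes, 1, "same", rng)

    # -- plumbing

    def _all_layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.pools
        yield from self.bottleneck
        for up, blk in zip(self.ups, self.dec):
            yield up
            yield from blk
        yield self.head

    def parameters(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0

    def seed_dropout(self, seed: int):
        for k, layer in enumerate(self._all_layers()):
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(seed + k)

    # -- forward / backward

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (N, 1, t, t) tiles to (N, n_classes, H, W) probabilities."""
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            for layer in blk:
                h = layer.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for layer in self.bottleneck:
            h = layer.forward(h, train)
        self._crops = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            skip_c = _center_crop(skip, h.shape[2], h.shape[3])
            self._crops.append((skip.shape, h.shape[2], h.shape[3]))
            h = np.concatenate([skip_c, h], axis=1)
            for layer in blk:
                h = layer.forward(h, train)
        logits = self.head.forward(h, train)
        self._probs = softmax(logits)
        return self._probs

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        """Inference on one 2-D tile in [0, 1]; returns (n_classes, H, W)."""
        out = self.forward(tile[None, None, :, :], train=False)
        return out[0]

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        gskips = []
        for up, blk, (skip_shape, ch, cw) in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._crops)
        ):
            for layer in reversed(blk):
                g = layer.backward(g)
            nskip = skip_shape[1]
            gskip_c, gup = g[:, :nskip], g[:, nskip:]
            gskip = np.zeros(skip_shape)
            dh = (skip_shape[2] - ch) // 2
            dw = (skip_shape[3] - cw) // 2
            gskip[:, :, dh:dh + ch, dw:dw + cw] = gskip_c
            gskips.append(gskip)
            g = up.backward(gup)
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        # gskips were collected shallowest-first; encoder backward runs deepest-first
        for blk, pool, gskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(gskips)
        ):
            g = pool.backward(g) + gskip
            for layer in reversed(blk):
                g = layer.backward(g)

    # -- persistence

    def state_arrays(self):
        arrs = {}
        for i, layer in enumerate(self._all_layers()):
            for attr in ("w", "b", "gamma", "beta", "rmean", "rvar"):
                if hasattr(layer, attr):
                    arrs[f"{i}.{attr}"] = getattr(layer, attr)
        return arrs

    def save(self, path) -> None:
        """Single-file weights blob plus a JSON sidecar with the spec."""
        path = Path(path)
        np.savez(path, **self.state_arrays())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.spec)))

    @classmethod
    def load(cls, path) -> "UNet":
        path = Path(path)
        spec = ModelSpec(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(spec)
        blob = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
        for key in blob.files:
            i, attr = key.split(".")
            layer = list(model._all_layers())[int(i)]
            getattr(layer, attr)[...] = blob[key]
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> UNet:
    return UNet(spec, seed=seed)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Chain a gradient w.r.t. probabilities through the softmax."""
    dot = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - dot)


# ---------------------------------------------------------------------------
# losses: each returns (value, gradient w.r.t. logits)

_EPS = 1e-12


def _onehot(target: np.ndarray, n_classes: int) -> np.ndarray:
    return np.moveaxis(np.eye(n_classes)[target], -1, 1)


def loss_weighted_ce(probs, target, weights):
    """Mean over pixels of w_target * (-log p_target).

    ``weights`` has one positive entry per class; with unit weights this
    is plain cross-entropy.  The two-class no-border ablation is the same
    computation on two-channel probabilities and {0, 1} targets.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size != probs.shape[1]:
        raise ValueError("one weight per class required")
    if (weights <= 0).any():
        raise ValueError("class weights must be positive")
    n = target.size
    onehot = _onehot(target, probs.shape[1])
    wmap = weights[target][:, None]  # (N,1,H,W)
    p_t = (probs * onehot).sum(axis=1, keepdims=True)
    value = float((wmap * -np.log(p_t + _EPS)).sum() / n)
    dprobs = -(wmap * onehot) / (p_t + _EPS) / n
    return value, softmax_backward(probs, dprobs)


def loss_generalized_dice(probs, target, eps: float = 1e-8):
    """1 - inverse-frequency-weighted mean of per-class Dice overlaps.

    Class weights are 1/frequency over the target; classes absent from
    the target get weight 0 (their inverse frequency is undefined).  The
    smoothing constant ``eps`` guards empty denominators.
    """
    n_classes = probs.shape[1]
    onehot = _onehot(target, n_classes)
    axes = (0, 2, 3)
    g_sum = onehot.sum(axis=axes)
    p_sum = probs.sum(axis=axes)
    pg = (probs * onehot).sum(axis=axes)
    present = g_sum > 0
    wts = np.where(present, 1.0 / np.maximum(g_sum, 1.0), 0.0)
    wts = wts / wts.sum()
    dice = (2.0 * pg + eps) / (p_sum + g_sum + eps)
    value = float(1.0 - (wts * dice)[present].sum())
    # d dice_c / d p_(n,c,h,w) = (2*g - dice_c) / (p_sum + g_sum + eps)
    denom = (p_sum + g_sum + eps)[None, :, None, None]
    dprobs = -(wts[None, :, None, None] * (2.0 * onehot - dice[None, :, None, None])
               / denom)
    dprobs[:, ~present] = 0.0
    return value, softmax_backward(probs, dprobs)


def loss_focal(probs, target, gamma: float = 0.25):
    """Mean over pixels of (1 - p_c)**gamma * (-log p_c), no class weights."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    n = target.size
    onehot = _onehot(target, probs.shape[1])
    p_t = (probs * onehot).sum(axis=1, keepdims=True)
    q = np.clip(1.0 - p_t, 0.0, 1.0)
    logp = np.log(p_t + _EPS)
    value = float((q**gamma * -logp).sum() / n)
    dp = -(q**gamma) / (p_t + _EPS)
    if gamma > 0:
        dp += gamma * q ** (gamma - 1.0) * logp
    dprobs = onehot * dp / n
    return value, softmax_backward(probs, dprobs)


def make_loss(config: TrainConfig, weights=None):
    """Bind a TrainConfig's loss choice to a (probs, target) -> (value, dlogits)."""
    if config.loss in ("weighted_ce", "weighted_ce_no_border"):
        if weights is None:
            raise ValueError(f"{config.loss} requires class weights")
        return lambda p, t: loss_weighted_ce(p, t, weights)
    if config.loss == "generalized_dice":
        return loss_generalized_dice
    return lambda p, t: loss_focal(p, t, config.gamma)


# ---------------------------------------------------------------------------
# training


def train(
    model: UNet,
    tiles,
    targets,
    config: TrainConfig,
    weights=None,
    checkpoint_dir=None,
):
    """SGD-with-momentum training over prepared tile/target pairs.

    ``tiles`` are uint8 2-D arrays (equalized here before each forward
    pass), ``targets`` the matching integer class maps.  Runs
    ``config.epochs`` epochs with the per-epoch learning-rate schedule
    ``lr0 * lr_decay**epoch``; the total iteration count is split evenly
    across epochs when ``iterations_total`` is given, otherwise each
    epoch is one shuffled pass.  Returns the per-iteration history as a
    list of dicts (iteration, epoch, lr, loss); checkpoints are written
    per epoch when ``checkpoint_dir`` is given.
    """
    config.validate()
    if len(tiles) == 0:
        raise ValueError("empty training set")
    if len(tiles) != len(targets):
        raise ValueError("tiles and targets differ in length")
    loss_fn = make_loss(config, weights)
    rng = np.random.default_rng(config.seed)
    model.seed_dropout(config.seed + 1)

    params = model.parameters()
    velocity = [np.zeros_like(p) for p, _ in params]
    n_tiles = len(tiles)
    per_epoch = (
        int(np.ceil(config.iterations_total / config.epochs))
        if config.iterations_total
        else int(np.ceil(n_tiles / config.batch_size))
    )

    prepared = [equalize_tile(t).astype(np.float64) / 255.0 for t in tiles]
    history = []
    it = 0
    for epoch in range(config.epochs):
        lr = config.lr0 * config.lr_decay**epoch
        order = rng.permutation(n_tiles)
        cursor = 0
        for _ in range(per_epoch):
            if cursor + config.batch_size > n_tiles:
                order = rng.permutation(n_tiles)
                cursor = 0
            idx = order[cursor:cursor + config.batch_size]
            cursor += config.batch_size
            x = np.stack([prepared[i] for i in idx])[:, None]
            t = np.stack([targets[i] for i in idx])
            model.zero_grad()
            probs = model.forward(x, train=True)
            if probs.shape[2:] != t.shape[1:]:  # valid padding shrinks output
                t = _center_crop(t[:, None], *probs.shape[2:])[:, 0]
            value, dlogits = loss_fn(probs, t)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at iteration {it} (epoch {epoch}); "
                    "lower the learning rate or inspect the tiles"
                )
            model.backward(dlogits)
            for (p, g), v in zip(params, velocity):
                v *= config.momentum
                v -= lr * g
                p += v
            history.append(
                {"iteration": it, "epoch": epoch, "lr": lr, "loss": value}
            )
            it += 1
        if checkpoint_dir is not None:
            ckpt = Path(checkpoint_dir) / f"epoch{epoch:02d}.npz"
            model.save(ckpt)
            ckpt.with_suffix(".hist.json").write_text(json.dumps(history))
    return history
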