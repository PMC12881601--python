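"""U-Net whole-cell segmenter: baseline and improved variants.

The improved variant adds a dilation rate to every encoder convolution (larger
receptive field at zero parameter cost) and swaps batch normalization for
group normalization (stable statistics at small batch sizes).  The exact
filter schedule is pinned by :func:`reconcile_architecture` against the
published parameter accounting rather than guessed: base 32 filters, five
encoder levels doubling to a 1024-filter bottleneck, parameter-free
nearest-neighbour up-sampling in the decoder (skip concatenation followed by
two 3x3 convolutions), normalization after every convolution, biased convs and
a 1x1 sigmoid output head.  That schedule gives 31,454,721 trainable weights;
with batch norm the running statistics add 2 per normalized channel over
6,016 channels = 12,032 non-trainable terms, with group norm none.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .metrics import dice_score, pixel_confusion, seg_metrics
from .nn.losses import jaccard_distance, jaccard_distance_grad
from .preprocess import binarize_prediction

__all__ = ["SegModelConfig", "TrainConfig", "ParamCount", "UNet",
           "build_unet", "count_parameters", "reconcile_architecture",
           "jaccard_distance_loss", "train_segmenter", "predict_mask",
           "STANDARD_UNET", "IMPROVED_UNET"]


@dataclass(frozen=True)
class SegModelConfig:
    """Full architectural description of a U-Net variant."""

    input_size: int = 224
    input_channels: int = 3
    depth: int = 5                 # encoder levels before the bottleneck
    base_filters: int = 32
    encoder_dilation: int = 2      # 1 = off (baseline)
    norm: str = "group"            # {batch, group}
    groups: int = 32               # clamped per layer to the channel count
    dropout_rate: float = 0.5
    dropout_placement: tuple = ("final_encoder_block", "final_decoder_block")
    upsampling: str = "upsample"   # {upsample, upsample_conv, transposed_conv}
    up_kernel: int = 2
    conv_bias: bool = True
    output_channels: int = 1       # sigmoid head

    def __post_init__(self):
        if self.norm not in ("batch", "group"):
            raise ValueError("norm must be 'batch' or 'group'")
        if self.encoder_dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.upsampling not in ("upsample", "upsample_conv", "transposed_conv"):
            raise ValueError(f"unknown upsampling {self.upsampling!r}")

    @property
    def encoder_filters(self) -> tuple:
        return tuple(self.base_filters * 2 ** i for i in range(self.depth))

    @property
    def bottleneck_filters(self) -> int:
        return self.base_filters * 2 ** self.depth


# the two published variants (schedule fixed by reconcile_architecture)
STANDARD_UNET = SegModelConfig(norm="batch", encoder_dilation=1)
IMPROVED_UNET = SegModelConfig(norm="group", encoder_dilation=2)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.003
    batch_size: int = 18
    max_epochs: int = 100
    loss_smooth: float = 100.0
    early_stop_patience: int = 5
    stop_at_val_dice: float | None = None  # optional compute budget cut-off
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass(frozen=True)
class ParamCount:
    total: int
    trainable: int
    non_trainable: int

    def __post_init__(self):
        if self.total != self.trainable + self.non_trainable:
            raise ValueError("total must equal trainable + non_trainable")
        if min(self.total, self.trainable, self.non_trainable) < 0:
            raise ValueError("parameter counts must be >= 0")


def _norm_layer(cfg: SegModelConfig, channels: int) -> nn.Layer:
    if cfg.norm == "batch":
        return nn.BatchNorm(channels)
    return nn.GroupNorm(channels, groups=cfg.groups)


class UNet(nn.Module):
    """Encoder/decoder segmenter with skip concatenations.

    Layers are created eagerly (shapes only); weights are allocated by
    ``build(rng)``, so parameter accounting never touches memory.
    """

    def __init__(self, config: SegModelConfig):
        if config.input_size % (2 ** config.depth):
            raise ValueError(
                f"input size {config.input_size} not divisible by 2^{config.depth}")
        self.config = config
        c = config
        drop_enc = "final_encoder_block" in c.dropout_placement
        drop_dec = "final_decoder_block" in c.dropout_placement

        def conv_block(cin, f, dilation):
            return [
                nn.Conv2D(cin, f, 3, dilation=dilation, bias=c.conv_bias),
                _norm_layer(c, f), nn.ReLU(),
                nn.Conv2D(f, f, 3, dilation=dilation, bias=c.conv_bias),
                _norm_layer(c, f), nn.ReLU(),
            ]

        self.encoder_blocks = []
        cin = c.input_channels
        for i, f in enumerate(c.encoder_filters):
            block = conv_block(cin, f, c.encoder_dilation)
            if drop_enc and i == c.depth - 1:
                block.append(nn.SpatialDropout2D(c.dropout_rate))
            self.encoder_blocks.append(nn.Sequential(block))
            cin = f
        self.pools = [nn.MaxPool2D(2) for _ in range(c.depth)]

        fb = c.bottleneck_filters
        self.bottleneck = nn.Sequential(conv_block(cin, fb, 1))
        cin = fb

        self.up_layers = []
        self.decoder_blocks = []
        for i, f in enumerate(reversed(c.encoder_filters)):
            if c.upsampling == "transposed_conv":
                up = nn.Sequential([nn.ConvTranspose2D(cin, f, k=c.up_kernel,
                                                       stride=2, pad=0,
                                                       bias=c.conv_bias)])
                cat_in = f + f
            elif c.upsampling == "upsample_conv":
                up = nn.Sequential([nn.UpSampling2D(2),
                                    nn.Conv2D(cin, f, c.up_kernel, bias=c.conv_bias)])
                cat_in = f + f
            else:
                up = nn.Sequential([nn.UpSampling2D(2)])
                cat_in = cin + f
            self.up_layers.append(up)
            block = conv_block(cat_in, f, 1)
            if drop_dec and i == c.depth - 1:
                block.append(nn.SpatialDropout2D(c.dropout_rate))
            self.decoder_blocks.append(nn.Sequential(block))
            cin = f

        self.head = nn.Sequential([
            nn.Conv2D(cin, c.output_channels, 1, bias=True), nn.Sigmoid()])

    def layers(self):
        out = []
        for b in self.encoder_blocks:
            out.extend(b.layers())
        out.extend(self.pools)
        out.extend(self.bottleneck.layers())
        for u, d in zip(self.up_layers, self.decoder_blocks):
            out.extend(u.layers())
            out.extend(d.layers())
        out.extend(self.head.layers())
        return out

    def forward(self, x, training=False):
        skips = []
        for block, pool in zip(self.encoder_blocks, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_channels = []
        for up, dec, skip in zip(self.up_layers, self.decoder_blocks,
                                 reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append((x.shape[-1], skip.shape[-1]))
            x = np.concatenate([x, skip], axis=-1)
            x = dec.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dout):
        dout = self.head.backward(dout)
        dskips = []
        for up, dec, (c_up, c_skip) in zip(reversed(self.up_layers),
                                           reversed(self.decoder_blocks),
                                           reversed(self._skip_channels)):
            dout = dec.backward(dout)
            dskips.append(dout[..., c_up:])
            dout = up.backward(np.ascontiguousarray(dout[..., :c_up]))
        dout = self.bottleneck.backward(dout)
        # backward visits decoders shallowest-first, so dskips[j] holds the
        # gradient for encoder level j; reversed encoder iteration needs -(i+1)
        for i, (block, pool) in enumerate(zip(reversed(self.encoder_blocks),
                                              reversed(self.pools))):
            dout = pool.backward(dout)
            dout = dout + dskips[-(i + 1)]
            dout = block.backward(np.ascontiguousarray(dout))
        return dout


def build_unet(config: SegModelConfig, rng: np.random.Generator | None = None) -> UNet:
    """Construct a U-Net; weights are allocated when ``rng`` is given."""
    model = UNet(config)
    if rng is not None:
        model.build(rng)
    return model


def count_parameters(model: nn.Module) -> ParamCount:
    """Exact integer parameter accounting (batch-norm statistics are
    non-trainable; group norm has none)."""
    total, trainable, non_trainable = nn.count_module_parameters(model)
    return ParamCount(total=total, trainable=trainable, non_trainable=non_trainable)


def default_search_space():
    """Candidate grid for reconciling the architecture against published counts."""
    grid = []
    for base, depth, ups, bias in itertools.product(
            (32, 64), (3, 4, 5), ("upsample", "upsample_conv", "transposed_conv"),
            (True, False)):
        grid.append(SegModelConfig(
            input_size=2 ** depth * 7, depth=depth, base_filters=base,
            upsampling=ups, norm="batch", encoder_dilation=1, conv_bias=bias))
    return grid


def reconcile_architecture(target: ParamCount, search_space=None):
    """Find the config whose ``count_parameters`` matches ``target`` exactly.

    Returns ``(config, candidates)`` where candidates is a list of
    ``(config, delta_total, delta_non_trainable)`` sorted by closeness;
    ``config`` is None when no exact match exists in the space.
    """
    space = list(default_search_space() if search_space is None else search_space)
    if not space:
        raise ValueError("empty search space")
    candidates = []
    exact = None
    for cfg in space:
        pc = count_parameters(UNet(cfg))
        d_tot = pc.total - target.total
        d_nt = pc.non_trainable - target.non_trainable
        d_tr = pc.trainable - target.trainable
        candidates.append((cfg, d_tot, d_nt))
        if d_tot == 0 and d_nt == 0 and d_tr == 0 and exact is None:
            exact = cfg
    candidates.sort(key=lambda c: abs(c[1]) + abs(c[2]))
    return exact, candidates


def jaccard_distance_loss(y_true, y_pred, smooth: float = 100.0) -> float:
    """Jaccard distance (1 - smoothed IoU) pooled over the batch."""
    return jaccard_distance(y_true, y_pred, smooth=smooth)


def _as_batches(images, masks, batch_size, rng=None):
    n = len(images)
    order = np.arange(n) if rng is None else rng.permutation(n)
    for i in range(0, n, batch_size):
        ix = order[i:i + batch_size]
        yield images[ix], masks[ix]


def _stack(samples):
    x = np.stack([s.image for s in samples]).astype(np.float32)
    y = np.stack([s.mask for s in samples]).astype(np.float32)[..., None]
    return x, y


def train_segmenter(model: UNet, train, val, cfg: TrainConfig):
    """Adam + Jaccard-distance training with early stopping on validation loss.

    Returns ``(model, history)`` where history is a list of per-epoch dicts
    (epoch, train_loss, val_loss, val_dice).  Best-validation weights are
    restored before returning.
    """
    if not len(train) or not len(val):
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    if not model.built:
        model.build(rng)
    model.set_dropout_rng(rng)
    opt = nn.Adam(model, lr=cfg.learning_rate)
    x_tr, y_tr = _stack(train)
    x_va, y_va = _stack(val)
    history = []
    best = (np.inf, None, -1)
    for epoch in range(cfg.max_epochs):
        losses = []
        for xb, yb in _as_batches(x_tr, y_tr, cfg.batch_size, rng):
            pred = model.forward(xb, training=True)
            losses.append(jaccard_distance(yb, pred, cfg.loss_smooth))
            model.backward(jaccard_distance_grad(yb, pred, cfg.loss_smooth))
            opt.step()
            opt.zero_grad()
        val_pred = predict_mask(model, x_va)
        val_loss = jaccard_distance(y_va, val_pred, cfg.loss_smooth)
        val_dice = dice_score(y_va.astype(np.uint8),
                              binarize_prediction(val_pred))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": float(val_loss), "val_dice": float(val_dice)})
        if val_loss < best[0] - 1e-6:
            best = (val_loss, model.get_weights(), epoch)
        elif epoch - best[2] >= cfg.early_stop_patience:
            break
        if cfg.stop_at_val_dice is not None and val_dice >= cfg.stop_at_val_dice:
            best = (val_loss, model.get_weights(), epoch)
            break
    if best[1] is not None:
        model.set_weights(best[1])
    return model, history


def predict_mask(model: UNet, images: np.ndarray, batch_size: int = 18) -> np.ndarray:
    """Per-pixel cell probabilities for a batch of normalized images."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    if images.shape[1] != model.config.input_size:
        raise ValueError(f"image size {images.shape[1]} does not match model "
                         f"input {model.config.input_size}")
    out = [model.forward(images[i:i + batch_size], training=False)
           for i in range(0, len(images), batch_size)]
    return np.concatenate(out, axis=0)


def architecture_json(model: UNet) -> str:
    """Serializable architecture description (full SegModelConfig)."""
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in model.config.__dict__.items()}
    pc = count_parameters(model)
    d["param_count"] = {"total": pc.total, "trainable": pc.trainable,
                        "non_trainable": pc.non_trainable}
    return json.dumps(d, indent=2)
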