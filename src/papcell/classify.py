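"""Classification stage: single-backbone classifier, 7-model majority voting,
and the 8-backbone feature-concatenation ensemble.

The canonical backbone names (ResNet50V2, VGG16, VGG19, Xception, InceptionV3,
DenseNet121, EfficientNetB2, MobileNetV2) are registered in a backbone
registry.  In this package each name maps to a compact convolutional feature
extractor with frozen, name-seeded random weights — the ensemble mechanics
(feature extraction, flatten/concat, 256/64 head, voting) are exactly those of
the full-scale design, while the backbones themselves are small enough to run
on a desk CPU.  ImageNet-pretrained weights are an optional enhancement that
this stack does not provide.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.losses import (categorical_crossentropy, categorical_crossentropy_grad)

__all__ = ["BackboneSpec", "ConcatEnsembleConfig", "VotingConfig",
           "ClfTrainConfig", "BACKBONE_NAMES", "VOTING_MEMBER_NAMES",
           "build_backbone", "build_single_classifier", "build_concat_ensemble",
           "majority_vote", "train_classifier", "predict",
           "SingleClassifier", "ConcatEnsemble", "backbone_checksum"]

# the eight concat-ensemble backbones; voting uses all but InceptionV3
BACKBONE_NAMES = ("ResNet50V2", "VGG19", "Xception", "InceptionV3", "VGG16",
                  "EfficientNetB2", "MobileNetV2", "DenseNet121")
VOTING_MEMBER_NAMES = ("ResNet50V2", "VGG19", "VGG16", "Xception",
                       "DenseNet121", "EfficientNetB2", "MobileNetV2")


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    weights: str = "random"   # {random, pretrained}; pretrained unavailable here
    frozen: bool = True

    def __post_init__(self):
        if self.name not in BACKBONE_NAMES:
            raise ValueError(f"unknown backbone {self.name!r}; "
                             f"known: {BACKBONE_NAMES}")


@dataclass(frozen=True)
class ConcatEnsembleConfig:
    backbones: tuple = tuple(BackboneSpec(n) for n in BACKBONE_NAMES)
    n_classes: int = 2
    head_dims: tuple = (256, 64)
    dropout: float = 0.5
    input_size: int = 64

    def __post_init__(self):
        if len(self.backbones) != 8:
            raise ValueError("concat ensemble uses exactly 8 backbones")
        if not all(b.frozen for b in self.backbones):
            raise ValueError("ensemble backbones must be frozen")


@dataclass(frozen=True)
class VotingConfig:
    members: tuple = tuple(BackboneSpec(n) for n in VOTING_MEMBER_NAMES)
    tie_break: str = "lowest_index"

    def __post_init__(self):
        if len(self.members) != 7:
            raise ValueError("majority voting uses exactly 7 members")


@dataclass(frozen=True)
class ClfTrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _name_seed(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")


def build_backbone(spec: BackboneSpec, rng: np.random.Generator | None = None):
    """Compact conv feature extractor; architecture varies with the name so
    ensemble members see genuinely different feature spaces."""
    h = _name_seed(spec.name)
    base = 4 + (h % 3) * 2           # 4, 6 or 8 first-stage filters
    n_stages = 2 + (h >> 8) % 2      # 2 or 3 conv/pool stages
    layers = []
    cin = 3
    for s in range(n_stages):
        f = base * 2 ** s
        layers += [nn.Conv2D(cin, f, 3), nn.ReLU(), nn.MaxPool2D(2)]
        cin = f
    net = nn.Sequential(layers)
    if rng is None:
        rng = np.random.default_rng(_name_seed(spec.name))
    net.build(rng)
    if spec.frozen:
        for l in net.layers():
            l.frozen = True
    return net


def backbone_checksum(backbone) -> float:
    """Sum of all parameter values; cheap frozen-weights fingerprint."""
    return float(sum(arr.sum() for l in backbone.layers()
                     for arr in l.params.values()))


class SingleClassifier(nn.Module):
    """backbone -> global average pooling -> softmax head."""

    def __init__(self, backbone, n_classes: int, feat_channels: int):
        self.backbone = backbone
        self.n_classes = n_classes
        self.head = nn.Sequential([
            nn.GlobalAvgPool2D(),
            nn.Dense(feat_channels, n_classes), nn.Softmax()])
        self.backbone_frozen = all(getattr(l, "frozen", False)
                                   for l in backbone.layers()
                                   if l.param_shapes())

    def layers(self):
        return self.backbone.layers() + self.head.layers()

    def forward(self, x, training=False):
        feats = self.backbone.forward(x, training=training and not self.backbone_frozen)
        return self.head.forward(feats, training=training)

    def backward(self, dout):
        dout = self.head.backward(dout)
        if not self.backbone_frozen:
            dout = self.backbone.backward(dout)
        return dout


def build_single_classifier(backbone_spec: BackboneSpec, n_classes: int,
                            input_size: int = 64,
                            rng: np.random.Generator | None = None):
    """Single-backbone softmax classifier; only the output layer depends on
    ``n_classes``."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if rng is None:
        rng = np.random.default_rng(_name_seed(backbone_spec.name))
    backbone = build_backbone(backbone_spec, rng)
    probe = backbone.forward(np.zeros((1, input_size, input_size, 3), np.float32))
    model = SingleClassifier(backbone, n_classes, probe.shape[-1])
    model.build(rng)
    return model


class ConcatEnsemble(nn.Module):
    """Eight frozen backbones; flattened features concatenated into the
    256/64 batch-norm + dropout head."""

    def __init__(self, cfg: ConcatEnsembleConfig, rng: np.random.Generator):
        self.config = cfg
        self.backbones = [build_backbone(b, np.random.default_rng(
            [_name_seed(b.name), 1])) for b in cfg.backbones]
        self.flattens = [nn.Flatten() for _ in self.backbones]
        probe = np.zeros((1, cfg.input_size, cfg.input_size, 3), np.float32)
        self.feature_dims = [int(np.prod(b.forward(probe).shape[1:]))
                             for b in self.backbones]
        d = sum(self.feature_dims)
        d1, d2 = cfg.head_dims
        # momentum 0.9: the head trains for few steps, so the moving batch
        # statistics must converge on a ~10-step timescale to be usable at eval
        self.head = nn.Sequential([
            nn.Dense(d, d1), nn.BatchNorm(d1, momentum=0.9), nn.ReLU(),
            nn.Dropout(cfg.dropout),
            nn.Dense(d1, d2), nn.ReLU(),
            nn.Dense(d2, cfg.n_classes), nn.Softmax()])
        self.head.build(rng)

    @property
    def concat_dim(self) -> int:
        return sum(self.feature_dims)

    def layers(self):
        out = []
        for b in self.backbones:
            out.extend(b.layers())
        out.extend(self.head.layers())
        return out

    def extract_features(self, x) -> np.ndarray:
        feats = [f.forward(b.forward(x)) for b, f in
                 zip(self.backbones, self.flattens)]
        return np.concatenate(feats, axis=1)

    def forward(self, x, training=False):
        return self.head.forward(self.extract_features(x), training=training)

    def forward_features(self, feats, training=False):
        return self.head.forward(feats, training=training)

    def backward(self, dout):
        # backbones are frozen: gradient stops at the head
        return self.head.backward(dout)


def build_concat_ensemble(cfg: ConcatEnsembleConfig,
                          rng: np.random.Generator | None = None) -> ConcatEnsemble:
    return ConcatEnsemble(cfg, rng if rng is not None else np.random.default_rng(0))


def majority_vote(votes: np.ndarray, tie_break: str = "lowest_index") -> np.ndarray:
    """Modal label per row of an (n_samples, n_models) vote matrix.

    Ties go to the smallest class index (the only rule implemented; the
    argument names the contract).
    """
    votes = np.asarray(votes, dtype=np.int64)
    if votes.ndim != 2 or votes.shape[1] < 1 or votes.shape[0] < 1:
        raise ValueError("votes must be a nonempty (n_samples, n_models) matrix")
    if tie_break != "lowest_index":
        raise ValueError(f"unknown tie_break {tie_break!r}")
    n_classes = int(votes.max()) + 1
    out = np.empty(votes.shape[0], dtype=np.int64)
    for i, row in enumerate(votes):
        out[i] = np.argmax(np.bincount(row, minlength=n_classes))
    return out


def _one_hot(labels, n_classes):
    eye = np.eye(n_classes, dtype=np.float32)
    return eye[np.asarray(labels, dtype=np.int64)]


def train_classifier(model, x_train, y_train, x_val, y_val,
                     cfg: ClfTrainConfig, n_classes: int):
    """Adam + categorical cross-entropy with early stopping on validation loss.

    ``model`` is a SingleClassifier or ConcatEnsemble; frozen backbones are
    exploited by extracting features once and training only the head.
    Returns (model, history).
    """
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be nonempty")
    present = np.unique(y_train)
    if len(present) < n_classes:
        missing = sorted(set(range(n_classes)) - set(present.tolist()))
        raise ValueError(f"classes {missing} absent from the training set")
    rng = np.random.default_rng(cfg.seed)
    model.set_dropout_rng(rng)
    opt = nn.Adam(model, lr=cfg.learning_rate)
    t_train = _one_hot(y_train, n_classes)
    t_val = _one_hot(y_val, n_classes)

    use_features = isinstance(model, ConcatEnsemble)
    if use_features:
        f_train = model.extract_features(np.asarray(x_train, np.float32))
        f_val = model.extract_features(np.asarray(x_val, np.float32))
        fwd = model.forward_features
    else:
        f_train = np.asarray(x_train, np.float32)
        f_val = np.asarray(x_val, np.float32)
        fwd = model.forward

    history = []
    best = (np.inf, None, -1)
    n = len(f_train)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            ix = order[i:i + cfg.batch_size]
            p = fwd(f_train[ix], training=True)
            losses.append(categorical_crossentropy(t_train[ix], p))
            model.backward(categorical_crossentropy_grad(t_train[ix], p))
            opt.step()
            opt.zero_grad()
        p_val = fwd(f_val, training=False)
        val_loss = categorical_crossentropy(t_val, p_val)
        val_acc = float((p_val.argmax(1) == y_val).mean())
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": float(val_loss), "val_acc": val_acc})
        if val_loss < best[0] - 1e-6:
            best = (val_loss, model.get_weights(), epoch)
        elif epoch - best[2] >= cfg.early_stop_patience:
            break
    if best[1] is not None:
        model.set_weights(best[1])
    return model, history


def predict(model, images, batch_size: int = 32) -> np.ndarray:
    """Class-probability matrix (rows on the simplex)."""
    images = np.asarray(images, dtype=np.float32)
    out = [model.forward(images[i:i + batch_size], training=False)
           for i in range(0, len(images), batch_size)]
    return np.concatenate(out, axis=0)
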