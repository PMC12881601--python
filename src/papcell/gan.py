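"""Residual DCGAN augmentor.

The generator projects a latent noise vector to a 6x6 spatial seed and pushes
it through four stride-2 transposed-convolution up-sampling stages (filters
decreasing 512 -> 64), each followed by one or more identity-skip residual
blocks, ending in a 3-channel tanh head rescaled to [0, 1] at 96x96.  The
discriminator is a plain 5-layer strided CNN with filters increasing 32 -> 512
and a single real-vs-fake probability output.  Training is the standard
alternating non-saturating GAN game with Adam(4e-4, beta1=0.5) and one-sided
label smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.losses import binary_crossentropy, binary_crossentropy_grad

__all__ = ["GeneratorConfig", "DiscriminatorConfig", "GanTrainConfig",
           "Generator", "build_generator", "build_discriminator",
           "discriminator_conv_census", "train_gan", "sample_images"]


@dataclass(frozen=True)
class GeneratorConfig:
    latent_dim: int = 128
    seed_spatial: int = 6
    stage_filters: tuple = (512, 256, 128, 64)
    residual_blocks_per_stage: int = 1
    output_size: int = 96
    output_channels: int = 3

    def __post_init__(self):
        if len(self.stage_filters) < 1:
            raise ValueError("need at least one up-sampling stage")
        if any(a <= b for a, b in zip(self.stage_filters, self.stage_filters[1:])):
            raise ValueError("stage filters must be strictly decreasing")
        if self.seed_spatial * 2 ** len(self.stage_filters) != self.output_size:
            raise ValueError(
                f"{self.seed_spatial} * 2^{len(self.stage_filters)} != {self.output_size}")
        if self.residual_blocks_per_stage < 0:
            raise ValueError("residual_blocks_per_stage must be >= 0")


@dataclass(frozen=True)
class DiscriminatorConfig:
    input_size: int = 96
    layer_filters: tuple = (32, 64, 128, 256, 512)

    def __post_init__(self):
        if len(self.layer_filters) != 5:
            raise ValueError("discriminator uses exactly 5 convolutional layers")
        if any(a >= b for a, b in zip(self.layer_filters, self.layer_filters[1:])):
            raise ValueError("discriminator filters must be strictly increasing")


@dataclass(frozen=True)
class GanTrainConfig:
    batch_size: int = 32
    steps: int = 300
    learning_rate: float = 4e-4
    beta1: float = 0.5
    label_smoothing: bool = True
    ema_decay: float = 0.99   # generator weight EMA; 0 disables
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if not (0 <= self.ema_decay < 1):
            raise ValueError("ema_decay must lie in [0, 1)")


class ResidualBlock(nn.Layer):
    """Two 3x3 convs at constant channel count with an identity skip.

    With all-zero branch weights the block is exactly the identity.
    """

    def __init__(self, channels):
        # note: no super().__init__() — params/grads are delegated properties
        self.branch = nn.Sequential([
            nn.Conv2D(channels, channels, 3), nn.ReLU(),
            nn.Conv2D(channels, channels, 3)])
        self.act = nn.ReLU()

    def param_shapes(self):
        shapes = {}
        for i, l in enumerate(self.branch.layers()):
            for k, v in l.param_shapes().items():
                shapes[f"l{i}_{k}"] = v
        return shapes

    @property
    def params(self):  # expose flat view for counting/opt
        out = {}
        for i, l in enumerate(self.branch.layers()):
            for k, v in l.params.items():
                out[f"l{i}_{k}"] = v
        return out

    @params.setter
    def params(self, value):
        for i, l in enumerate(self.branch.layers()):
            l.params = {k[len(f"l{i}_"):]: v for k, v in value.items()
                        if k.startswith(f"l{i}_")}

    @property
    def grads(self):
        out = {}
        for i, l in enumerate(self.branch.layers()):
            for k, v in l.grads.items():
                out[f"l{i}_{k}"] = v
        return out

    @grads.setter
    def grads(self, value):
        for l in self.branch.layers():
            l.grads = {}

    @property
    def non_trainable(self):
        return {}

    @non_trainable.setter
    def non_trainable(self, value):
        pass

    def build(self, rng):
        self.branch.build(rng)
        self.built = True

    @property
    def built(self):
        return all(l.built for l in self.branch.layers())

    @built.setter
    def built(self, value):
        if not value:
            for l in self.branch.layers():
                l.built = False

    def forward(self, x, training=False):
        if training:
            self._x = x
        return self.act.forward(x + self.branch.forward(x, training), training)

    def backward(self, dout):
        dout = self.act.backward(dout)
        return dout + self.branch.backward(dout)

    def zero_grad(self):
        for l in self.branch.layers():
            l.zero_grad()


class Generator(nn.Sequential):
    def __init__(self, cfg: GeneratorConfig):
        self.config = cfg
        s = cfg.seed_spatial
        f0 = cfg.stage_filters[0]
        layers = [nn.Dense(cfg.latent_dim, s * s * f0),
                  nn.Reshape((s, s, f0)), nn.ReLU()]
        cin = f0
        for f in cfg.stage_filters:
            layers += [nn.ConvTranspose2D(cin, f, k=4, stride=2, pad=1),
                       nn.BatchNorm(f), nn.ReLU()]
            layers += [ResidualBlock(f) for _ in range(cfg.residual_blocks_per_stage)]
            cin = f
        layers += [nn.Conv2D(cin, cfg.output_channels, 3), nn.TanhRescaled()]
        super().__init__(layers)

    def generate(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n == 0:
            s = self.config.output_size
            return np.empty((0, s, s, self.config.output_channels), dtype=np.float32)
        z = rng.standard_normal((n, self.config.latent_dim)).astype(np.float32)
        return self.forward(z, training=False)


class Discriminator(nn.Sequential):
    def __init__(self, cfg: DiscriminatorConfig):
        self.config = cfg
        layers = []
        cin = 3
        for f in cfg.layer_filters:
            layers += [nn.Conv2D(cin, f, 3, stride=2, padding="same"),
                       nn.LeakyReLU(0.2)]
            cin = f
        size = cfg.input_size
        for _ in cfg.layer_filters:
            size = (size + 1) // 2
        layers += [nn.Flatten(), nn.Dense(size * size * cin, 1), nn.Sigmoid()]
        super().__init__(layers)

    def forward(self, x, training=False):
        if x.shape[1] != self.config.input_size:
            raise ValueError(f"expected {self.config.input_size}px input, "
                             f"got {x.shape[1]}")
        return super().forward(x, training).reshape(len(x))

    def backward(self, dout):
        return super().backward(dout.reshape(len(dout), 1))


def build_generator(cfg: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> Generator:
    gen = Generator(cfg)
    if rng is not None:
        gen.build(rng)
    return gen


def build_discriminator(cfg: DiscriminatorConfig,
                        rng: np.random.Generator | None = None) -> Discriminator:
    disc = Discriminator(cfg)
    if rng is not None:
        disc.build(rng)
    return disc


def discriminator_conv_census(disc: Discriminator):
    """(count, filters) of convolutional layers, for architecture checks."""
    convs = [l for l in disc.layers() if isinstance(l, nn.Conv2D)]
    return len(convs), tuple(c.cout for c in convs)


def train_gan(gen: Generator, disc: Discriminator, images: np.ndarray,
              cfg: GanTrainConfig):
    """Alternating non-saturating GAN training; returns (gen, history).

    The returned generator carries an exponential moving average of the
    trained weights (when ``cfg.ema_decay > 0``), which smooths the step-to-
    step oscillation of adversarial training.
    """
    images = np.asarray(images, dtype=np.float32)
    if len(images) < 2 * cfg.batch_size:
        raise ValueError(f"need at least {2 * cfg.batch_size} images, "
                         f"got {len(images)}")
    rng = np.random.default_rng(cfg.seed)
    if not gen.built:
        gen.build(rng)
    if not disc.built:
        disc.build(rng)
    opt_g = nn.Adam(gen, lr=cfg.learning_rate, beta1=cfg.beta1)
    opt_d = nn.Adam(disc, lr=cfg.learning_rate, beta1=cfg.beta1)
    real_label = 0.9 if cfg.label_smoothing else 1.0
    b = cfg.batch_size
    history = []
    # EMA covers the batch-norm moving statistics too, keeping them
    # consistent with the averaged weights
    ema = [{k: v.copy() for k, v in list(l.params.items())
            + list(l.non_trainable.items())} for l in gen.layers()] \
        if cfg.ema_decay > 0 else None
    for step in range(cfg.steps):
        # --- discriminator update on real + fake halves
        real = images[rng.choice(len(images), b, replace=False)]
        z = rng.standard_normal((b, gen.config.latent_dim)).astype(np.float32)
        fake = gen.forward(z, training=False)
        x = np.concatenate([real, fake])
        t = np.concatenate([np.full(b, real_label, np.float32),
                            np.zeros(b, np.float32)])
        p = disc.forward(x, training=True)
        d_loss = binary_crossentropy(t, p)
        disc.backward(binary_crossentropy_grad(t, p))
        opt_d.step()
        opt_d.zero_grad()
        # --- generator update: fool the discriminator
        z = rng.standard_normal((b, gen.config.latent_dim)).astype(np.float32)
        fake = gen.forward(z, training=True)
        p = disc.forward(fake, training=True)
        g_loss = binary_crossentropy(np.ones(b, np.float32), p)
        dfake = disc.backward(binary_crossentropy_grad(np.ones(b, np.float32), p))
        opt_d.zero_grad()  # discard discriminator grads from the generator pass
        gen.backward(dfake)
        opt_g.step()
        opt_g.zero_grad()
        if ema is not None:
            d = cfg.ema_decay
            for slot, layer in zip(ema, gen.layers()):
                for k, v in list(layer.params.items()) \
                        + list(layer.non_trainable.items()):
                    slot[k] *= d
                    slot[k] += (1 - d) * v
        history.append({"step": step, "d_loss": float(d_loss),
                        "g_loss": float(g_loss)})
    if ema is not None:
        for slot, layer in zip(ema, gen.layers()):
            for k in layer.params:
                layer.params[k][...] = slot[k]
            for k in layer.non_trainable:
                layer.non_trainable[k][...] = slot[k]
    return gen, history


def sample_images(gen: Generator, n: int, seed: int) -> np.ndarray:
    """Exactly ``n`` images in [0,1], deterministic in ``seed``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return gen.generate(n, np.random.default_rng(seed))
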