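"""Train the residual DCGAN on one phantom class and track FID.

FID is computed against the real images under a fixed random-projection
embedding before and after training; training should reduce it.
Run:  python examples/04_gan_augmentation.py    (~3 minutes on one CPU)
"""

import numpy as np

from papcell.fid import RandomProjectionEmbedding, compute_fid
from papcell.gan import (DiscriminatorConfig, GanTrainConfig, GeneratorConfig,
                         build_discriminator, build_generator, sample_images,
                         train_gan)
from papcell.phantoms import PhantomSpec, generate_dataset

spec = PhantomSpec(image_size=32)
samples, _ = generate_dataset(spec, {"abnormal": 200}, seed=1)
imgs = np.stack([s.image for s in samples])

gcfg = GeneratorConfig(latent_dim=32, seed_spatial=2,
                       stage_filters=(64, 32, 16, 8), output_size=32)
dcfg = DiscriminatorConfig(input_size=32, layer_filters=(8, 16, 32, 64, 128))
gen = build_generator(gcfg, np.random.default_rng(1))
disc = build_discriminator(dcfg, np.random.default_rng(2))

emb = RandomProjectionEmbedding(dim=32, seed=0)
fid0 = compute_fid(imgs, sample_images(gen, 200, seed=3), embedding=emb).value
print(f"FID before training: {fid0:.3f}")

gen, history = train_gan(gen, disc, imgs, GanTrainConfig(seed=1))
print(f"step 0:   d_loss={history[0]['d_loss']:.3f} "
      f"g_loss={history[0]['g_loss']:.3f}")
print(f"step 299: d_loss={history[-1]['d_loss']:.3f} "
      f"g_loss={history[-1]['g_loss']:.3f}")

fid1 = compute_fid(imgs, sample_images(gen, 200, seed=3), embedding=emb).value
print(f"FID after 300 steps: {fid1:.3f} "
      f"({'improved' if fid1 < fid0 else 'did not improve'})")
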