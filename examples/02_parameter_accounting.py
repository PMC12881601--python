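"""Reproduce the published parameter accounting of the two U-Net variants.

The standard U-Net (batch norm) and the improved U-Net (group norm + dilated
encoder convolutions) share every trainable weight; the only difference in
the accounting is the batch-norm moving statistics.  The architecture is
recovered from the published counts by exhaustive search.
Run:  python examples/02_parameter_accounting.py
"""

from papcell.unet import (IMPROVED_UNET, STANDARD_UNET, UNet, count_parameters,
                          reconcile_architecture)

std = count_parameters(UNet(STANDARD_UNET))
imp = count_parameters(UNet(IMPROVED_UNET))
print("standard U-Net :", f"total={std.total:,}",
      f"trainable={std.trainable:,}", f"non-trainable={std.non_trainable:,}")
print("improved U-Net :", f"total={imp.total:,}",
      f"trainable={imp.trainable:,}", f"non-trainable={imp.non_trainable:,}")

exact, candidates = reconcile_architecture(std)
print("\nreconciliation over the candidate grid:")
print(f"  exact match: base_filters={exact.base_filters}, depth={exact.depth},"
      f" upsampling={exact.upsampling!r}, conv_bias={exact.conv_bias}")
print(f"  next-closest candidates (|total delta| + |non-trainable delta|):")
for cfg, d_tot, d_nt in candidates[1:4]:
    print(f"    base={cfg.base_filters} depth={cfg.depth} "
          f"ups={cfg.upsampling:15s} bias={cfg.conv_bias}: "
          f"delta_total={d_tot:+,} delta_nt={d_nt:+,}")
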