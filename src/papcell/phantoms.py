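"""Desk-scale Pap-smear-like phantoms: stained single-cell images with masks.

Each phantom is an RGB image containing one rotated elliptical cytoplasm with
an interior elliptical nucleus on a uniform background, plus the pixel-aligned
binary whole-cell mask (cytoplasm union nucleus) and a class label driven by
the nucleus-to-cytoplasm (N/C) area ratio — the morphological cue cytologists
use to grade squamous lesions.  Texture is Gaussian noise followed by Gaussian
blur, enough to defeat colour-lookup shortcuts while keeping classes separable
by construction.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "LabeledSample", "generate_cell_image",
           "generate_dataset", "write_herlev_style_mask", "DEFAULT_PALETTE",
           "HERLEV_REGION_PALETTE"]

# stain-like palette: pale cytoplasm, dark basophilic nucleus, light background
DEFAULT_PALETTE = {
    "background": (0.92, 0.90, 0.95),
    "cytoplasm": (0.55, 0.75, 0.80),
    "nucleus": (0.25, 0.15, 0.45),
}

# Herlev-style colour mask regions
HERLEV_REGION_PALETTE = {
    "background": (255, 0, 0),
    "cytoplasm": (0, 255, 0),
    "nucleus": (0, 0, 255),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, stain and noise model for one phantom family."""

    image_size: int = 96
    cytoplasm_radius_range: tuple[float, float] = (0.25, 0.38)
    nc_ratio_by_class: dict = field(default_factory=lambda: {
        "normal": (0.05, 0.15), "abnormal": (0.5, 0.7)})
    stain_palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    noise_sd: float = 0.03
    blur_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        lo, hi = self.cytoplasm_radius_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("cytoplasm radii must keep the cell inside the frame")
        for cls, (rlo, rhi) in self.nc_ratio_by_class.items():
            if not (0 < rlo < rhi < 1):
                raise ValueError(f"nc ratio interval for {cls!r} must lie in (0,1)")


@dataclass
class LabeledSample:
    """One image + whole-cell mask + class label."""

    image: np.ndarray  # (H, W, 3) float in [0,1]
    mask: np.ndarray   # (H, W) uint8 in {0,1}
    label: str
    meta: dict = field(default_factory=dict)


def _ellipse_mask(size, cy, cx, ry, rx, theta):
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_cell_image(spec: PhantomSpec, label: str,
                        rng: np.random.Generator) -> LabeledSample:
    """Draw one phantom whose measured N/C area ratio falls in the class interval."""
    if label not in spec.nc_ratio_by_class:
        raise KeyError(f"unknown label {label!r}; known: {sorted(spec.nc_ratio_by_class)}")
    rlo, rhi = spec.nc_ratio_by_class[label]
    s = spec.image_size
    lo, hi = spec.cytoplasm_radius_range
    # shrink the target interval so pixelisation cannot push the ratio out
    margin = 0.08 * (rhi - rlo)
    target = rng.uniform(rlo + margin, rhi - margin)

    rx = rng.uniform(lo, hi) * s
    ry = rng.uniform(lo, hi) * s
    theta = rng.uniform(0, np.pi)
    rmax = max(rx, ry)
    cy = rng.uniform(rmax + 1, s - rmax - 1)
    cx = rng.uniform(rmax + 1, s - rmax - 1)

    cyto = _ellipse_mask(s, cy, cx, ry, rx, theta)
    if not cyto.any():
        raise ValueError("infeasible geometry: empty cytoplasm")
    # nucleus: concentric ellipse scaled so that area ratio ~= target,
    # with a small random centre offset that keeps it strictly inside
    scale = np.sqrt(target)
    if scale >= 0.95:
        raise ValueError("infeasible geometry: nucleus would touch the cytoplasm edge")
    off = (1 - scale) * 0.3
    ocy = cy + rng.uniform(-off, off) * ry
    ocx = cx + rng.uniform(-off, off) * rx
    nuc = _ellipse_mask(s, ocy, ocx, ry * scale, rx * scale, theta)
    nuc &= cyto

    mask = (cyto | nuc).astype(np.uint8)
    img = np.empty((s, s, 3), dtype=np.float64)
    img[:] = spec.stain_palette["background"]
    img[cyto & ~nuc] = spec.stain_palette["cytoplasm"]
    img[nuc] = spec.stain_palette["nucleus"]
    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, img.shape)
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    img = np.clip(img, 0, 1).astype(np.float32)

    meta = {"label": label, "target_nc_ratio": float(target),
            "measured_nc_ratio": float(nuc.sum() / mask.sum()),
            "center": (float(cy), float(cx)), "radii": (float(ry), float(rx)),
            "theta": float(theta),
            "cytoplasm_mask": cyto, "nucleus_mask": nuc}
    return LabeledSample(image=img, mask=mask, label=label, meta=meta)


def generate_dataset(spec: PhantomSpec, class_counts: dict, seed: int | None = None):
    """Generate ``sum(counts)`` phantoms plus a manifest table.

    Returns ``(samples, manifest)`` where the manifest is a DataFrame with
    columns (filename, mask_filename, label, seed); filenames are the names
    ``write_dataset`` would use.
    """
    if not class_counts:
        raise ValueError("class_counts must not be empty")
    if any(c < 0 for c in class_counts.values()):
        raise ValueError("class counts must be >= 0")
    if seed is None:
        seed = spec.seed
    samples: list[LabeledSample] = []
    rows = []
    i = 0
    for label in sorted(class_counts):
        for _ in range(class_counts[label]):
            sub = np.random.default_rng([seed, i])
            sample = generate_cell_image(spec, label, sub)
            sample.meta["seed"] = (seed, i)
            samples.append(sample)
            rows.append({"filename": f"img_{i:05d}.png",
                         "mask_filename": f"mask_{i:05d}.png",
                         "label": label, "seed": i})
            i += 1
    manifest = pd.DataFrame(rows, columns=["filename", "mask_filename", "label", "seed"])
    return samples, manifest


def write_herlev_style_mask(sample: LabeledSample, region_palette: dict | None = None):
    """Render the sample's regions as a colour mask (Herlev-style ground truth).

    Round-tripping through :func:`papcell.preprocess.color_mask_to_binary`
    with the palette's background colour reproduces ``sample.mask`` exactly.
    """
    palette = region_palette or HERLEV_REGION_PALETTE
    colors = list(palette.values())
    if len({tuple(c) for c in colors}) != len(colors):
        raise ValueError("region palette assigns the same colour to two regions")
    s = sample.mask.shape[0]
    out = np.empty((s, s, 3), dtype=np.uint8)
    out[:] = palette["background"]
    cyto = sample.meta.get("cytoplasm_mask")
    nuc = sample.meta.get("nucleus_mask")
    if cyto is None:  # fall back to the binary mask only
        out[sample.mask.astype(bool)] = palette["cytoplasm"]
    else:
        out[cyto & ~nuc] = palette["cytoplasm"]
        out[nuc] = palette["nucleus"]
    return out


def write_dataset(samples, manifest: pd.DataFrame, outdir: str):
    """Write images/masks as 8-bit PNG plus manifest.csv; returns the manifest path."""
    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    for sample, row in zip(samples, manifest.itertuples()):
        iio.imwrite(os.path.join(outdir, row.filename),
                    (sample.image * 255).round().astype(np.uint8))
        iio.imwrite(os.path.join(outdir, row.mask_filename),
                    (sample.mask * 255).astype(np.uint8))
    path = os.path.join(outdir, "manifest.csv")
    manifest.to_csv(path, index=False)
    return path
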