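"""Image/mask I/O and preprocessing: resize to 224x224, [0,1] normalization,
brightness/contrast, colour->binary mask conversion, threshold masks, ROI.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = ["load_image", "resize_normalize", "resize_mask",
           "adjust_brightness_contrast", "color_mask_to_binary",
           "threshold_mask_from_image", "binarize_prediction", "apply_roi",
           "save_image", "save_mask", "load_dataset"]


def load_image(path) -> np.ndarray:
    """Read a BMP/PNG/JPEG raster as (H, W, 3) uint8; grayscale is replicated."""
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface the path in the error
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def save_image(path, img01: np.ndarray):
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(img01, 0, 1) * 255).round().astype(np.uint8))


def save_mask(path, mask: np.ndarray):
    """Masks on disk are single-channel PNG, 0 = background, 255 = cell."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def resize_normalize(img: np.ndarray, target: int = 224) -> np.ndarray:
    """Bilinear resize to target x target and scale to [0,1] float32."""
    if target < 8:
        raise ValueError("target size must be >= 8")
    img = np.asarray(img)
    if img.dtype != np.float32 and img.dtype != np.float64:
        img = img.astype(np.float32) / 255.0
    if img.shape[0] != target or img.shape[1] != target:
        img = _sk_resize(img, (target, target), order=1, mode="edge",
                         anti_aliasing=img.shape[0] > target, preserve_range=True)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def resize_mask(mask: np.ndarray, target: int) -> np.ndarray:
    """Nearest-neighbour resize; keeps masks strictly binary."""
    mask = np.asarray(mask)
    if mask.shape[0] == target and mask.shape[1] == target:
        return mask.astype(np.uint8)
    out = _sk_resize(mask.astype(np.float32), (target, target), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def adjust_brightness_contrast(img: np.ndarray, gain: float = 1.0,
                               bias: float = 0.0) -> np.ndarray:
    """Affine brightness/contrast: clip(gain * img + bias, 0, 1)."""
    if gain <= 0:
        raise ValueError("gain must be > 0")
    return np.clip(gain * np.asarray(img, dtype=np.float32) + bias, 0.0, 1.0)


def color_mask_to_binary(color_mask: np.ndarray, background_color,
                         tolerance: float = 0.0) -> np.ndarray:
    """Binary whole-cell mask: 0 where within tolerance of the background colour."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    cm = np.asarray(color_mask, dtype=np.int32)
    bg = np.asarray(background_color, dtype=np.int32)
    is_bg = (np.abs(cm - bg) <= tolerance).all(axis=-1)
    return (~is_bg).astype(np.uint8)


def _luminance(img: np.ndarray) -> np.ndarray:
    return img @ np.asarray([0.299, 0.587, 0.114], dtype=img.dtype)


def threshold_mask_from_image(img: np.ndarray, threshold: float = 0.1):
    """Automated whole-cell mask: pixels whose luminance departs from the modal
    background luminance by more than ``threshold``; largest connected
    component kept.  Returns ``(mask, warning)`` where warning flags an empty
    foreground.  This is an automated stand-in for hand-drawn masks.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0,1)")
    lum = _luminance(np.asarray(img, dtype=np.float32))
    hist, edges = np.histogram(lum, bins=64, range=(0, 1))
    mode = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
    fg = np.abs(lum - mode) > threshold
    if not fg.any():
        return np.zeros(lum.shape, dtype=np.uint8), True
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        fg = labels == keep
    fg = ndimage.binary_fill_holes(fg)
    return fg.astype(np.uint8), False


def binarize_prediction(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map at ``threshold`` (>= rule)."""
    p = np.asarray(prob_map)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0,1]")
    return (p >= threshold).astype(np.uint8)


def apply_roi(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Region of interest: per-channel product of image and binary mask."""
    img = np.asarray(img)
    mask = np.asarray(mask)
    if img.shape[:2] != mask.shape[:2]:
        raise ValueError(f"shape mismatch: image {img.shape[:2]} vs mask {mask.shape[:2]}")
    return (img * mask[..., None]).astype(np.float32)


def load_dataset(directory, image_size: int | None = None):
    """Read a ``manifest.csv`` dataset directory back into LabeledSamples.

    Expects the layout written by :func:`papcell.phantoms.write_dataset`:
    per-row image and mask PNGs.  When ``image_size`` is given, images are
    resized/normalized and masks nearest-resized to that size; otherwise
    images are normalized at native size.
    """
    import os

    import pandas as pd

    from .phantoms import LabeledSample

    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    samples = []
    for row in manifest.itertuples():
        img = load_image(os.path.join(directory, row.filename)).astype(np.float32) / 255.0
        mask_path = os.path.join(directory, row.mask_filename) \
            if isinstance(getattr(row, "mask_filename", None), str) else None
        mask = None
        if mask_path and os.path.exists(mask_path):
            m = load_image(mask_path)
            mask = (m[..., 0] > 127).astype(np.uint8)
        if image_size is not None:
            img = resize_normalize(img, image_size)
            if mask is not None:
                mask = resize_mask(mask, image_size)
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        origin = getattr(row, "origin", "real")
        if not isinstance(origin, str):
            origin = "real"
        samples.append(LabeledSample(
            image=img, mask=mask, label=row.label,
            meta={"filename": row.filename, "origin": origin}))
    return samples, manifest
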