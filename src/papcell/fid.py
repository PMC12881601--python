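"""Frechet Inception Distance between real and generated image collections.

FID fits a Gaussian to each collection's feature embedding and reports

    ||mu_r - mu_f||^2 + Tr(S_r + S_f - 2 (S_r S_f)^{1/2})

The embedding is pluggable: any callable mapping an image batch to (n, d)
features.  The default is a fixed, seeded random-projection embedding of the
flattened pixels, which keeps the statistic fully reproducible offline; an
inception-style network can be passed in where available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["FidScore", "RandomProjectionEmbedding", "compute_fid"]


@dataclass(frozen=True)
class FidScore:
    value: float
    embedding_name: str
    n_real: int
    n_fake: int


class RandomProjectionEmbedding:
    """Fixed Gaussian random projection of flattened pixels to ``dim`` features.

    The projection matrix is drawn once from ``seed`` for a given input
    dimensionality, so the embedding is deterministic across calls and across
    the two collections being compared.
    """

    name = "random_projection"

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        self.dim = dim
        self.seed = seed
        self._mats: dict[int, np.ndarray] = {}

    def __call__(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        x = x.reshape(len(x), -1)
        d = x.shape[1]
        if d not in self._mats:
            rng = np.random.default_rng(self.seed)
            self._mats[d] = rng.standard_normal((d, self.dim)) / np.sqrt(d)
        return x @ self._mats[d]


def _gaussian_stats(feats: np.ndarray):
    mu = feats.mean(axis=0)
    sigma = np.cov(feats, rowvar=False)
    return mu, np.atleast_2d(sigma)


def compute_fid(real, fake, embedding=None, jitter: float = 1e-6) -> FidScore:
    """FID between two image (or feature) collections.

    ``real``/``fake`` are arrays whose first axis indexes samples; if
    ``embedding`` is None and the inputs are already 2-D they are used as
    features directly, otherwise the default random-projection embedding is
    applied.  The covariance square root is symmetrized and stabilized with a
    small diagonal jitter when needed.
    """
    real = np.asarray(real)
    fake = np.asarray(fake)
    if len(real) < 2 or len(fake) < 2:
        raise ValueError("need at least 2 samples per collection")
    if embedding is None:
        embedding = (lambda x: np.asarray(x, dtype=np.float64)) \
            if real.ndim == 2 else RandomProjectionEmbedding()
    fr = np.asarray(embedding(real), dtype=np.float64)
    ff = np.asarray(embedding(fake), dtype=np.float64)
    mu_r, s_r = _gaussian_stats(fr)
    mu_f, s_f = _gaussian_stats(ff)
    diff = mu_r - mu_f
    covmean = np.asarray(linalg.sqrtm(s_r @ s_f))
    if not np.isfinite(covmean).all():
        warnings.warn("singular covariance product; applying diagonal jitter")
        eye = np.eye(s_r.shape[0]) * jitter
        covmean = np.asarray(linalg.sqrtm((s_r + eye) @ (s_f + eye)))
    covmean = covmean.real
    covmean = 0.5 * (covmean + covmean.T)
    value = float(diff @ diff + np.trace(s_r + s_f - 2.0 * covmean))
    value = max(value, 0.0) if abs(value) < 1e-6 else value
    name = getattr(embedding, "name", getattr(embedding, "__name__", "custom"))
    return FidScore(value=value, embedding_name=name,
                    n_real=len(fr), n_fake=len(ff))
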