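"""Texture statistics of a normalized co-occurrence matrix.

The five statistics summarise a k x k normalized pair-frequency matrix G the
way gray-level co-occurrence texture descriptors summarise an image:

* energy        = sum G_ij^2                   (uniformity of the distribution)
* entropy       = -sum G_ij * log2(G_ij + eps) (randomness, in bits)
* homogeneity   = sum G_ij / (1 + (i-j)^2)     (mass near the diagonal)
* contrast      = sum (i-j)^2 * G_ij           (mass far from the diagonal)
* dissimilarity = sum |i-j| * G_ij

Indices i, j are 1-based row/column positions; only differences enter, so
the origin is cosmetic.  ``eps`` guards log(0); the default 1e-12 is
negligible against the smallest possible nonzero entry 1/k^2 >= 1/400.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .composition import CooccurrenceMatrix

__all__ = ["TextureFeatures", "TEXTURE_STAT_NAMES", "texture_features"]

#: Canonical feature order within a texture block.
TEXTURE_STAT_NAMES: tuple[str, ...] = (
    "energy",
    "entropy",
    "homogeneity",
    "contrast",
    "dissimilarity",
)


@dataclass(frozen=True)
class TextureFeatures:
    energy: float
    entropy: float
    homogeneity: float
    contrast: float
    dissimilarity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


def texture_features(matrix: CooccurrenceMatrix, eps: float = 1e-12) -> TextureFeatures:
    """Compute the five texture statistics of a (normalized) matrix.

    An all-zero matrix (no pairs at this offset) yields all-zero
    statistics; entropy is then exactly ``-k^2 * 0 * log2(eps) = 0``.
    """
    g = matrix.values
    k = g.shape[0]
    idx = np.arange(1, k + 1)
    diff = idx[:, None] - idx[None, :]
    energy = float(np.sum(g**2))
    entropy = float(-np.sum(g * np.log2(g + eps)))
    homogeneity = float(np.sum(g / (1.0 + diff**2)))
    contrast = float(np.sum(diff**2 * g))
    dissimilarity = float(np.sum(np.abs(diff) * g))
    return TextureFeatures(
        energy=energy,
        entropy=entropy,
        homogeneity=homogeneity,
        contrast=contrast,
        dissimilarity=dissimilarity,
    )
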