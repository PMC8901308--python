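"""Region features for a masked image area.

First-order statistics, shape descriptors, and co-occurrence texture at unit
horizontal/vertical offsets, computed strictly inside the mask (pairs with
either pixel outside the mask are discarded, so anything beyond the mask
cannot leak into the values).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from skimage.measure import perimeter_crofton
from skimage.morphology import convex_hull_image

GLCM_LEVELS = 16


@dataclass
class FirstOrderFeatures:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    entropy: float


@dataclass
class ShapeFeatures:
    area: int
    perimeter: float
    circularity: float
    solidity: float


@dataclass
class TextureFeatures:
    """Co-occurrence statistics on 16-level quantization; ``_h`` is the
    (1,0) x-offset, ``_v`` the (0,1) y-offset."""

    contrast_h: float
    contrast_v: float
    homogeneity_h: float
    homogeneity_v: float
    energy_h: float
    energy_v: float
    correlation_h: float
    correlation_v: float


@dataclass
class RegionFeatures:
    first_order: FirstOrderFeatures
    shape: ShapeFeatures
    texture: TextureFeatures

    def as_dict(self) -> dict:
        flat = {}
        for group in (self.first_order, self.shape, self.texture):
            flat.update(asdict(group))
        return flat


def _quantize(pixels: np.ndarray) -> np.ndarray:
    q = np.floor(np.clip(pixels, 0.0, 1.0) * GLCM_LEVELS).astype(int)
    return np.clip(q, 0, GLCM_LEVELS - 1)


def _masked_glcm(q: np.ndarray, mask: np.ndarray, offset: tuple) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix over in-mask pixel pairs."""
    dy, dx = offset[1], offset[0]
    h, w = q.shape
    src = np.zeros((h, w), dtype=bool)
    src[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)] = True
    valid = src & mask & np.roll(np.roll(mask, -dy, axis=0), -dx, axis=1)
    i = q[valid]
    j = np.roll(np.roll(q, -dy, axis=0), -dx, axis=1)[valid]
    glcm = np.zeros((GLCM_LEVELS, GLCM_LEVELS), dtype=float)
    np.add.at(glcm, (i, j), 1.0)
    glcm = glcm + glcm.T  # symmetric accumulation
    total = glcm.sum()
    if total == 0:
        return glcm
    return glcm / total


def _glcm_props(P: np.ndarray) -> tuple:
    idx = np.arange(GLCM_LEVELS)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    if P.sum() == 0:
        return 0.0, 1.0, 1.0, 1.0
    contrast = float((P * (ii - jj) ** 2).sum())
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    energy = float(np.sqrt((P**2).sum()))
    mu_i = float((P * ii).sum())
    mu_j = float((P * jj).sum())
    var_i = float((P * (ii - mu_i) ** 2).sum())
    var_j = float((P * (jj - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0  # degenerate single-level region
    else:
        correlation = float((P * (ii - mu_i) * (jj - mu_j)).sum() / np.sqrt(var_i * var_j))
    return contrast, homogeneity, energy, correlation


def extract_features(pixels: np.ndarray, mask: np.ndarray) -> RegionFeatures:
    """Compute the full feature vector of the masked region."""
    pixels = np.asarray(pixels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pixels.shape != mask.shape:
        raise ValueError("pixels and mask shapes differ")
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    vals = pixels[mask]

    mean = float(vals.mean())
    if np.ptp(vals) == 0:
        sd = 0.0
        skew = kurt = 0.0  # undefined for constant regions; reported as 0
    else:
        sd = float(vals.std())
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals))  # excess (Fisher) kurtosis
    hist, _ = np.histogram(vals, bins=GLCM_LEVELS, range=(0.0, 1.0))
    p = hist[hist > 0] / hist.sum()
    entropy = float(stats.entropy(p, base=2))

    area = int(mask.sum())
    perim = float(perimeter_crofton(mask, directions=4))
    circularity = 1.0 if perim == 0 else float(4.0 * np.pi * area / perim**2)
    hull_area = int(convex_hull_image(mask).sum())
    solidity = float(area / hull_area)

    glcm_h = _masked_glcm(_quantize(pixels), mask, (1, 0))
    glcm_v = _masked_glcm(_quantize(pixels), mask, (0, 1))
    ch, hh, eh, rh = _glcm_props(glcm_h)
    cv, hv, ev, rv = _glcm_props(glcm_v)

    return RegionFeatures(
        first_order=FirstOrderFeatures(mean, sd, skew, kurt, entropy),
        shape=ShapeFeatures(area, perim, circularity, solidity),
        texture=TextureFeatures(ch, cv, hh, hv, eh, ev, rh, rv),
    )
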