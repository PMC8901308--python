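"""Multilevel threshold segmentation driven by binary swarm search.

Thresholds are encoded as gray-coded 8-bit integers (one group of bits per
level) and scored by the multilevel between-class variance (Otsu) criterion
on a 256-bin intensity histogram.  The swarm maximizes the criterion; the
returned foreground is the intensity class whose mean is farthest from the
dominant background mode.  For a single threshold the 256-point exhaustive
scan provides an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .swarm import SwarmConfig, run_optimizer

N_BINS = 256


@dataclass
class ThresholdEncoding:
    """Bit layout of a threshold vector: ``n_levels`` thresholds, each a
    gray-coded integer of ``bits_per_level`` bits mapped to [0, 1]."""

    n_levels: int = 1
    bits_per_level: int = 8

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.bits_per_level < 1:
            raise ValueError("bits_per_level must be >= 1")

    @property
    def dims(self) -> int:
        return self.n_levels * self.bits_per_level

    def decode(self, bits: np.ndarray) -> np.ndarray:
        """Bits -> sorted, de-duplicated thresholds in [0, 1]."""
        bits = np.asarray(bits).astype(int).reshape(self.n_levels, self.bits_per_level)
        # gray -> binary: b[0] = g[0], b[i] = b[i-1] xor g[i]
        binary = np.cumsum(bits, axis=1) % 2
        weights = 2 ** np.arange(self.bits_per_level - 1, -1, -1)
        ints = binary @ weights
        values = ints / (2**self.bits_per_level - 1)
        return np.unique(values)


def image_histogram(pixels: np.ndarray) -> tuple:
    """256-bin histogram of an image in [0, 1]; returns (counts, centers)."""
    pixels = np.asarray(pixels, dtype=float)
    counts, edges = np.histogram(pixels, bins=N_BINS, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def otsu_objective(counts: np.ndarray, centers: np.ndarray, thresholds: np.ndarray) -> float:
    """Between-class variance sum w_c (mu_c - mu)^2 for the classes induced
    by the thresholds (class of bin = number of thresholds <= its center)."""
    p = counts / counts.sum()
    mu = float(p @ centers)
    labels = np.searchsorted(np.sort(np.asarray(thresholds, dtype=float)), centers, side="right")
    obj = 0.0
    for c in np.unique(labels):
        sel = labels == c
        w = p[sel].sum()
        if w > 0:
            mu_c = float(p[sel] @ centers[sel]) / w
            obj += w * (mu_c - mu) ** 2
    return float(obj)


def exhaustive_threshold_scan(pixels: np.ndarray) -> tuple:
    """Exact single-threshold oracle: evaluate all 256 8-bit thresholds.

    Returns ``(best_threshold, best_objective)``; ties resolve to the lowest
    threshold.
    """
    counts, centers = image_histogram(pixels)
    best_t, best_obj = 0.0, -np.inf
    for k in range(2**8):
        t = k / (2**8 - 1)
        obj = otsu_objective(counts, centers, np.array([t]))
        if obj > best_obj:
            best_obj, best_t = obj, t
    return best_t, best_obj


@dataclass
class SegmentationResult:
    mask: np.ndarray = field(repr=False)
    thresholds: np.ndarray
    objective: float


def _select_foreground(pixels: np.ndarray, thresholds: np.ndarray, counts, centers) -> np.ndarray:
    """Pick the intensity class whose mean is farthest from the background
    mode (the histogram's tallest bin) — phantoms guarantee a dominant
    background, so the lesion is the most contrasted class."""
    mode_value = centers[int(np.argmax(counts))]
    labels = np.searchsorted(np.sort(thresholds), pixels.ravel(), side="right").reshape(
        pixels.shape
    )
    best_c, best_dist = None, -1.0
    for c in np.unique(labels):
        mean_c = pixels[labels == c].mean()
        dist = abs(mean_c - mode_value)
        if dist > best_dist:
            best_dist, best_c = dist, c
    return labels == best_c


class BPSOThresholdSegmenter(BaseEstimator):
    """Estimator wrapping swarm-searched multilevel Otsu thresholding.

    ``fit(image)`` searches the thresholds for that image and stores
    ``thresholds_``, ``objective_`` and ``mask_``; ``segment(image)`` applies
    the fitted thresholds to a (possibly different) image.
    """

    def __init__(
        self,
        n_levels: int = 1,
        bits_per_level: int = 8,
        n_particles: int = 20,
        n_iterations: int = 30,
        variant: str = "modified_binary",
        random_state: int = 0,
    ):
        self.n_levels = n_levels
        self.bits_per_level = bits_per_level
        self.n_particles = n_particles
        self.n_iterations = n_iterations
        self.variant = variant
        self.random_state = random_state

    def fit(self, image, y=None):
        pixels = np.asarray(image, dtype=float)
        if pixels.ndim != 2:
            raise ValueError("image must be 2-D grayscale")
        if np.ptp(pixels) == 0:
            raise ValueError("flat image: no separable intensity classes")
        enc = ThresholdEncoding(self.n_levels, self.bits_per_level)
        counts, centers = image_histogram(pixels)

        def fitness(bits):
            return otsu_objective(counts, centers, enc.decode(bits))

        config = SwarmConfig(
            n_particles=self.n_particles,
            dims=enc.dims,
            n_iterations=self.n_iterations,
            variant=self.variant,
            seed=self.random_state,
        )
        res = run_optimizer(fitness, config)
        self.encoding_ = enc
        self.thresholds_ = enc.decode(res.best_position)
        self.objective_ = float(res.best_fitness)
        self.n_evaluations_ = res.evaluations
        self.mask_ = _select_foreground(pixels, self.thresholds_, counts, centers)
        return self

    def segment(self, image) -> np.ndarray:
        pixels = np.asarray(image, dtype=float)
        counts, centers = image_histogram(pixels)
        return _select_foreground(pixels, self.thresholds_, counts, centers)


def bpso_threshold_segment(
    image: np.ndarray,
    config: Optional[SwarmConfig] = None,
    n_levels: int = 1,
    bits_per_level: int = 8,
) -> SegmentationResult:
    """Swarm-searched multilevel Otsu segmentation of one image.

    When a :class:`SwarmConfig` is given, its ``dims`` must equal
    ``n_levels * bits_per_level``.
    """
    enc = ThresholdEncoding(n_levels, bits_per_level)
    if config is not None and config.dims != enc.dims:
        raise ValueError(f"config.dims={config.dims} must equal n_levels*bits_per_level={enc.dims}")
    kwargs = dict(n_levels=n_levels, bits_per_level=bits_per_level)
    if config is not None:
        kwargs.update(
            n_particles=config.n_particles,
            n_iterations=config.n_iterations,
            variant=config.variant,
            random_state=config.seed,
        )
    seg = BPSOThresholdSegmenter(**kwargs).fit(image)
    return SegmentationResult(mask=seg.mask_, thresholds=seg.thresholds_, objective=seg.objective_)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * (a & b).sum() / denom)
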