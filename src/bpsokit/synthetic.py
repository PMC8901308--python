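"""Synthetic data generators.

Two generators stand in for clinical material that cannot be redistributed:

* **Tumor phantoms** — 2-D grayscale images with an elliptical lesion over a
  darker background.  Benign lesions are smooth and homogeneous (clear
  boundary, uniform signal); malignant lesions get a lobulated boundary
  (low-order Fourier perturbation of the ellipse radius) and multiplicative
  intra-tumor speckle (mixed signal).  Ground-truth masks are returned with
  every image.
* **Feature tables** — two-class Gaussian tables with a known informative
  subset: informative columns shift their class-1 mean by ``effect_size``
  within-class standard deviations; noise columns are class-independent.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .selection import FeatureTable

TUMOR_CLASSES = ("benign", "malignant")


@dataclass
class PhantomSpec:
    """Geometry and texture parameters of one phantom.

    Grayscale convention: floats in [0, 1], row-major, origin top-left.
    ``axes`` are the ellipse semi-axes in pixels; ``boundary_lobulation`` is
    the SD (pixels) of the radial boundary perturbation;
    ``heterogeneity_sigma`` the SD of the multiplicative intra-tumor speckle;
    ``noise_sigma`` the SD of the additive pixel noise.  Benign phantoms are
    always generated with lobulation and heterogeneity forced to zero
    (smooth, homogeneous), regardless of the field values.
    """

    width: int = 128
    height: int = 128
    tumor_class: str = "malignant"
    tumor_center: Optional[tuple] = None
    axes: tuple = (30.0, 22.0)
    background_level: float = 0.2
    tumor_level: float = 0.7
    heterogeneity_sigma: float = 0.2
    boundary_lobulation: float = 4.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_class not in TUMOR_CLASSES:
            raise ValueError(f"tumor_class must be one of {TUMOR_CLASSES}")
        if self.width < 8 or self.height < 8:
            raise ValueError("image must be at least 8x8 pixels")
        if self.tumor_center is None:
            self.tumor_center = (self.width / 2.0, self.height / 2.0)
        a, b = self.axes
        cx, cy = self.tumor_center
        if a <= 0 or b <= 0:
            raise ValueError("ellipse axes must be positive")
        if not (a < cx < self.width - a and b < cy < self.height - b):
            raise ValueError("ellipse does not fit inside the image")
        for name in ("background_level", "tumor_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.heterogeneity_sigma < 0 or self.boundary_lobulation < 0 or self.noise_sigma < 0:
            raise ValueError("sigma parameters must be >= 0")


@dataclass
class PhantomImage:
    pixels: np.ndarray
    truth_mask: np.ndarray
    label: str
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.truth_mask.sum() == 0:
            raise ValueError("truth mask is empty")


@dataclass
class SyntheticFeatureSpec:
    """Conditions of a synthetic two-class feature table."""

    n_samples: int = 200
    n_informative: int = 5
    n_noise: int = 15
    effect_size: float = 1.5
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie in (0, 1)")
        n1 = round(self.n_samples * self.class_balance)
        if n1 < 2 or self.n_samples - n1 < 2:
            raise ValueError("each class needs at least 2 samples")


def _lobulation_profile(theta: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random radial perturbation: Fourier orders 3-7, scaled so its
    SD over angle equals ``amplitude`` pixels."""
    if amplitude == 0:
        # consume the coefficient draws anyway to keep draw order fixed
        rng.normal(size=(5, 2))
        return np.zeros_like(theta)
    coef = rng.normal(size=(5, 2))
    prof = np.zeros_like(theta)
    for row, k in zip(coef, range(3, 8)):
        prof += row[0] * np.cos(k * theta) + row[1] * np.sin(k * theta)
    sd = prof.std()
    if sd > 0:
        prof *= amplitude / sd
    return prof


def generate_phantom(spec: PhantomSpec) -> PhantomImage:
    """Render one phantom; deterministic per ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lob = spec.boundary_lobulation
    het = spec.heterogeneity_sigma
    if spec.tumor_class == "benign":
        lob, het = 0.0, 0.0
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cx, cy = spec.tumor_center
    a, b = spec.axes
    dx, dy = xx - cx, yy - cy
    rho = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    theta = np.arctan2(dy, dx)
    mean_axis = 0.5 * (a + b)
    perturb = _lobulation_profile(theta, lob, rng)
    mask = rho <= 1.0 + perturb / mean_axis
    pixels = np.full((spec.height, spec.width), spec.background_level, dtype=float)
    tumor = np.full(mask.sum(), spec.tumor_level)
    if het > 0:
        field = rng.normal(size=(spec.height, spec.width))
        field = gaussian_filter(field, sigma=2.0)
        sd = field[mask].std()
        if sd > 0:
            field = field / sd * het
        tumor = spec.tumor_level * (1.0 + field[mask])
    else:
        rng.normal(size=(spec.height, spec.width))  # fixed draw order
    pixels[mask] = tumor
    if spec.noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sigma, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)
    return PhantomImage(pixels=pixels, truth_mask=mask, label=spec.tumor_class, spec=spec)


def generate_cohort(
    n: int, malignant_fraction: float, base_spec: PhantomSpec | None = None, seed: int = 0
) -> list:
    """Generate ``n`` phantoms with jittered geometry and exact class counts
    ``round(n * malignant_fraction)`` malignant; deterministic per seed."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 phantoms")
    if not (0.0 < malignant_fraction < 1.0):
        raise ValueError("malignant_fraction must lie in (0, 1)")
    base = base_spec or PhantomSpec()
    n_mal = round(n * malignant_fraction)
    labels = np.array(["malignant"] * n_mal + ["benign"] * (n - n_mal))
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    cohort = []
    for label in labels:
        a0, b0 = base.axes
        a = a0 * rng.uniform(0.8, 1.2)
        b = b0 * rng.uniform(0.8, 1.2)
        cx = base.width / 2.0 + rng.uniform(-0.1, 0.1) * base.width / 2.0
        cy = base.height / 2.0 + rng.uniform(-0.1, 0.1) * base.height / 2.0
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base,
            tumor_class=str(label),
            tumor_center=(cx, cy),
            axes=(a, b),
            seed=sub_seed,
        )
        cohort.append(generate_phantom(spec))
    return cohort


def generate_feature_table(spec: SyntheticFeatureSpec) -> FeatureTable:
    """Draw a labelled feature table with a known informative subset.

    Informative columns: N(0,1) in class 0 vs N(effect_size, 1) in class 1.
    Noise columns: N(0,1) regardless of class.  Informative columns are
    placed at seeded random positions; ``informative_mask`` records them.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_informative + spec.n_noise
    n1 = round(n * spec.class_balance)
    labels = np.array([1] * n1 + [0] * (n - n1))
    rng.shuffle(labels)
    X = rng.normal(size=(n, d))
    positions = rng.permutation(d)[: spec.n_informative]
    mask = np.zeros(d, dtype=bool)
    mask[positions] = True
    X[np.ix_(labels == 1, mask)] += spec.effect_size
    names = [
        f"feat_{i:03d}" for i in range(d)
    ]
    return FeatureTable(values=X, labels=labels, feature_names=names, informative_mask=mask)
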