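"""Deterministic synthetic fixtures for both fusion regimes.

No public image-fusion benchmark ships with this package, so every test and
demo runs on generated data with known ground truth:

* **Multifocus pairs** — a sharp "all-in-focus" truth image (band-limited
  texture plus geometric shapes with edges at several orientations) is
  blurred region-wise: source A is sharp where the true depth map is 1 and
  Gaussian-blurred elsewhere; source B is the complement.  The fixture
  carries the truth image and the true map, so decision-map accuracy and
  fused RMSE are directly measurable.  Blur is a hard-masked composite of
  the globally blurred image, so a band of about 3 sigma around the depth
  boundary contains blur-tail leakage and is excluded from accuracy scoring.

* **Multimodal pairs** — a Shepp-Logan-like head phantom of nested ellipses
  (background, skull, two soft tissues, a lesion) rendered twice with
  different contrast tables: the CT-like view maps the skull bright and soft
  tissue flat; the MR-like view maps the skull dark and the tissues and
  lesion distinct.  Both share the identical geometry grid (perfect
  registration); additive Gaussian noise is clipped to [0, 1].

All generators are bit-exact reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import Image2D

__all__ = [
    "MultifocusFixture",
    "MultimodalFixture",
    "make_texture",
    "make_multifocus",
    "make_multimodal",
    "REGIONS",
    "CT_CONTRAST",
    "MR_CONTRAST",
]

REGIONS = ("background", "skull", "tissue_a", "tissue_b", "lesion")

# Contrast tables: CT-like is bone-bright with flat soft tissue; MR-like is
# skull-dark with distinct soft-tissue levels and a conspicuous lesion.
CT_CONTRAST = {"background": 0.02, "skull": 0.95, "tissue_a": 0.25,
               "tissue_b": 0.30, "lesion": 0.33}
MR_CONTRAST = {"background": 0.02, "skull": 0.10, "tissue_a": 0.70,
               "tissue_b": 0.40, "lesion": 0.90}


@dataclass(frozen=True)
class MultifocusFixture:
    source_a: Image2D
    source_b: Image2D
    truth: Image2D
    true_map: np.ndarray  # 1 where A is the in-focus source
    sigma: float
    split: str
    seed: int

    def boundary_band(self, width: "float | None" = None) -> np.ndarray:
        """Boolean mask of pixels within ``width`` (default 3 sigma) of the
        depth boundary, where blur leakage makes focus ambiguous."""
        from scipy.ndimage import distance_transform_edt

        if width is None:
            width = 3.0 * self.sigma
        inside = self.true_map == 1
        d_in = distance_transform_edt(inside)
        d_out = distance_transform_edt(~inside)
        return np.maximum(d_in, d_out) <= width


@dataclass(frozen=True)
class MultimodalFixture:
    ct_like: Image2D
    mr_like: Image2D
    geometry: np.ndarray  # region labels, indices into REGIONS
    noise_sigma: float
    seed: int


def make_texture(shape: tuple[int, int] = (256, 256), seed: int = 0) -> Image2D:
    """Band-limited random texture with superimposed oriented structures."""
    rows, cols = shape
    if rows < 64 or cols < 64:
        raise ValueError("texture shape must be at least 64x64")
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.standard_normal(shape), 2.0)
    base += 0.5 * gaussian_filter(rng.standard_normal(shape), 6.0)
    yy, xx = np.mgrid[0:rows, 0:cols]
    # oriented bars and discs give edges at several orientations
    for _ in range(8):
        cy, cx = rng.uniform(0.15, 0.85) * rows, rng.uniform(0.15, 0.85) * cols
        angle = rng.uniform(0, np.pi)
        u = (yy - cy) * np.sin(angle) + (xx - cx) * np.cos(angle)
        v = -(yy - cy) * np.cos(angle) + (xx - cx) * np.sin(angle)
        length = rng.uniform(0.1, 0.3) * min(rows, cols)
        thickness = rng.uniform(0.01, 0.04) * min(rows, cols)
        bar = (np.abs(u) < length) & (np.abs(v) < thickness)
        base[bar] += rng.uniform(-1.5, 1.5)
    for _ in range(4):
        cy, cx = rng.uniform(0.2, 0.8) * rows, rng.uniform(0.2, 0.8) * cols
        r = rng.uniform(0.04, 0.12) * min(rows, cols)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 < r * r
        base[disc] += rng.uniform(-1.0, 1.0)
    lo, hi = base.min(), base.max()
    px = (base - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)
    return Image2D(px)


def _split_mask(shape: tuple[int, int], split: str) -> np.ndarray:
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    if split == "left_right":
        return (xx < cols // 2).astype(np.int8)
    if split == "diagonal":
        return (yy * cols + xx * rows < rows * cols).astype(np.int8)
    if split == "disc":
        cy, cx = rows / 2.0, cols / 2.0
        r = 0.3 * min(rows, cols)
        return ((yy - cy) ** 2 + (xx - cx) ** 2 < r * r).astype(np.int8)
    raise ValueError(f"unknown split {split!r}")


def make_multifocus(truth: "Image2D | None" = None, split: str = "left_right",
                    sigma: float = 3.0, seed: int = 0,
                    shape: tuple[int, int] = (256, 256)) -> MultifocusFixture:
    """Complementary region-blurred pair from a sharp ground-truth image."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if truth is None:
        truth = make_texture(shape, seed)
    t = truth.pixels
    true_map = _split_mask(t.shape, split)
    blurred = gaussian_filter(t, sigma)
    a = np.where(true_map == 1, t, blurred)
    b = np.where(true_map == 1, blurred, t)
    return MultifocusFixture(source_a=Image2D(a), source_b=Image2D(b),
                             truth=truth, true_map=true_map,
                             sigma=sigma, split=split, seed=seed)


def _head_geometry(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    u = (yy - cy) / (rows / 2.0)
    v = (xx - cx) / (cols / 2.0)

    def ellipse(dy, dx, ry, rx):
        return ((u - dy) / ry) ** 2 + ((v - dx) / rx) ** 2 < 1.0

    geom = np.zeros(shape, dtype=np.int8)  # background
    geom[ellipse(0, 0, 0.9, 0.75)] = 1     # skull shell
    inner = ellipse(0, 0, 0.78, 0.63)
    geom[inner] = 2                         # tissue A fills the cranium
    geom[inner & ellipse(0.1, 0.18, 0.45, 0.28)] = 3   # tissue B lobe
    geom[inner & ellipse(-0.25, -0.2, 0.14, 0.12)] = 4  # lesion
    return geom


def make_multimodal(shape: tuple[int, int] = (256, 256),
                    contrast_ct: "dict | None" = None,
                    contrast_mr: "dict | None" = None,
                    noise_sigma: float = 0.01, seed: int = 0) -> MultimodalFixture:
    """CT-like / MR-like phantom pair over one shared geometry."""
    contrast_ct = contrast_ct or CT_CONTRAST
    contrast_mr = contrast_mr or MR_CONTRAST
    for table in (contrast_ct, contrast_mr):
        missing = set(REGIONS) - set(table)
        if missing:
            raise ValueError(f"contrast table missing regions {sorted(missing)}")
    geom = _head_geometry(shape)
    rng = np.random.default_rng(seed)
    images = []
    for table in (contrast_ct, contrast_mr):
        lut = np.array([table[name] for name in REGIONS])
        px = lut[geom]
        if noise_sigma > 0:
            px = px + rng.normal(0.0, noise_sigma, size=px.shape)
        images.append(Image2D(np.clip(px, 0.0, 1.0)))
    return MultimodalFixture(ct_like=images[0], mr_like=images[1],
                             geometry=geom, noise_sigma=noise_sigma, seed=seed)
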