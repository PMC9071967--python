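"""Gaussian and Laplacian pyramid analysis, synthesis and pyramid-domain fusion.

The Gaussian pyramid is built by recursive 5x5 binomial low-pass filtering and
dyadic subsampling,

    G_l(i, j) = sum_{m,n=-2..2} w(m, n) G_{l-1}(2i + m, 2j + n),

with the separable window w(m, n) = h(m) h(n), h = [1, 4, 6, 4, 1] / 16, so
the full 5x5 kernel carries an overall factor 1/256 and a central weight
36/256.  Laplacian detail levels are the differences

    LP_l = G_l - EXPAND(G_{l+1}),        LP_N = G_N,

where EXPAND zero-stuffs the coarser level and filters with 4 w; because each
detail level records exactly what the next reduction discarded, synthesis
(`reconstruct`) inverts analysis up to floating-point rounding.

Borders use whole-sample symmetric (mirror-without-repeat) extension, which
preserves constants and therefore gives identically-zero detail levels for a
constant image.  Odd dimensions halve as ceil(n / 2); EXPAND takes the target
shape explicitly so round trips are exact for any size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import Image2D, as_array

__all__ = [
    "WindowKernel",
    "GaussianPyramid",
    "LaplacianPyramid",
    "make_window_kernel",
    "gaussian_reduce",
    "expand",
    "build_pyramids",
    "reconstruct",
    "fuse_lp",
]


@dataclass(frozen=True)
class WindowKernel:
    """Separable 5x5 generating window w(m, n) = h(m) h(n), sum 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (5, 5):
            raise ValueError("window kernel must be 5x5")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("window kernel entries must sum to 1")
        object.__setattr__(self, "weights", w)


def make_window_kernel() -> WindowKernel:
    """The binomial generating kernel: outer product of [1,4,6,4,1]/16."""
    h = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    return WindowKernel(np.outer(h, h))


@dataclass(frozen=True)
class GaussianPyramid:
    """Levels G_0 (source) .. G_N, each ceil-half the size of its predecessor."""

    levels: list[np.ndarray] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels) - 1


@dataclass(frozen=True)
class LaplacianPyramid:
    """Signed detail levels LP_0..LP_{N-1} plus the coarse top LP_N = G_N."""

    details: list[np.ndarray]
    top: np.ndarray

    @property
    def n_levels(self) -> int:
        return len(self.details)

    def __post_init__(self) -> None:
        if not self.details:
            raise ValueError("Laplacian pyramid needs at least one detail level")


def _reflect(idx: np.ndarray, n: int) -> np.ndarray:
    """Whole-sample symmetric index: ..., 2, 1 | 0, 1, ..., n-1 | n-2, n-3, ..."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n - 2
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - idx, idx)


def gaussian_reduce(g_prev: "Image2D | np.ndarray", kernel: WindowKernel | None = None) -> np.ndarray:
    """Low-pass filter and subsample one pyramid level (REDUCE)."""
    a = as_array(g_prev)
    if a.shape[0] < 4 or a.shape[1] < 4:
        raise ValueError(f"input too small to reduce: {a.shape}")
    w = (kernel or make_window_kernel()).weights
    rows = -(-a.shape[0] // 2)
    cols = -(-a.shape[1] // 2)
    out = np.zeros((rows, cols))
    ii = 2 * np.arange(rows)
    jj = 2 * np.arange(cols)
    for m in range(-2, 3):
        ri = _reflect(ii + m, a.shape[0])
        for n in range(-2, 3):
            cj = _reflect(jj + n, a.shape[1])
            out += w[m + 2, n + 2] * a[np.ix_(ri, cj)]
    return out


def expand(g: "Image2D | np.ndarray", kernel: WindowKernel | None = None,
           target_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Interpolate one level up to ``target_shape`` (EXPAND).

    Zero-stuffed upsampling followed by the 5x5 window scaled by 4; only taps
    landing on integer source coordinates contribute.  ``target_shape`` must be
    2*s or 2*s - 1 per axis for a source of size s.
    """
    a = as_array(g)
    w = (kernel or make_window_kernel()).weights
    if target_shape is None:
        target_shape = (2 * a.shape[0], 2 * a.shape[1])
    for t, s in zip(target_shape, a.shape):
        if t not in (2 * s, 2 * s - 1):
            raise ValueError(f"target_shape {target_shape} incompatible with source {a.shape}")
    rows, cols = target_shape
    out = np.zeros((rows, cols))
    ii = np.arange(rows)
    jj = np.arange(cols)
    for m in range(-2, 3):
        num_i = ii + m
        ok_i = num_i % 2 == 0
        pi = _reflect(num_i[ok_i] // 2, a.shape[0])
        for n in range(-2, 3):
            num_j = jj + n
            ok_j = num_j % 2 == 0
            pj = _reflect(num_j[ok_j] // 2, a.shape[1])
            out[np.ix_(ok_i, ok_j)] += 4.0 * w[m + 2, n + 2] * a[np.ix_(pi, pj)]
    return out


def build_pyramids(img: "Image2D | np.ndarray", n_levels: int,
                   kernel: WindowKernel | None = None) -> tuple[GaussianPyramid, LaplacianPyramid]:
    """Decompose an image into its Gaussian and Laplacian pyramids."""
    a = as_array(img)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    kernel = kernel or make_window_kernel()
    levels = [a]
    for _ in range(n_levels):
        if levels[-1].shape[0] < 4 or levels[-1].shape[1] < 4:
            raise ValueError(
                f"image {a.shape} too small for {n_levels} pyramid levels")
        levels.append(gaussian_reduce(levels[-1], kernel))
    details = [
        levels[l] - expand(levels[l + 1], kernel, target_shape=levels[l].shape)
        for l in range(n_levels)
    ]
    return GaussianPyramid(levels), LaplacianPyramid(details, levels[-1])


def reconstruct(lp: LaplacianPyramid, kernel: WindowKernel | None = None) -> np.ndarray:
    """Invert the Laplacian decomposition: G_l = LP_l + EXPAND(G_{l+1})."""
    kernel = kernel or make_window_kernel()
    g = lp.top
    for detail in reversed(lp.details):
        g = detail + expand(g, kernel, target_shape=detail.shape)
    return g


def fuse_lp(pa: LaplacianPyramid, pb: LaplacianPyramid,
            detail_rule=None, top_rule=None) -> LaplacianPyramid:
    """Merge two Laplacian pyramids level by level.

    ``detail_rule``/``top_rule`` are callables (a, b) -> fused coefficient
    grid; defaults are absolute-maximum selection for details and averaging
    for the top approximation.
    """
    from .fusion import abs_max_rule, average_rule

    if pa.n_levels != pb.n_levels or any(
            da.shape != db.shape for da, db in zip(pa.details, pb.details)):
        raise ValueError("pyramid structures differ")
    detail_rule = detail_rule or abs_max_rule
    top_rule = top_rule or average_rule
    details = [detail_rule(da, db) for da, db in zip(pa.details, pb.details)]
    return LaplacianPyramid(details, top_rule(pa.top, pb.top))
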