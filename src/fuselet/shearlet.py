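"""Nonsubsampled shearlet-style directional decomposition (Parseval frame).

The transform splits the Fourier plane into one low-pass region plus, for each
of ``n_scales`` octave bands, a set of orientation wedges, every subband kept
at full image size (fully redundant, hence shift-invariant).  Radial windows
are Meyer-smooth octave transitions; angular windows are Meyer bumps on the
orientation (slope) coordinate, symmetric under xi -> -xi so all spatial
coefficients are real.  Both families are built as exact squared partitions of
unity, so the transfer functions satisfy the Parseval condition

    |W_low(xi)|^2 + sum_{j,l} |W_{j,l}(xi)|^2 = 1   for every frequency xi,

and synthesis by the adjoint (multiply each band by its window and sum) is an
exact inverse.  Coarse scales get fewer direction wedges than fine scales,
matching the anisotropic scaling in which the support of a scale-j atom grows
like 2^{2j} x 2^j with slopes on the grid l * 2^{-j}.

Discretization is frequency-domain with periodic (FFT) boundary semantics; the
defaults (4 scales, [6, 6, 10, 10] directions coarse to fine) give 1 + 32
subbands.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .image import Image2D, as_array

__all__ = [
    "ShearletSystem",
    "ShearletDecomposition",
    "build_system",
    "decompose",
    "reconstruct",
    "frame_violation",
]

DEFAULT_SHEARS = (6, 6, 10, 10)


def _meyer_nu(t: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial: 0 -> 0, 1 -> 1, C^3-smooth ramp."""
    t = np.clip(t, 0.0, 1.0)
    return t ** 4 * (35.0 - 84.0 * t + 70.0 * t ** 2 - 20.0 * t ** 3)


def _symmetrize(w: np.ndarray) -> np.ndarray:
    """Enforce w(k) = w(-k mod N) exactly, preserving sum-of-squares.

    The FFT grid folds +Nyquist and -Nyquist onto one sample, so angular
    wedges are not automatically centrally symmetric there; symmetrizing the
    squared window keeps the Parseval partition intact while guaranteeing
    real-valued spatial coefficients.
    """
    flipped = np.roll(w[::-1, ::-1], (1, 1), axis=(0, 1))
    return np.sqrt(0.5 * (w ** 2 + flipped ** 2))


def _radial_step(r: np.ndarray, cut: float) -> np.ndarray:
    """cos-Meyer fall from 1 (r <= cut/2) to 0 (r >= cut), one-octave ramp."""
    with np.errstate(divide="ignore"):
        rho = np.where(r > 0, np.log2(np.maximum(r, 1e-300) / cut) + 1.0, -np.inf)
    return np.cos(0.5 * np.pi * _meyer_nu(rho))


@dataclass(frozen=True)
class ShearletSystem:
    """Precomputed transfer functions for one image shape.

    ``band_windows[j][l]`` is the real window of scale ``j`` (0 = coarsest),
    orientation ``l``; all windows share ``shape``.
    """

    shape: tuple[int, int]
    n_scales: int
    shears_per_scale: tuple[int, ...]
    lowpass_window: np.ndarray
    band_windows: list[list[np.ndarray]]

    @property
    def n_subbands(self) -> int:
        return 1 + sum(self.shears_per_scale)


def build_system(shape: tuple[int, int], n_scales: int = 4,
                 shears_per_scale: "tuple[int, ...] | None" = None) -> ShearletSystem:
    """Construct the window stack for images of ``shape``.

    Radial cuts sit at Nyquist/2^(n_scales-j); each scale's annulus is split
    into ``shears_per_scale[j]`` orientation wedges by Meyer bumps in angle
    (period pi, so windows are centrally symmetric and coefficients real).
    """
    rows, cols = shape
    if rows < 32 or cols < 32:
        raise ValueError(f"image {shape} too small for a shearlet system (min 32x32)")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if shears_per_scale is None:
        shears_per_scale = tuple(DEFAULT_SHEARS[:n_scales]) if n_scales <= 4 else \
            tuple(DEFAULT_SHEARS) + (10,) * (n_scales - 4)
    shears_per_scale = tuple(int(k) for k in shears_per_scale)
    if len(shears_per_scale) != n_scales or any(k < 2 for k in shears_per_scale):
        raise ValueError("shears_per_scale must give >= 2 directions for each scale")

    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    r = np.hypot(fy, fx)
    theta = np.mod(np.arctan2(fy, fx), np.pi)  # orientation, period pi

    # Radial squared partition of unity: R_1 <= R_2 <= ... <= R_n <= 1,
    # lowpass = R_1, band_j = sqrt(R_{j+1}^2 - R_j^2).
    cuts = [0.5 / 2 ** (n_scales - j) for j in range(1, n_scales + 1)]
    steps = [_radial_step(r, c) for c in cuts] + [np.ones_like(r)]
    lowpass = steps[0]
    band_windows: list[list[np.ndarray]] = []
    for j in range(n_scales):
        radial = np.sqrt(np.maximum(steps[j + 1] ** 2 - steps[j] ** 2, 0.0))
        K = shears_per_scale[j]
        t = theta * K / np.pi  # orientation slot coordinate in [0, K)
        wedges = []
        for l in range(K):
            d = np.mod(t - l + K / 2.0, K) - K / 2.0  # periodic distance
            bump = np.where(np.abs(d) < 1.0,
                            np.cos(0.5 * np.pi * _meyer_nu(np.abs(d))), 0.0)
            wedges.append(_symmetrize(radial * bump))
        band_windows.append(wedges)
    return ShearletSystem(shape=(rows, cols), n_scales=n_scales,
                          shears_per_scale=shears_per_scale,
                          lowpass_window=lowpass, band_windows=band_windows)


def frame_violation(sys: ShearletSystem) -> float:
    """Max over frequencies of | sum of squared window magnitudes - 1 |."""
    total = sys.lowpass_window ** 2
    for wedges in sys.band_windows:
        for w in wedges:
            total = total + w ** 2
    return float(np.abs(total - 1.0).max())


@dataclass(frozen=True)
class ShearletDecomposition:
    """Low-pass band plus {(scale, shear) -> full-size signed band}."""

    lowpass: np.ndarray
    highpass: dict

    def band(self, scale: int, shear: int) -> np.ndarray:
        return self.highpass[(scale, shear)]


def decompose(img: "Image2D | np.ndarray", sys: ShearletSystem) -> ShearletDecomposition:
    """Project an image onto every subband (frequency-domain windowing)."""
    a = as_array(img)
    if a.shape != sys.shape:
        raise ValueError(f"image shape {a.shape} does not match system {sys.shape}")
    spec = np.fft.fft2(a)
    lowpass = np.fft.ifft2(spec * sys.lowpass_window).real
    highpass = {}
    for j, wedges in enumerate(sys.band_windows):
        for l, w in enumerate(wedges):
            highpass[(j, l)] = np.fft.ifft2(spec * w).real
    return ShearletDecomposition(lowpass=lowpass, highpass=highpass)


def reconstruct(dec: ShearletDecomposition, sys: ShearletSystem) -> np.ndarray:
    """Adjoint-frame synthesis; exact inverse for unmodified coefficients."""
    expected = {(j, l) for j, wedges in enumerate(sys.band_windows)
                for l in range(len(wedges))}
    if set(dec.highpass) != expected or dec.lowpass.shape != sys.shape:
        raise ValueError("decomposition does not match system band layout")
    acc = np.fft.fft2(dec.lowpass) * sys.lowpass_window
    for j, wedges in enumerate(sys.band_windows):
        for l, w in enumerate(wedges):
            acc = acc + np.fft.fft2(dec.highpass[(j, l)]) * w
    return np.fft.ifft2(acc).real


def save_decomposition(dec: ShearletDecomposition, directory: str | os.PathLike) -> None:
    """Serialize bands as TIFFs plus a JSON manifest (debugging aid)."""
    import tifffile

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    manifest = {"lowpass": "lowpass.tif", "bands": {}}
    tifffile.imwrite(os.path.join(directory, "lowpass.tif"),
                     dec.lowpass.astype(np.float32))
    for (j, l), band in sorted(dec.highpass.items()):
        name = f"band_s{j}_d{l}.tif"
        tifffile.imwrite(os.path.join(directory, name), band.astype(np.float32))
        manifest["bands"][f"{j},{l}"] = name
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
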