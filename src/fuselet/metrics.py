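"""Objective fusion-quality indicators: EN, SD, Q_o and Piella's Q_w.

* ``entropy`` — Shannon entropy of the 256-bin intensity histogram, in bits;
  measures how much of the dynamic range the fused image actually uses.
* ``std_dev`` — population standard deviation, reported on the 0-255 scale
  for comparability with the fusion literature.
* ``q0`` — the Wang-Bovik universal image quality index between two images,
  computed in sliding windows (default 8x8, step 1) and averaged:
  q = 4 sigma_xy mu_x mu_y / ((sigma_x^2 + sigma_y^2)(mu_x^2 + mu_y^2)).
  It factors into correlation, luminance and contrast agreement and equals
  1 exactly when the window contents coincide.
* ``qw`` — Piella-Heijmans weighted fusion quality: per window,
  lambda = sigma_a^2 / (sigma_a^2 + sigma_b^2) splits credit between the two
  sources, and windows are weighted by normalized saliency
  c(w) = max(sigma_a^2, sigma_b^2); rewards a fusion that follows whichever
  source is locally more informative.

Windows where the Q0 denominator vanishes (flat, zero-mean content) are
counted as 1 when the two windows are identical and are skipped otherwise;
inside Q_w such undefined windows contribute 0 while keeping their weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .image import Image2D, RegisteredPair, as_array

__all__ = ["QualityReport", "entropy", "std_dev", "q0", "qw", "report"]

_EPS = 1e-12


def entropy(img: "Image2D | np.ndarray") -> float:
    """Shannon histogram entropy in bits (256 bins over [0, 1])."""
    px = np.clip(as_array(img), 0.0, 1.0)
    hist, _ = np.histogram(px, bins=256, range=(0.0, 1.0))
    p = hist[hist > 0] / px.size
    return float(-(p * np.log2(p)).sum())


def std_dev(img: "Image2D | np.ndarray") -> float:
    """Population standard deviation on the 0-255 intensity scale."""
    return float(np.std(as_array(img)) * 255.0)


def _box(x: np.ndarray, w: int) -> np.ndarray:
    """Sums over every w x w window (valid positions), via integral image."""
    ii = np.zeros((x.shape[0] + 1, x.shape[1] + 1))
    ii[1:, 1:] = np.cumsum(np.cumsum(x, axis=0), axis=1)
    return (ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w])


def _window_stats(x: np.ndarray, y: np.ndarray, w: int):
    """Per-window means, variances and covariance (population convention)."""
    n = w * w
    mx = _box(x, w) / n
    my = _box(y, w) / n
    vx = _box(x * x, w) / n - mx ** 2
    vy = _box(y * y, w) / n - my ** 2
    cxy = _box(x * y, w) / n - mx * my
    return mx, my, np.maximum(vx, 0.0), np.maximum(vy, 0.0), cxy


def _q0_map(x: np.ndarray, y: np.ndarray, window: int):
    """Per-window Q0 values plus masks: (values, defined, identical)."""
    mx, my, vx, vy, cxy = _window_stats(x, y, window)
    denom = (vx + vy) * (mx ** 2 + my ** 2)
    defined = denom > _EPS
    identical = _box(np.abs(x - y), window) <= _EPS * window * window
    vals = np.zeros_like(denom)
    np.divide(4.0 * cxy * mx * my, denom, out=vals, where=defined)
    return vals, defined, identical


def _check_shapes(*imgs: np.ndarray) -> None:
    shapes = {a.shape for a in imgs}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def q0(x: "Image2D | np.ndarray", y: "Image2D | np.ndarray", window: int = 8) -> float:
    """Wang-Bovik universal image quality index, sliding-window average."""
    xa, ya = as_array(x), as_array(y)
    _check_shapes(xa, ya)
    vals, defined, identical = _q0_map(xa, ya, window)
    keep = defined | identical  # undefined non-identical windows are skipped
    if not keep.any():
        return 1.0 if np.abs(xa - ya).max() <= _EPS else 0.0
    vals = np.where(defined, vals, np.where(identical, 1.0, 0.0))
    return float(vals[keep].mean())


def qw(a: "Image2D | np.ndarray", b: "Image2D | np.ndarray",
       f: "Image2D | np.ndarray", window: int = 8) -> float:
    """Piella-Heijmans weighted fusion quality of ``f`` against sources."""
    aa, ba, fa = as_array(a), as_array(b), as_array(f)
    _check_shapes(aa, ba, fa)
    _, _, va, vb, _ = _window_stats(aa, ba, window)
    qa, da, ia = _q0_map(aa, fa, window)
    qb, db, ib = _q0_map(ba, fa, window)
    qa = np.where(da, qa, np.where(ia, 1.0, 0.0))
    qb = np.where(db, qb, np.where(ib, 1.0, 0.0))
    tot = va + vb
    lam = np.full_like(tot, 0.5)
    np.divide(va, tot, out=lam, where=tot > _EPS)
    sal = np.maximum(va, vb)
    c = sal.sum()
    if c <= _EPS:
        weights = np.full_like(sal, 1.0 / sal.size)
    else:
        weights = sal / c
    return float((weights * (lam * qa + (1.0 - lam) * qb)).sum())


@dataclass(frozen=True)
class QualityReport:
    """The four quality indicators for one fusion result."""

    en: float
    sd: float
    q_o: float
    q_w: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "QualityReport":
        return cls(**json.loads(s))


def report(pair: RegisteredPair, fused: "Image2D | np.ndarray",
           window: int = 8) -> QualityReport:
    """Assemble all four metrics for a fused image.

    EN and SD describe the fused image alone; Q_o is the mean of
    Q0(a, fused) and Q0(b, fused); Q_w is as defined above.
    """
    fa = as_array(fused)
    _check_shapes(pair.a.pixels, fa)
    return QualityReport(
        en=entropy(fa),
        sd=std_dev(fa),
        q_o=0.5 * (q0(pair.a.pixels, fa, window) + q0(pair.b.pixels, fa, window)),
        q_w=qw(pair.a.pixels, pair.b.pixels, fa, window),
    )
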