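"""Separable 2-D biorthogonal wavelet analysis/synthesis and wavelet fusion.

Analysis applies the two-channel recurrences

    a_{m,n} = sum_k h_{2n-k} a_{m-1,k}        (approximation)
    c_{m,n} = sum_k g_{2n-k} a_{m-1,k}        (detail)

along rows then columns of the running approximation; synthesis inverts them
with the dual pair (h~, g~):

    a_{m-1,l} = sum_n h~_{2n-l} a_{m,n} + g~_{2n-l} c_{m,n}.

High-pass filters follow the quadrature relation g_l = (-1)^l h_{1-l} applied
to the *dual* low-pass (g from h~, g~ from h), the standard biorthogonal
duality; :func:`check_pr` quantifies the perfect-reconstruction condition
sum_n h_n h~_{n+2k} = delta_{k,0} directly.

Signals are extended periodically (circular indexing), which makes perfect
reconstruction exact for every PR bank independent of tap symmetry; image
dimensions must therefore be divisible by 2^M for an M-level transform.
Filters carry an explicit support start index so the downsampling phase is
unambiguous and a brute-force evaluation of the recurrences reproduces the
fast implementation tap for tap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Image2D, as_array

__all__ = [
    "WaveletFilter",
    "FilterBank",
    "WaveletDecomposition2D",
    "derive_highpass",
    "check_pr",
    "haar_bank",
    "cdf97_bank",
    "bank_from_file",
    "dwt2",
    "idwt2",
    "fuse_dwt",
]


@dataclass(frozen=True)
class WaveletFilter:
    """A finite filter: ``taps[j]`` is the coefficient at index ``start + j``."""

    taps: np.ndarray
    start: int = 0

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.taps, dtype=np.float64))
        if t.size == 0 or not np.all(np.isfinite(t)):
            raise ValueError("filter taps must be nonempty and finite")
        object.__setattr__(self, "taps", t)

    def __getitem__(self, n: int) -> float:
        j = n - self.start
        if 0 <= j < self.taps.size:
            return float(self.taps[j])
        return 0.0

    @property
    def support(self) -> range:
        return range(self.start, self.start + self.taps.size)


def derive_highpass(h: WaveletFilter) -> WaveletFilter:
    """Quadrature-mirror construction g_l = (-1)^l h_{1-l}."""
    length = h.taps.size
    start_g = 2 - h.start - length
    taps = np.empty(length)
    for j in range(length):
        n = start_g + j
        taps[j] = ((-1.0) ** n) * h[1 - n]
    return WaveletFilter(taps, start_g)


@dataclass(frozen=True)
class FilterBank:
    """Analysis pair (h, g) and synthesis pair (h~, g~)."""

    h: WaveletFilter
    g: WaveletFilter
    h_tilde: WaveletFilter
    g_tilde: WaveletFilter
    name: str = ""

    @classmethod
    def from_lowpass(cls, h: WaveletFilter, h_tilde: WaveletFilter, name: str = "") -> "FilterBank":
        return cls(h=h, g=derive_highpass(h_tilde), h_tilde=h_tilde,
                   g_tilde=derive_highpass(h), name=name)


def check_pr(bank: FilterBank) -> float:
    """Max violation of the biorthogonality condition sum_n h_n h~_{n+2k} = delta_k."""
    h, ht = bank.h, bank.h_tilde
    worst = 0.0
    lo = min(h.support.start, ht.support.start) - max(h.taps.size, ht.taps.size)
    hi = max(h.support.stop, ht.support.stop) + max(h.taps.size, ht.taps.size)
    for k in range(lo, hi):
        s = sum(h[n] * ht[n + 2 * k] for n in h.support)
        target = 1.0 if k == 0 else 0.0
        worst = max(worst, abs(s - target))
    return worst


def haar_bank() -> FilterBank:
    """Orthonormal Haar bank (h = h~ = [1, 1] / sqrt(2))."""
    s = 1.0 / np.sqrt(2.0)
    h = WaveletFilter([s, s], start=0)
    return FilterBank.from_lowpass(h, h, name="haar")


# CDF 9/7 lowpass taps (sqrt(2) normalization), analysis centered on [-4, 4],
# synthesis on [-3, 3]; the pair used in lossy JPEG 2000.
_CDF97_ANALYSIS = [
    0.03782845550726404, -0.023849465019556843, -0.11062440441843718,
    0.37740285561283066, 0.8526986790088938, 0.37740285561283066,
    -0.11062440441843718, -0.023849465019556843, 0.03782845550726404,
]
_CDF97_SYNTHESIS = [
    -0.06453888262869706, -0.04068941760916406, 0.41809227322161724,
    0.7884856164055829, 0.41809227322161724, -0.04068941760916406,
    -0.06453888262869706,
]


def cdf97_bank() -> FilterBank:
    """Biorthogonal CDF 9/7 bank, the workhorse for smooth-image fusion."""
    h = WaveletFilter(_CDF97_ANALYSIS, start=-4)
    ht = WaveletFilter(_CDF97_SYNTHESIS, start=-3)
    return FilterBank.from_lowpass(h, ht, name="cdf97")


def bank_from_file(path) -> FilterBank:
    """Load a bank from a plain-text tap file.

    Lines are ``<filter> <index> <value>`` where filter is ``h`` or
    ``h_tilde``; blank lines and ``#`` comments are ignored.  High-pass
    filters are derived by the quadrature relation.
    """
    entries: dict[str, dict[int, float]] = {"h": {}, "h_tilde": {}}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            which, idx, val = line.split()
            entries[which][int(idx)] = float(val)
    filters = {}
    for which, taps in entries.items():
        if not taps:
            raise ValueError(f"tap file {path!r} missing filter {which!r}")
        lo, hi = min(taps), max(taps)
        arr = np.zeros(hi - lo + 1)
        for i, v in taps.items():
            arr[i - lo] = v
        filters[which] = WaveletFilter(arr, start=lo)
    return FilterBank.from_lowpass(filters["h"], filters["h_tilde"])


@dataclass(frozen=True)
class WaveletDecomposition2D:
    """Coarsest approximation plus (horizontal, vertical, diagonal) details.

    ``details[0]`` is the finest level; each entry is a tuple
    (low-row/high-col, high-row/low-col, high-row/high-col).
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]

    @property
    def n_levels(self) -> int:
        return len(self.details)


def _analyze_cols(x: np.ndarray, f: WaveletFilter) -> np.ndarray:
    """y[:, n] = sum_k f_{2n-k} x[:, k] with periodic k."""
    L = x.shape[1]
    n = np.arange(L // 2)
    out = np.zeros((x.shape[0], L // 2))
    for j, v in enumerate(f.taps):
        k = np.mod(2 * n - (f.start + j), L)
        out += v * x[:, k]
    return out


def _synthesize_cols(a: np.ndarray, c: np.ndarray, ht: WaveletFilter,
                     gt: WaveletFilter) -> np.ndarray:
    """x[:, l] = sum_n ht_{2n-l} a[:, n] + gt_{2n-l} c[:, n], periodic."""
    half = a.shape[1]
    L = 2 * half
    n = np.arange(half)
    out = np.zeros((a.shape[0], L))
    for f, band in ((ht, a), (gt, c)):
        for j, v in enumerate(f.taps):
            l = np.mod(2 * n - (f.start + j), L)
            out[:, l] += v * band
    return out


def _dwt2_level(a: np.ndarray, bank: FilterBank):
    lo = _analyze_cols(a, bank.h)
    hi = _analyze_cols(a, bank.g)
    ll = _analyze_cols(lo.T, bank.h).T
    hl = _analyze_cols(lo.T, bank.g).T   # high rows, low cols
    lh = _analyze_cols(hi.T, bank.h).T   # low rows, high cols
    hh = _analyze_cols(hi.T, bank.g).T
    return ll, (lh, hl, hh)


def dwt2(img: "Image2D | np.ndarray", bank: FilterBank, n_levels: int = 1) -> WaveletDecomposition2D:
    """M-level separable 2-D wavelet analysis."""
    a = as_array(img)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if a.shape[0] % (1 << n_levels) or a.shape[1] % (1 << n_levels):
        raise ValueError(
            f"dimensions {a.shape} not divisible by 2^{n_levels}")
    details = []
    for _ in range(n_levels):
        a, bands = _dwt2_level(a, bank)
        details.append(bands)  # first appended = finest level
    return WaveletDecomposition2D(approx=a, details=details)


def idwt2(dec: WaveletDecomposition2D, bank: FilterBank) -> np.ndarray:
    """Inverse M-level transform (exact for a PR bank)."""
    a = dec.approx
    for lh, hl, hh in reversed(dec.details):
        if lh.shape != a.shape:
            raise ValueError("decomposition structure inconsistent")
        lo = _synthesize_cols(a.T, hl.T, bank.h_tilde, bank.g_tilde).T
        hi = _synthesize_cols(lh.T, hh.T, bank.h_tilde, bank.g_tilde).T
        a = _synthesize_cols(lo, hi, bank.h_tilde, bank.g_tilde)
    return a


def fuse_dwt(da: WaveletDecomposition2D, db: WaveletDecomposition2D,
             detail_rule=None, approx_rule=None) -> WaveletDecomposition2D:
    """Merge two same-structure decompositions band by band.

    Defaults: absolute-maximum selection on details, averaging on the
    approximation.
    """
    from .fusion import abs_max_rule, average_rule

    if da.n_levels != db.n_levels or da.approx.shape != db.approx.shape:
        raise ValueError("decomposition structures differ")
    detail_rule = detail_rule or abs_max_rule
    approx_rule = approx_rule or average_rule
    details = []
    for bands_a, bands_b in zip(da.details, db.details):
        if any(x.shape != y.shape for x, y in zip(bands_a, bands_b)):
            raise ValueError("decomposition structures differ")
        details.append(tuple(detail_rule(x, y) for x, y in zip(bands_a, bands_b)))
    return WaveletDecomposition2D(approx=approx_rule(da.approx, db.approx),
                                  details=details)
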