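"""Coefficient-combination rules and the end-to-end fusion drivers.

Two pipelines are provided.

**Multimodal fusion** (CT-like with MR-like) follows a four-step scheme:
decompose both sources with a multiscale backend (``nsst`` shearlet by
default, ``lp`` Laplacian pyramid or ``dwt`` wavelet as alternatives); merge
the low-pass approximation with per-pixel energy-proportional weights
w_A = E_A / (E_A + E_B), a convex combination so weights sum to one
everywhere; merge every high-pass band by comparing PCNN firing-count maps
of the coefficient magnitudes (larger count wins, ties resolved by larger
magnitude then source A); invert the transform.

**Multifocus fusion** composites two differently-focused photographs through
a two-stage decision map: stage 1 classifies each block by a Sobel-energy
focus measure (sharper source wins); stage 2 removes boundary artifacts by
majority (consistency) filtering, small-region removal, and optional
edge-preserving smoothing of the 0/1 map with a box guided filter, producing
soft weights in [0, 1].  The fused image is w * A + (1 - w) * B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import Image2D, RegisteredPair, as_array
from .pcnn import PCNNParams, fire_counts
from . import pyramid as _pyr
from . import wavelet as _wav
from . import shearlet as _sh

__all__ = [
    "FusionConfig",
    "DecisionMap",
    "FusedResult",
    "abs_max_rule",
    "average_rule",
    "local_energy",
    "fuse_lowpass_energy",
    "fuse_highpass_pcnn",
    "fuse_multimodal",
    "focus_measure",
    "stage1_decision",
    "stage2_refine",
    "fuse_multifocus",
]


def abs_max_rule(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Keep the coefficient of larger magnitude (ties -> source A)."""
    return np.where(np.abs(b) > np.abs(a), b, a)


def average_rule(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 0.5 * (a + b)


@dataclass(frozen=True)
class FusionConfig:
    """Settings shared by both pipelines.

    backend        multiscale transform for multimodal fusion
    n_levels       decomposition depth (4 scales by default)
    lowpass_rule   'energy_weighted' or 'average'
    highpass_rule  'pcnn' or 'abs_max'
    energy_window  odd window for the local-energy activity measure
    block_size     multifocus focus-measure block side
    consistency_window  odd window of the stage-2 majority filter
    refine         'none', 'majority', or 'guided' (majority + guided filter)
    guided_eps     regularization of the guided filter
    """

    backend: str = "nsst"
    n_levels: int = 4
    lowpass_rule: str = "energy_weighted"
    highpass_rule: str = "pcnn"
    pcnn: PCNNParams = field(default_factory=PCNNParams)
    energy_window: int = 5
    block_size: int = 8
    consistency_window: int = 5
    refine: str = "guided"
    guided_eps: float = 0.01

    def __post_init__(self) -> None:
        if self.backend not in ("nsst", "lp", "dwt"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.lowpass_rule not in ("energy_weighted", "average"):
            raise ValueError(f"unknown lowpass_rule {self.lowpass_rule!r}")
        if self.highpass_rule not in ("pcnn", "abs_max"):
            raise ValueError(f"unknown highpass_rule {self.highpass_rule!r}")
        if self.refine not in ("none", "majority", "guided"):
            raise ValueError(f"unknown refine {self.refine!r}")
        if self.energy_window % 2 == 0 or self.consistency_window % 2 == 0:
            raise ValueError("windows must be odd")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "backend", "n_levels", "lowpass_rule", "highpass_rule",
            "energy_window", "block_size", "consistency_window", "refine",
            "guided_eps")}
        d["pcnn"] = self.pcnn.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        d = dict(d)
        if "pcnn" in d and isinstance(d["pcnn"], dict):
            d["pcnn"] = PCNNParams.from_dict(d["pcnn"])
        return cls(**d)


@dataclass(frozen=True)
class DecisionMap:
    """Per-pixel soft assignment (1 = take source A) with hard companion."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.min() < 0.0 or w.max() > 1.0:
            raise ValueError("decision weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)

    @property
    def hard(self) -> np.ndarray:
        return self.weights >= 0.5


@dataclass(frozen=True)
class FusedResult:
    image: Image2D
    config: FusionConfig
    decision: "DecisionMap | None" = None
    metrics: "object | None" = None


# ---------------------------------------------------------------------------
# coefficient rules

def local_energy(band: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-pixel sum of squared coefficients over a centered odd window."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    b = as_array(band)
    return ndimage.uniform_filter(b * b, size=window, mode="reflect") * window * window


def fuse_lowpass_energy(aA: np.ndarray, aB: np.ndarray, window: int = 5) -> np.ndarray:
    """Energy-proportional convex combination of two low-pass bands."""
    aA, aB = as_array(aA), as_array(aB)
    if aA.shape != aB.shape:
        raise ValueError("low-pass band shapes differ")
    ea = local_energy(aA, window)
    eb = local_energy(aB, window)
    tot = ea + eb
    wa = np.full_like(tot, 0.5)
    np.divide(ea, tot, out=wa, where=tot > 0)
    return wa * aA + (1.0 - wa) * aB


def fuse_highpass_pcnn(cA: np.ndarray, cB: np.ndarray,
                       params: PCNNParams | None = None) -> np.ndarray:
    """Select coefficients by PCNN firing counts.

    The source whose fire map is strictly larger at a pixel supplies the
    coefficient; ties fall back to larger magnitude, then to source A.
    """
    cA, cB = as_array(cA), as_array(cB)
    if cA.shape != cB.shape:
        raise ValueError("high-pass band shapes differ")
    params = params or PCNNParams()
    fa = fire_counts(cA, params).counts
    fb = fire_counts(cB, params).counts
    take_b = (fb > fa) | ((fb == fa) & (np.abs(cB) > np.abs(cA)))
    return np.where(take_b, cB, cA)


# ---------------------------------------------------------------------------
# multimodal driver

def _highpass_rule(cfg: FusionConfig):
    if cfg.highpass_rule == "pcnn":
        return lambda a, b: fuse_highpass_pcnn(a, b, cfg.pcnn)
    return abs_max_rule


def _lowpass_rule(cfg: FusionConfig):
    if cfg.lowpass_rule == "energy_weighted":
        return lambda a, b: fuse_lowpass_energy(a, b, cfg.energy_window)
    return average_rule


def fuse_multimodal(pair: RegisteredPair, cfg: FusionConfig | None = None) -> FusedResult:
    """Decompose, merge subbands, reconstruct.  Deterministic given cfg."""
    cfg = cfg or FusionConfig()
    a, b = pair.a.pixels, pair.b.pixels
    lo_rule, hi_rule = _lowpass_rule(cfg), _highpass_rule(cfg)
    if cfg.backend == "lp":
        _, pa = _pyr.build_pyramids(a, cfg.n_levels)
        _, pb = _pyr.build_pyramids(b, cfg.n_levels)
        fused_pyr = _pyr.fuse_lp(pa, pb, detail_rule=hi_rule, top_rule=lo_rule)
        out = _pyr.reconstruct(fused_pyr)
    elif cfg.backend == "dwt":
        bank = _wav.cdf97_bank()
        levels = cfg.n_levels
        da = _wav.dwt2(a, bank, levels)
        db = _wav.dwt2(b, bank, levels)
        fused_dec = _wav.fuse_dwt(da, db, detail_rule=hi_rule, approx_rule=lo_rule)
        out = _wav.idwt2(fused_dec, bank)
    else:  # nsst
        system = _sh.build_system(a.shape, n_scales=cfg.n_levels)
        da = _sh.decompose(a, system)
        db = _sh.decompose(b, system)
        lowpass = lo_rule(da.lowpass, db.lowpass)
        highpass = {k: hi_rule(da.highpass[k], db.highpass[k]) for k in da.highpass}
        out = _sh.reconstruct(_sh.ShearletDecomposition(lowpass, highpass), system)
    return FusedResult(image=Image2D(np.clip(out, 0.0, 1.0)), config=cfg)


# ---------------------------------------------------------------------------
# multifocus pipeline

def focus_measure(img: "Image2D | np.ndarray", block: int = 8) -> np.ndarray:
    """Blockwise Sobel-gradient energy, broadcast back to per-pixel scores."""
    if block < 3:
        raise ValueError("block must be >= 3")
    a = as_array(img)
    gx = ndimage.sobel(a, axis=1, mode="reflect")
    gy = ndimage.sobel(a, axis=0, mode="reflect")
    energy = gx * gx + gy * gy
    rows, cols = a.shape
    score = np.zeros_like(a)
    for i0 in range(0, rows, block):
        for j0 in range(0, cols, block):
            blk = energy[i0:i0 + block, j0:j0 + block]
            score[i0:i0 + block, j0:j0 + block] = blk.sum()
    return score


def stage1_decision(pair: RegisteredPair, block: int = 8) -> DecisionMap:
    """Hard focus classification: per block, the sharper source wins."""
    sa = focus_measure(pair.a, block)
    sb = focus_measure(pair.b, block)
    return DecisionMap((sa >= sb).astype(np.float64))


def _guided_filter(guide: np.ndarray, src: np.ndarray, radius: int,
                   eps: float) -> np.ndarray:
    """Box guided filter: edge-preserving smoothing of src steered by guide."""
    size = 2 * radius + 1
    mean = lambda x: ndimage.uniform_filter(x, size=size, mode="reflect")
    mg, ms = mean(guide), mean(src)
    var_g = mean(guide * guide) - mg * mg
    cov = mean(guide * src) - mg * ms
    a = cov / (var_g + eps)
    b = ms - a * mg
    return mean(a) * guide + mean(b)


def stage2_refine(dm: DecisionMap, guide: "Image2D | np.ndarray",
                  cfg: FusionConfig | None = None) -> DecisionMap:
    """Consistency verification and boundary-artifact suppression.

    (i) majority filter on the hard map; (ii) removal of connected regions
    smaller than block_size^2; (iii) for ``refine='guided'``, edge-preserving
    smoothing of the cleaned 0/1 map guided by the fused-intensity image,
    clamped to [0, 1].
    """
    cfg = cfg or FusionConfig()
    g = as_array(guide)
    hard = dm.hard
    if g.shape != hard.shape:
        raise ValueError("guide shape does not match decision map")
    if cfg.refine == "none":
        return dm
    frac = ndimage.uniform_filter(hard.astype(np.float64),
                                  size=cfg.consistency_window, mode="reflect")
    hard = frac >= 0.5
    # drop connected components smaller than one focus block
    min_px = cfg.block_size ** 2
    for value in (True, False):
        labels, n = ndimage.label(hard == value)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(g), labels, np.arange(1, n + 1))
            for lab in np.nonzero(sizes < min_px)[0] + 1:
                hard[labels == lab] = not value
    if cfg.refine == "majority":
        return DecisionMap(hard.astype(np.float64))
    soft = _guided_filter(g, hard.astype(np.float64), cfg.block_size, cfg.guided_eps)
    return DecisionMap(np.clip(soft, 0.0, 1.0))


def fuse_multifocus(pair: RegisteredPair, cfg: FusionConfig | None = None) -> FusedResult:
    """Two-stage decision-map compositing of a multifocus pair."""
    cfg = cfg or FusionConfig()
    dm = stage1_decision(pair, cfg.block_size)
    a, b = pair.a.pixels, pair.b.pixels
    guide = dm.weights * a + (1.0 - dm.weights) * b
    dm = stage2_refine(dm, guide, cfg)
    w = dm.weights
    fused = w * a + (1.0 - w) * b
    return FusedResult(image=Image2D(np.clip(fused, 0.0, 1.0)), config=cfg,
                       decision=dm)
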