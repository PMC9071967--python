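"""Pulse-coupled neural network activity maps and QPSO parameter search.

A PCNN is a lattice of spiking units, one per coefficient, driven by the
normalized coefficient magnitude S through the simplified discrete dynamics

    F_t = S                                      (static feeding branch)
    L_t = exp(-alpha_l) L_{t-1} + v_l (W * Y_{t-1})   (lateral linking)
    U_t = F_t (1 + beta L_t)                     (modulated internal activity)
    Y_t = [U_t > Theta_{t-1}]                    (spike)
    Theta_t = exp(-alpha_theta) Theta_{t-1} + v_theta Y_t   (dynamic threshold)

iterated for a fixed number of steps from L_0 = Y_0 = 0, Theta_0 = 1.  The
per-pixel total firing count is a salience measure: strong, spatially
coherent coefficients pulse earlier and more often, so comparing the fire
maps of two source bands decides which coefficient survives fusion.  The 3x3
linking weight matrix is inverse Euclidean distance (corners 1/sqrt(2), edges
1, center 0).

The five free parameters (beta, alpha_l, alpha_theta, v_l, v_theta) can be
tuned per image pair by quantum-behaved particle swarm optimization (QPSO):
particles sample positions around per-dimension attractors with the
logarithmic kernel x = p +/- ce * |mbest - x| * ln(1/u), where mbest is the
mean personal best and the contraction-expansion coefficient ce decreases
linearly over the run (1.0 -> 0.5 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import correlate

__all__ = [
    "PCNNParams",
    "FireMap",
    "QPSOConfig",
    "link_kernel",
    "fire_counts",
    "qpso_minimize",
    "optimize_pcnn_params",
]


def link_kernel() -> np.ndarray:
    """3x3 inverse-distance linking weights: corners 1/sqrt(2), edges 1, center 0."""
    w = np.zeros((3, 3))
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di or dj:
                w[di + 1, dj + 1] = 1.0 / np.hypot(di, dj)
    return w


@dataclass(frozen=True)
class PCNNParams:
    """Free parameters of the simplified PCNN.

    ``alpha_f`` is retained for the full model's feeding-decay term but is
    inert under the static feeding branch used here.
    """

    beta: float = 0.5
    alpha_f: float = 0.1
    alpha_l: float = 1.0
    alpha_theta: float = 0.2
    v_l: float = 1.0
    v_theta: float = 20.0
    iterations: int = 100
    link_matrix: np.ndarray = field(default_factory=link_kernel)

    def __post_init__(self) -> None:
        for name in ("beta", "alpha_f", "alpha_l", "alpha_theta", "v_l", "v_theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        w = np.asarray(self.link_matrix, dtype=np.float64)
        if w.shape != (3, 3):
            raise ValueError("link_matrix must be 3x3")
        object.__setattr__(self, "link_matrix", w)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["link_matrix"] = self.link_matrix.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PCNNParams":
        d = dict(d)
        if "link_matrix" in d:
            d["link_matrix"] = np.asarray(d["link_matrix"], dtype=np.float64)
        return cls(**d)


@dataclass(frozen=True)
class FireMap:
    """Integer per-pixel firing totals, bounded by the iteration count."""

    counts: np.ndarray
    iterations: int


def fire_counts(coeffs: np.ndarray, params: PCNNParams | None = None) -> FireMap:
    """Run the PCNN on a coefficient grid and return total firing counts.

    The stimulus is |coeffs| scaled to [0, 1] (by the grid maximum; an
    all-zero grid yields all-zero stimulus and hence zero counts).
    """
    params = params or PCNNParams()
    c = np.asarray(coeffs, dtype=np.float64)
    if not np.all(np.isfinite(c)):
        raise ValueError("coefficients must be finite")
    s = np.abs(c)
    peak = s.max()
    if peak > 0:
        s = s / peak
    decay_l = np.exp(-params.alpha_l)
    decay_t = np.exp(-params.alpha_theta)
    L = np.zeros_like(s)
    Y = np.zeros_like(s)
    theta = np.ones_like(s)
    counts = np.zeros(s.shape, dtype=np.int64)
    for _ in range(params.iterations):
        L = decay_l * L + params.v_l * correlate(Y, params.link_matrix,
                                                 mode="constant", cval=0.0)
        U = s * (1.0 + params.beta * L)
        Y = (U > theta).astype(np.float64)
        theta = decay_t * theta + params.v_theta * Y
        counts += Y.astype(np.int64)
    return FireMap(counts=counts, iterations=params.iterations)


@dataclass(frozen=True)
class QPSOConfig:
    """Swarm settings; defaults are D = 5, N = 20, 50 iterations."""

    dims: int = 5
    n_particles: int = 20
    max_iter: int = 50
    bounds: tuple = ((0.01, 2.0), (0.01, 2.0), (0.01, 2.0), (0.01, 2.0), (1.0, 50.0))
    seed: int = 0
    ce_start: float = 1.0
    ce_end: float = 0.5

    def __post_init__(self) -> None:
        if len(self.bounds) != self.dims:
            raise ValueError("bounds must give one (low, high) per dimension")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("search space must be bounded with low < high")


def qpso_minimize(objective, cfg: QPSOConfig,
                  initial_points: "np.ndarray | None" = None):
    """Minimize ``objective`` over the box ``cfg.bounds`` with canonical QPSO.

    Returns ``(best_point, best_value, trace)`` where ``trace`` is the
    best-so-far value after each iteration (non-increasing).  Fully
    reproducible for a fixed ``cfg.seed``; ``initial_points`` rows are
    injected into the initial swarm (e.g. known-good defaults).
    """
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    x = lo + (hi - lo) * rng.random((cfg.n_particles, cfg.dims))
    if initial_points is not None:
        pts = np.atleast_2d(np.asarray(initial_points, dtype=np.float64))
        k = min(len(pts), cfg.n_particles)
        x[:k] = np.clip(pts[:k], lo, hi)
    fvals = np.array([objective(xi) for xi in x])
    pbest, pbest_f = x.copy(), fvals.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    trace = []
    for t in range(cfg.max_iter):
        frac = t / max(cfg.max_iter - 1, 1)
        ce = cfg.ce_start + (cfg.ce_end - cfg.ce_start) * frac
        mbest = pbest.mean(axis=0)
        for i in range(cfg.n_particles):
            phi = rng.random(cfg.dims)
            p = phi * pbest[i] + (1.0 - phi) * gbest
            u = rng.random(cfg.dims)
            sign = np.where(rng.random(cfg.dims) < 0.5, -1.0, 1.0)
            xi = p + sign * ce * np.abs(mbest - x[i]) * np.log(1.0 / u)
            xi = np.clip(xi, lo, hi)
            fi = float(objective(xi))
            x[i] = xi
            if fi < pbest_f[i]:
                pbest[i], pbest_f[i] = xi, fi
                if fi < gbest_f:
                    gbest, gbest_f = xi.copy(), fi
        trace.append(gbest_f)
    return gbest, gbest_f, np.array(trace)


def _params_from_vector(v: np.ndarray, iterations: int = 100) -> PCNNParams:
    return PCNNParams(beta=v[0], alpha_l=v[1], alpha_theta=v[2],
                      v_l=v[3], v_theta=v[4], iterations=iterations)


def optimize_pcnn_params(pair_bands, cfg: QPSOConfig | None = None,
                         objective=None, iterations: int = 100) -> PCNNParams:
    """Search (beta, alpha_l, alpha_theta, v_l, v_theta) for best band fusion.

    ``pair_bands`` is a sequence of (band_a, band_b) training coefficient
    grids.  The default objective maximizes the Piella Q_w of the PCNN-fused
    bands against the two sources (summed over band pairs).  Degenerate
    (constant) training bands trigger a warning and the documented defaults.
    The default parameter vector is injected into the initial swarm, so the
    optimized result is never worse than the defaults on the training pair.
    """
    from .fusion import fuse_highpass_pcnn
    from .metrics import qw

    pair_bands = list(pair_bands)
    if not pair_bands:
        raise ValueError("need at least one training band pair")
    if all(np.ptp(a) == 0 and np.ptp(b) == 0 for a, b in pair_bands):
        warnings.warn("constant training bands; falling back to default PCNN "
                      "parameters", stacklevel=2)
        return PCNNParams(iterations=iterations)
    cfg = cfg or QPSOConfig()

    if objective is None:
        def objective(v: np.ndarray) -> float:
            params = _params_from_vector(v, iterations)
            score = 0.0
            for a, b in pair_bands:
                fused = fuse_highpass_pcnn(a, b, params)
                score += qw(a, b, fused)
            return -score

    defaults = PCNNParams(iterations=iterations)
    d0 = np.array([defaults.beta, defaults.alpha_l, defaults.alpha_theta,
                   defaults.v_l, defaults.v_theta])
    best, _, _ = qpso_minimize(objective, cfg, initial_points=d0[None, :])
    return _params_from_vector(best, iterations)
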