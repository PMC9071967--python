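# Methods

This note records the models implemented by `fuselet`, the parameter
choices that matter, what the synthetic fixtures do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Image model

All processing happens on unit-range float64 rasters. Integer input is
scaled by its bit depth on load (8-bit by 255, 16-bit by 65535) and
quantized once on save (round-half-up), so multiscale processing never
accumulates quantization loss. RGB input is collapsed to BT.601 luminance;
the fusion pipelines themselves are strictly grayscale. Fusion assumes
perfectly registered inputs: a shape mismatch is refused rather than
resampled, since misregistration would corrupt every coefficient-level
comparison downstream.

## Laplacian pyramid

REDUCE filters with the separable 5×5 binomial window (outer product of
[1,4,6,4,1]/16; entries sum to 1, central weight 36/256) and keeps
even-indexed samples; EXPAND zero-stuffs and filters with 4ω. Detail
levels are LP_l = G_l − EXPAND(G_{l+1}) with the top LP_N = G_N, a
telescoping identity, so synthesis is exact regardless of the filter —
the only requirement is that EXPAND be the deterministic function of the
recorded target shape. Borders use whole-sample symmetric (mirror) extension,
which preserves constants: a constant image yields identically zero detail
levels. Odd sizes ceil-halve; EXPAND accepts both 2s and 2s−1 targets so
round trips are exact for any geometry. Default depth is 4 levels,
matching the decomposition depth used throughout the package.

## Biorthogonal wavelet transform

The analysis recurrences a_{m,n} = Σ_k h_{2n−k}a_{m−1,k},
c_{m,n} = Σ_k g_{2n−k}a_{m−1,k} and the synthesis recurrence
a_{m−1,l} = Σ_n h̃_{2n−l}a_{m,n} + g̃_{2n−l}c_{m,n} are applied separably
(rows, then columns) and recursively on the approximation. High-pass
filters follow g_l = (−1)^l h_{1−l} applied to the *dual* low-pass (g from
h̃, g̃ from h), the standard biorthogonal duality; `check_pr` evaluates
Σ_n h_n h̃_{n+2k} − δ_{k,0} directly so a bank's perfect-reconstruction
quality is a measured number, not an assumption.

Signals are extended **periodically** rather than symmetrically. Symmetric
extension gives perfect reconstruction only when the extension mode matches
the filters' symmetry class (whole-sample for odd-length symmetric pairs
such as CDF 9/7, half-sample for Haar); circular indexing gives exact
reconstruction for *every* PR bank and makes the brute-force oracle a
one-line index formula. The cost is that image dimensions must be
divisible by 2^M for an M-level transform, and that content may wrap
across edges — acceptable for fusion, where both sources wrap identically.
Filters carry an explicit support start index, fixing the downsampling
phase (output n pools inputs 2n − support), which is why the Haar
zero-detail reconstruction averages sample pairs {2n−1, 2n}.

Shipped banks: orthonormal Haar (exact round trip at 1e-10) and CDF 9/7
(the lossy JPEG 2000 pair, round trip at 1e-7 given its published-precision
taps). No wavelet family is canonical for fusion; Haar serves the exact
tests and CDF 9/7 the smooth-image quality runs.

## Shearlet-style decomposition

The directional transform is a frequency-domain Parseval frame: one
low-pass window plus, per octave scale, orientation wedges, all full image
size (fully redundant, hence exactly shift-invariant). Radial windows are
built from Meyer-smooth octave transitions R_j (falling 1→0 between
c_j/2 and c_j, cuts c_j = Nyquist/2^{n_scales−j}); band j is
√(R_{j+1}² − R_j²), so low-pass² + Σ bands² = 1 *identically*. Angular
windows are Meyer bumps in the orientation coordinate θ mod π with unit
slot spacing, again squaring to one. Scale-dependent direction counts
(defaults [6, 6, 10, 10] coarse→fine) mirror the anisotropic scaling in
which a scale-j atom occupies a ~2^{2j}×2^j frequency trapezoid with slope
grid l·2^{−j}: finer scales resolve more orientations.

Two numerical points. First, the FFT grid folds ±Nyquist onto a single
sample, so angular wedges are not automatically centrally symmetric there;
each window's squared magnitude is symmetrized under k → −k, which keeps
the exact partition of unity while guaranteeing real spatial coefficients.
Second, boundary semantics are periodic (FFT); callers should window their
images if wrap-around ringing matters. Reconstruction is the adjoint
(multiply each band by its window and sum), exact to ~1e-15; the test
suite asserts 1e-6.

This is a deliberate discretization choice: the filter-tree constructions
used elsewhere in the literature trade exact frame inversion for compact
support. Here exactness was preferred because the fusion drivers depend on
the transform being losslessly invertible after coefficient surgery.

## PCNN activity maps

Each coefficient drives one spiking unit via the simplified discrete PCNN:
static feeding F = S (stimulus = |coefficient| normalized by the band
maximum), linking L_t = e^{−α_l}L_{t−1} + v_l(W⊛Y_{t−1}) with the 3×3
inverse-distance link matrix (corners 1/√2, edges 1, center 0, zero-padded
convolution), modulation U_t = F(1 + βL_t), spike Y_t = [U_t > Θ_{t−1}],
threshold Θ_t = e^{−α_θ}Θ_{t−1} + v_θ Y_t. Initial state L = Y = 0,
Θ = 1; 100 iterations. The total firing count is the activity measure:
strong coefficients cross the decaying threshold earlier each cycle and
accumulate more spikes, and the lateral linking lets coherent neighborhoods
fire together, which is what distinguishes PCNN salience from plain
magnitude. A zero-stimulus pixel never fires (Θ decays toward zero but
stays positive, and the spike test is strict), so an empty band can never
out-vote a textured one.

Defaults β = 0.5, α_l = 1.0, α_θ = 0.2, v_l = 1.0, v_θ = 20: with Θ
starting at 1 and v_θ = 20, a unit-stimulus pixel fires roughly every
15 steps (e^{−0.2·15} ≈ 0.05), giving ~6 well-separated firing cycles in
100 iterations — enough dynamic range in the counts to rank stimuli. The
full model's feeding decay α_f is kept as a parameter field but is inert
under the static feeding branch; it is retained so a leaky-feeding variant
can reuse the same configuration type.

## QPSO parameter search

The five free PCNN parameters (β, α_l, α_θ, v_l, v_θ) map to the five
search dimensions; default bounds (0.01–2)⁴ × (1–50). Canonical QPSO:
per-dimension attractor p = φ·pbest + (1−φ)·gbest, update
x ← p ± ce·|mbest − x|·ln(1/u) with mbest the mean personal best, clamped
to bounds; the contraction–expansion coefficient ce decreases linearly
1.0 → 0.5 across iterations (exposed as config). Swarm defaults N = 20,
50 iterations. The fitness for parameter tuning is the Piella Q_w of the
PCNN-fused band against the two source bands; the default parameter vector
is injected into the initial swarm, so tuned parameters can never score
worse than the defaults on their training pair. All randomness flows from
one integer seed; runs are bit-reproducible.

## Fusion drivers

Multimodal: decompose both sources (shearlet by default; pyramid and
wavelet as alternatives), fuse the low-pass by per-pixel energy proportion
w_A = E_A/(E_A+E_B) (local energy over a 5×5 window; w_A = 0.5 where both
energies vanish — an exact convex combination), fuse each high-pass band
by PCNN count comparison (strictly larger count wins; ties fall back to
larger magnitude, then source A), invert the transform, clip to [0, 1].
With identical inputs every rule returns its input, so fuse(a, a) = a
within transform round-trip error.

Multifocus: stage 1 scores each 8×8 block by the sum of squared Sobel
gradient magnitudes and assigns the block to the sharper source — a
handcrafted focus measure behind a pluggable interface, so a learned
classifier can be substituted without touching the rest of the pipeline.
Stage 2 (consistency verification) majority-filters the hard map over a
5×5 window, deletes connected components smaller than one block (8² px),
and optionally smooths the 0/1 map with a box guided filter (radius =
block, ε = 0.01) steered by the stage-1 composite, producing soft weights;
the final image is w·A + (1−w)·B. The majority/small-region stage is what
suppresses isolated block misclassifications near the focus boundary; the
guided stage feathers the seam without crossing intensity edges.

## Quality metrics

Q_o is the Wang–Bovik universal index, Q_w the Piella–Heijmans weighted
quality with λ(w) = σ_a²/(σ_a²+σ_b²) and window saliency c(w) ∝ max(σ_a²,
σ_b²), both over 8×8 sliding windows with step 1 and population-variance
convention, implemented with integral images (exact to 1e-12 against the
literal window loops). Degenerate windows (vanishing denominator) count as
1 when the contents are identical and are otherwise skipped (Q_o) or
contribute 0 while keeping their saliency weight (Q_w); fixtures in the
tests never hinge on this edge case. EN uses 256 histogram bins over
[0, 1] regardless of source bit depth; SD is reported on the 0–255 scale.
The pair report computes EN/SD on the fused image and Q_o as the mean of
Q0(a, f) and Q0(b, f).

## Synthetic fixtures

Multifocus pairs: a band-limited noise texture plus oriented bars and
discs (edges at many orientations, detail everywhere — a focus measure
needs texture to see) is blurred with a Gaussian (σ = 3 by default) and
composited region-wise by a hard mask (left/right, disc, or diagonal
split). Source A equals the truth exactly where its mask is 1; blur tails
leak across the boundary, so accuracy scoring excludes a 3σ band around
the split (measured by distance transform). Multimodal pairs: a
Shepp-Logan-like nested-ellipse head phantom rendered under two contrast
tables — CT-like (skull 0.95, near-flat soft tissue ~0.25–0.33) and
MR-like (skull 0.10, tissues 0.40/0.70, lesion 0.90) — with additive
Gaussian noise (σ = 0.01) clipped to [0, 1]. Noise σ, contrast tables and
geometry are fixed defaults chosen once to look like a plausible low-noise
acquisition; they are not tuned per experiment.

What the fixtures do *not* emulate: sensor-specific noise statistics
(Poisson, bias fields, MR speckle), partial-volume effects, anatomical
texture inside tissue regions, registration error, or depth-graded blur.
Passing tests therefore demonstrate the algorithms' correctness and their
behavior under idealized complementary-information conditions, not
clinical performance.

## Problem sizes and determinism

Default experiment sizes are 256×256 for pipeline-quality runs, 64×64 for
round-trip checks and ≤16×16 for brute-force oracle comparisons; these
sizes fully exercise every code path while keeping the whole suite fast
on a single CPU. Every stochastic component (fixture generation, QPSO)
derives from one integer seed, and drivers are deterministic given config
plus seed, so all reported numbers regenerate bit-exactly.

## Known limitations

* Wavelet sizes must be divisible by 2^levels; no arbitrary-size padding.
* Periodic boundaries (wavelet, shearlet) can wrap strong edge content;
  pre-windowing is the caller's responsibility.
* The PCNN high-pass rule is a hard selector; it does not blend
  coefficients, which can leave selection seams in bands when both sources
  are equally active (mitigated by the energy-weighted low-pass).
* Only two-source fusion is implemented; the N-source generalization of
  the convex-combination formalism is out of scope.
* The stage-1 focus classifier is gradient-based; scenes whose defocused
  regions contain stronger gradients than their focused counterparts
  (rare, but possible with bokeh highlights) would mislead it.
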