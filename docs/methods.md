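# Methods

## The model

`mfscreen` implements wavelet transform modulus maxima (WTMM)
multifractal analysis in one and two dimensions, and the screening
pipeline built on it: tile-wise classification of breast images and of
per-pixel temperature dynamics into correlation / multifractality
classes, connected-cluster statistics of flagged tiles, and cohort
comparisons.

### Continuous wavelet transform

* **1D.** `W[S](t0, a) = (1/a) ∫ S(t) ψ((t−t0)/a) dt` with ψ an
  order-n Gaussian derivative (default n = 3, three vanishing
  moments, so polynomial trends up to degree 2 are invisible). The
  transform is evaluated spectrally — the dilated kernels have exact
  closed-form Fourier transforms — with mirror padding of the data.
* **2D.** The two analyzing wavelets are the partial derivatives of
  the isotropic Gaussian smoother `φ(x,y) = exp(−|x|²/2)`; the
  transform is the gradient field of the smoothed image (Canny's
  multiscale edge operator), with modulus `M = |W|` and argument
  `A = arg(W₁ + iW₂)`, under the L1 (1/a²) normalisation so that the
  modulus along a maxima line scales as `a^h` with h the local Hölder
  exponent.

### Maxima, chains and the skeleton

At each scale the edge-like points where M is locally maximal along
the gradient direction form connected **maxima chains**; the maxima of
M *along* a chain are the WTMMM. In the production path WTMMM are
detected directly as strict 3×3 spatial local maxima of M: a modulus
maximum along a chain is simultaneously maximal across it, so the two
definitions coincide for smooth fields, but the direct detection is
immune to the fragmentation of pixel-discretised chains. (Chain-level
operations — chain extraction, ordering, per-chain maxima with the
plateau tie rule — are implemented and tested as an API for chain
geometry, and are not used for exponent estimation.) Fragmented
chains matter: counting one maximum per chain fragment changes the
maxima-count decay from `a⁻²` to roughly `a⁻¹` and destroys
`τ(0) = −2`.

WTMMM are chained fine→coarse into **maxima lines** by greedy
nearest-neighbour assignment within a chaining radius
`max(1.5 px, 0.3·a·unit_scale)`; a coarse maximum can be claimed once
(losing lines terminate — line merging) and unclaimed coarse maxima
root new lines. The number of lines crossing scale a therefore decays
like the singularity-support dimension demands.

### Partition functions and spectra

With the supremum replacement (each line carries at scale a the
supremum of its moduli at scales ≤ a — the standard guard making
q < 0 moments finite):

    Z(q,a) = Σ_{l ∈ L(a)} M_sup(l,a)^q            ~ a^τ(q)
    h(q,a) = Σ ln(M_sup) Ŵ(q,l,a),   D(q,a) = Σ Ŵ ln Ŵ = q·h(q,a) − ln Z

where `Ŵ = M_sup^q / Z` are the Boltzmann weights (they sum to 1 at
every (q, a); `Z(0,a)` is the integer line count). `L(a)` contains
every line alive at a. τ(q) is the slope of `log2 Z` vs `log2 a` over
the fit window; h(q) and D(q) are the slopes of the expectation values
vs `ln a`, giving D(h) as a curve parametrised by q. Because the
regressions are linear in the data, `D(q) = q·h(q) − τ(q)` holds
exactly (Legendre consistency).

The quadratic (log-normal) summary `τ(q) = −c₀ + c₁q − c₂q²/2` is
fitted by weighted least squares (weights = inverse per-q regression
variance) on q ∈ [−1, 2] for images and q ∈ [−2, 5] for time series;
c₂ is clipped at 0. The Hurst exponent is the slope of a weighted
linear fit of τ(q) on q ∈ [−1, 3] (the statistically converged
moments); its weighted RMS nonlinearity is reported as a
monofractality check. q is computed on [−2, 5] in steps of 0.25.

### Scaling-quality gate

A tile is flagged *no-scaling* (pink / white) unless, at each control
moment q ∈ {0, 1, 2}, the `log2 Z` vs `log2 a` regression has
R² ≥ 0.98 **or** RMS deviation from the fitted line ≤ 0.05 (log2
units). The residual alternative is essential: when the true slope is
near zero (1D tiles with H ≈ 0.5 have τ(2) ≈ 0) R² is uninformative —
a perfectly flat, perfectly scaling curve has R² ≈ 0. The pair of
thresholds flags degenerate input (constants, pure noise crossovers)
while passing ≥ 93% of monofractal control tiles.

## Scale ladders and fit windows

Scales are geometric; `unit_scale` maps the dimensionless a to pixels
(7 px = 0.35 mm at the nominal 50 μm pitch) or samples.

* **Whole-image 2D default** (`ScaleGrid.default_image()`): 26 scales,
  a ∈ [1, 9.2], fit window a ∈ [2, 8] = 0.7–2.8 mm (the window where
  mammographic partition functions scale cleanly; larger scales are
  kept only to stabilise chaining). Scales above a ≈ 9 contribute
  nothing to the fit and only add padding cost, so the ladder stops
  there.
* **Tile classification** (`ScaleGrid.tile_image()`): 20 scales,
  a ∈ [0.25, 2.3], fit window a ∈ [0.5, 2] (kernel widths 3.5–14 px).
  Rationale: a 256² tile core contains only ~20 independent patches at
  kernel width 56 px, which bounds the per-tile Hurst noise at ≈ 0.135
  no matter the estimator — too noisy to resolve the
  0.45 ≤ H ≤ 0.55 band. At 3.5–14 px the same core holds ~16× more
  patches and the per-tile noise drops to 0.05–0.08 with negligible
  bias (verified on exact fBm tiles at H = 1/3, 1/2, 2/3). Synthetic
  surfaces are scale-free, so this window is a units convention, not a
  physical claim; analyses of real 50 μm mammograms should prefer the
  default window, which avoids detector-scale noise.
  The ladder always extends well below the fit window so the supremum
  replacement saturates before the first fitted scale (a short
  supremum history tilts τ upward).
* **1D** (`ScaleGrid.from_frequency_window()`): the 0.3–4 Hz window
  (respiratory frequency up to the white-noise cross-over) is mapped
  to scales via `a = f_c·f_s/f` with f_c = √n/2π the spectral peak of
  the order-n wavelet; 24 scales with a 25% margin on both sides.
  Maxima inside the cone of influence (within 5a samples of either
  end) are discarded.

Whole-surface Hurst estimation excludes maxima lines rooted within 1.5
dilated-kernel widths of the image border (a scale-independent
interior margin, so the line-count decay is undistorted); mirror
padding alone leaves a ≈ −0.04 bias from boundary-softened gradients.

## Pipeline stages

* **Mammograms** are tiled into 360² analysis windows with disjoint,
  exhaustive 256² central cores (stride 256, corner-anchored; border
  windows are clipped and mirror-padded, never dropped). Partition
  functions per tile use only lines rooted inside the core. Classes:
  blue (H < 0.45), yellow (0.45 ≤ H ≤ 0.55), red (H > 0.55), pink
  (no-scaling). A breast mask (Otsu + largest component + fill, or
  user-supplied) excludes tiles with < 50% coverage.
* **Thermograms**: 8×8-pixel squares; the 64 per-pixel series are
  cumulatively integrated (a Hölder exponent h of the raw noise-like
  series becomes h_c = h + 1), analysed individually, and their
  partition functions are averaged arithmetically at fixed (q, a)
  before the log-log regressions. Series failing skeleton
  construction are excluded; a tile fails when more than 16 of 64 are.
  Classes: red (monofractal, c₂ < 0.03), blue (multifractal,
  c₂ ≥ 0.03 — the boundary value is multifractal), white (no-scaling).
* **Oscillation suppression**: cardiogenic (~1 Hz) and vasomotor
  (~0.1 Hz) perfusion oscillations sit inside or near the analysis
  band and, at phantom amplitudes (3× the scaling component), dominate
  the wavelet modulus. Before integration, periodogram peaks
  exceeding 10× the local median continuum are removed by
  least-squares subtraction of sinusoids at DFT-refined frequencies
  (deterministic; broadband inputs are untouched because no bin
  reaches the threshold).
* **Clusters**: connected components of yellow (or monofractal-red)
  tiles under edge-or-corner (default) or edge-only connectivity;
  sizes sorted descending; "larger than k" is strict. The cohort
  summary averages per-breast totals, cluster counts and largest
  sizes per side; breasts with no flagged square in any view are
  excluded from the averages (they contribute no cluster statistics),
  which reproduces the embedded cohort table's printed summary rows
  exactly. Standard deviations use ddof = 1.
* **Group statistics**: Wilcoxon rank-sum (exact when n₁·n₂ ≤ 400 and
  tie-free, else normal approximation with tie and continuity
  correction) and Pearson correlation, two-sided, via scipy.stats.

## Synthetic data

* **fBm 1D**: exact Davies–Harte circulant embedding of the fGn
  autocovariance (returns increments; spectral-synthesis fallback with
  a warning if an embedding were indefinite).
* **fBm surfaces**: exact circulant embedding of a radially tapered
  stationary covariance on a doubled torus plus an independent random
  plane (Stein-type construction), giving
  `Var[B(x)−B(y)] = |x−y|^{2H}` exactly at all lags. Plain periodic
  spectral synthesis was rejected: it has zero power below the box
  wavenumber, which measurably flattens the modulus-vs-scale slope
  inside the fit window (checked against the deterministic
  discrete-spectrum expectation).
* **MRW**: fGn of base exponent H₀ = c₁ − c₂ modulated by `exp(ω)`,
  with ω a zero-mean Gaussian field of covariance
  `c₂·ln⁺(L/(1+|τ|))` (integral scale L, default n/8) and mean offset
  `−c₂ ln L` so `E[e^{2ω}] = 1`; the cumulative walk then has
  `τ(q) = −1 + c₁q − c₂q²/2` for scales ≪ L.
* **Thermogram phantom**: per pixel, cardiac (1.1 Hz) and vasomotor
  (0.08 Hz) sinusoids with random phases at 3× the unit scaling
  component (MRW c₂ = 0.05 for healthy pixels, fGn H = 0.5 for tumor
  pixels), plus 0.05-σ white instrumental noise; background pixels
  are constant. 50 Hz sampling.
* **Mammogram phantom**: fBm background with an independent,
  variance-matched fBm lesion blended over a 16-px feathering band,
  plus a per-core truth map.

What the phantoms do **not** emulate: detector noise spectra and
quantisation, breast-edge geometry and compression artefacts,
anatomical texture (ducts, vessels), frequency-drifting and
amplitude-modulated physiological oscillations, or motion. Passing
the synthetic studies therefore demonstrates correctness of the
estimators and pipeline on fields with known exponents — not clinical
performance.

## Problem sizes used in the shipped studies

Hurst recovery uses five 1024² surfaces per H with partition functions
averaged over the five seeds (the same averaging the method applies to
the 64 series of a thermogram square), analysed on the fine-scale
window: at 1024 pixels the default window's coarsest kernels (56 px)
sit in the finite-size regime where scaling deteriorates, which
biases pooled estimates by −0.05 to −0.07 for H ≥ 1/2; at kernel
widths 3.5–14 px every fitted scale is ≥ 73 kernel widths from the
image size and replicate pools agree with the generator H to ±0.02. The dynamics study uses
64-series tiles of 30 000 samples (the nominal 10 min at 50 Hz). The
lesion study uses a 2048² phantom (8×8 cores) with a 3×3-core lesion
and a null control.

## Numerical choices and degenerate inputs

Modulus maxima below 1e−9 of the per-scale peak are discarded
(log-of-zero guard; this also makes `H(αI+β) = H(I)` exact for
α > 0). Sub-pixel maxima positions by separable quadratic
interpolation (offsets clipped to ±0.5 px). Plateau ties — constant
modulus along a chain — keep one representative (largest modulus,
then lowest (row, col)). Constant images and constant series yield
empty skeletons and are reported as no-scaling rather than errors.
Ties in linking are resolved deterministically (distance, then larger
modulus, then lexicographic position), so identical inputs give
bit-identical outputs.

## Known limitations

* Per-tile Hurst classification at the 0.7–2.8 mm window carries
  ≈ 0.135 noise (the information limit of ~20 independent patches per
  core); tile maps at that window are statistical, and cluster-level
  statistics are the robust readout.
* The 2D fBm embedding solves a positive-definiteness weight
  numerically for H > 1/2 and clips residual negative eigenvalues;
  increments were verified exact for H up to 2/3 (and the
  construction is known to hold up to H = 3/4).
* MRW moments are only asymptotically log-normal for scales near L;
  recovered c₂ runs ~10% above the generator value at n = 30 000,
  L = n/8, well within the classification margins used.
* The oscillation filter assumes near-stationary sinusoids; strongly
  drifting oscillations would leave residual ridges.
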