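# mfscreen

Wavelet transform modulus maxima (WTMM) multifractal screening of
breast images and skin-temperature dynamics.

Malignant breast tumors reorganise the tissue around them, and that
reorganisation leaves statistical fingerprints in routine screening
data: the spatial roughness of X-ray mammograms and the temporal
fluctuations of infrared skin temperature. `mfscreen` quantifies both
with the WTMM method — the wavelet-based estimation of singularity
spectra — and turns the estimates into tile-wise classification maps,
cluster statistics and cohort comparisons. It is aimed at researchers
in quantitative breast-imaging and physiological-signal analysis who
need a tested, scriptable implementation of 1D and 2D WTMM with the
screening pipeline on top.

## The method in brief

For an image `I`, the WT at scale `a` is the gradient of the
Gaussian-smoothed image (Canny's multiscale edge operator); its
modulus maxima chain across scales into *maxima lines* along which the
modulus behaves as `a^h`, `h` the local Hölder exponent. Moments of
the modulus over the maxima lines `L(a)`,

    Z(q, a) = Σ_{l ∈ L(a)} M(l, a)^q  ~  a^τ(q),

define the scaling exponents τ(q); the singularity spectrum `D(h)`
follows by Legendre transform, computed in practice from the
Boltzmann-weight expectation values `h(q, a)` and `D(q, a)`. A
monofractal rough surface has `τ(q) = qH − 2` (a single exponent, the
Hurst exponent H); curvature of τ(q), summarised by the log-normal fit
`τ(q) = −c₀ + c₁q − c₂q²/2`, signals multifractality with
intermittency coefficient c₂. The same machinery in 1D (with the
series' cumulative integral) diagnoses temperature dynamics as
monofractal (`c₂ < 0.03`), multifractal (`c₂ ≥ 0.03`) or no-scaling.

Screening layers:

* mammogram tiles (256² cores inside 360² windows) are colour-coded
  blue (`H < 0.45`, anti-correlated "fatty"), yellow
  (`0.45 ≤ H ≤ 0.55`, uncorrelated — the "risky" class), red
  (`H > 0.55`, long-range correlated "dense") or pink (no scaling);
* thermogram 8×8-pixel squares are classified red / blue / white by
  the c₂ rule applied to the averaged partition functions of their 64
  series;
* connected clusters of flagged tiles (sharing an edge or corner) are
  counted and sized per breast, and cohorts are compared with Wilcoxon
  rank-sum and Pearson tests.

Exact synthetic generators (fractional Brownian surfaces and noise,
multifractal random walks, lesion and thermogram phantoms) provide
ground truth for every stage.

## Worked example

```python
from mfscreen import WTMM2D, ScaleGrid, simulate_fbm_surface

surface = simulate_fbm_surface(1024, H=1/3, seed=7)   # exact fBm, H = 1/3
model = WTMM2D(surface, grid=ScaleGrid.tile_image())
res = model.fit(margin=24)                            # interior maxima lines
print(res.summary())
```

```
WTMM scaling spectra
====================================================
support dimension        2
fit range (a)            [0.5, 2]
scaling flag             scaling
quality R^2 (q=0,1,2)    0: 0.9998, 1: 0.9998, 2: 0.9996
Hurst H                  0.3391 +/- 0.0003  (rms nonlinearity 0.0013)
log-normal c0, c1, c2    1.970, 0.338, 0.0000
----------------------------------------------------
   q      tau(q)     se        h(q)      D(q)
 -2.0    -2.6175    0.0756    0.3141    1.9893
 -1.0    -2.3041    0.0149    0.3239    1.9802
  0.0    -1.9710    0.0087    0.3391    1.9710
  1.0    -1.6301    0.0077    0.3413    1.9715
  2.0    -1.2901    0.0080    0.3382    1.9665
  3.0    -0.9546    0.0088    0.3322    1.9513
  4.0    -0.6263    0.0099    0.3242    1.9230
  5.0    -0.3067    0.0117    0.3148    1.8809
```

The Hurst estimate 0.339 recovers the generator's H = 1/3; τ(q) is
linear (rms nonlinearity 0.001) with fitted intermittency c₂ = 0 —
the surface is monofractal — and `τ(0) = −1.97`, `D(q) ≈ 2` say the
singularities fill the plane: the `D(h)` spectrum collapses onto the
single point `(H, 2)` expected for a monofractal rough surface.

The cohort layer runs off the embedded cluster table:

```
$ mfscreen table1-report
      mean_total  sd_total  mean_n_clusters  sd_n_clusters  mean_largest  sd_largest  n_breasts
side
CB         14.30      6.87             3.90           1.98          8.88        5.09         60
CUB         7.12      5.47             3.16           2.31          4.03        3.55         58

pooled cluster sizes CB (n=234) vs CUB (n=183): p = 6.08e-04 (normal-approx-tie-corrected)
clusters with size > 5: CB 21.8%, CUB 8.7%
```

Cancerous breasts (CB) carry twice the uncorrelated-square load of the
contralateral unaffected breasts (CUB), with much larger clusters —
21.8% of CB clusters exceed five tiles against 8.7% on the unaffected
side, and the difference in the pooled size distributions is
significant at p < 10⁻³.

A CLI mirrors the pipeline stages: `analyze-2d`, `analyze-1d`,
`segment`, `clusters`, `compare`, `simulate`, `table1-report`.

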