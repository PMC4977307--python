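"""Seeded generators of synthetic inputs with known scaling structure.

These provide ground truth for every stage of the pipeline:

* 1D fractional Gaussian noise (the increments of fBm) via exact
  Davies-Harte circulant embedding — monofractal with exponent H;
* 2D fractional Brownian surfaces via spectral synthesis with isotropic
  power spectrum ~ |k|^-(2H+2) — monofractal rough surfaces;
* 1D multifractal random walk (MRW): Gaussian increments modulated by
  exp(omega) with omega a log-correlated Gaussian field, giving the
  log-normal spectrum tau(q) = -1 + c1 q - c2 q^2 / 2 at scales well
  below the integral scale L;
* composite phantoms: a mammogram-like surface with an embedded lesion
  of different scaling class, and a thermogram-like stack of
  oscillation-plus-scaling-noise temperature dynamics.

All generators are deterministic under a fixed seed, and the phantoms
return their parameters alongside the data.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .wtmm1d import Signal1D
from .wtmm2d import Image2D

__all__ = [
    "GeneratorSpec",
    "simulate_fbm_1d",
    "simulate_fbm_surface",
    "simulate_mrw_1d",
    "simulate_thermogram_phantom",
    "simulate_mammogram_phantom",
    "variogram_exponent",
    "structure_function_exponents",
]


# ----------------------------------------------------------------------
# stationary Gaussian sampling (circulant embedding)
# ----------------------------------------------------------------------
def _circulant_eigs(cov_row: np.ndarray) -> np.ndarray:
    c = np.concatenate([cov_row, cov_row[-2:0:-1]])
    return np.fft.fft(c).real


def _sample_circulant(eigs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """One sample of a stationary Gaussian series of length n from the
    eigenvalues of its 2n-2 circulant embedding (Davies-Harte)."""
    m = eigs.size
    half = m // 2
    u = rng.standard_normal(m)
    v = rng.standard_normal(m)
    a = np.zeros(m, dtype=complex)
    w = np.sqrt(np.clip(eigs, 0.0, None) / m)
    a[0] = w[0] * u[0]
    a[half] = w[half] * u[half]
    k = np.arange(1, half)
    a[k] = w[k] * (u[k] + 1j * v[k]) / np.sqrt(2.0)
    a[m - k] = np.conj(a[k])
    return np.fft.fft(a).real[:n]


def _fgn_cov_row(n: int, H: float) -> np.ndarray:
    k = np.arange(n, dtype=float)
    return 0.5 * (np.abs(k - 1) ** (2 * H) - 2 * k ** (2 * H) + (k + 1) ** (2 * H))


def simulate_fbm_1d(n: int, H: float, seed: int) -> Signal1D:
    """Exact fractional Gaussian noise (unit variance): the increment
    process of fBm with Hurst exponent H.  Cumulative integration
    downstream reconstructs the fBm profile.

    Falls back to approximate spectral synthesis (with a warning) if
    the circulant embedding is not positive semi-definite.
    """
    if not 0 < H < 1:
        raise ValueError("H must be in (0, 1)")
    rng = np.random.default_rng(seed)
    eigs = _circulant_eigs(_fgn_cov_row(n, H))
    if eigs.min() < -1e-8 * eigs.max():
        warnings.warn("circulant embedding not PSD; using spectral synthesis")
        return _fgn_spectral(n, H, rng)
    return Signal1D(_sample_circulant(eigs, n, rng))


def _fgn_spectral(n: int, H: float, rng: np.random.Generator) -> Signal1D:
    f = np.fft.rfftfreq(2 * n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-(H + 0.5))
    noise = rng.standard_normal(2 * n)
    prof = np.fft.irfft(np.fft.rfft(noise) * amp, n=2 * n)[:n + 1]
    inc = np.diff(prof)
    return Signal1D(inc / inc.std())


def simulate_fbm_surface(n: int, H: float, seed: int) -> Image2D:
    """Isotropic fractional Brownian surface, n x n (n a power of two),
    with exact increment statistics: Var[B(x) - B(y)] = |x - y|^{2H}.

    Uses circulant embedding of a radially tapered stationary
    covariance on a doubled torus (the classical exact fBm-surface
    construction): a stationary field with covariance
    psi(r) = c0 + c2 r^2 - r^{2H} (tapered smoothly to zero on
    1 <= r <= 2) is sampled spectrally, and an independent random
    plane restores the quadratic term.  For H <= 1/2 the taper weight
    beta = 0 is positive definite; for larger H the smallest feasible
    beta is solved from the (affine-in-beta) embedding eigenvalues.
    Output is normalised to zero mean, unit variance (an affine map,
    irrelevant to any scaling exponent).
    """
    if not 0 < H < 1:
        raise ValueError("H must be in (0, 1)")
    if n & (n - 1):
        raise ValueError("n must be a power of 2")
    rng = np.random.default_rng(seed)
    m = 2 * n
    t = np.minimum(np.arange(m), m - np.arange(m)) / n     # torus distance, x-units
    r = np.hypot(t[:, None], t[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        inner0 = (1.0 - H) + H * r**2 - r ** (2 * H)       # beta = 0 branch
        g = np.where(r <= 1, 3.0 - 2.0 * r**2, (2.0 - r) ** 3 / np.maximum(r, 1e-12))
    psi0 = np.where(r <= 1, inner0, 0.0)
    lam0 = np.fft.fft2(psi0).real
    lamg = np.fft.fft2(np.where(r <= 1, g, np.where(r <= 2, g, 0.0))).real
    beta = 0.0
    if lam0.min() < 0:
        pos = lamg > 0
        lo = np.max(-lam0[pos] / lamg[pos]) if pos.any() else 0.0
        beta = float(max(lo, 0.0)) * 1.0001
    lam = np.clip(lam0 + beta * lamg, 0.0, None)
    c2v = H - 2.0 * beta
    xi = rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m))
    Z = (np.fft.fft2(np.sqrt(lam) * xi) / m).real
    gvec = rng.standard_normal(2)
    ax = np.arange(n) / n
    plane = np.sqrt(max(2.0 * c2v, 0.0)) * (gvec[0] * ax[:, None] + gvec[1] * ax[None, :])
    B = (Z[:n, :n] - Z[0, 0] + plane) / np.sqrt(2.0)
    B = (B - B.mean()) / B.std()
    return Image2D(B)


# ----------------------------------------------------------------------
def _log_correlated_field(n: int, c2: float, L: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean stationary Gaussian omega with
    Cov(omega_t, omega_{t+tau}) = c2 * max(ln(L / (1 + |tau|)), 0)."""
    tau = np.arange(n, dtype=float)
    cov = c2 * np.clip(np.log(L / (1.0 + tau)), 0.0, None)
    eigs = _circulant_eigs(cov)
    return _sample_circulant(eigs, n, rng)


def simulate_mrw_1d(
    n: int, c1: float = 0.55, c2: float = 0.05, L: float | None = None, seed: int = 0
) -> Signal1D:
    """Multifractal random walk increments with log-normal spectrum.

    Gaussian fGn increments of base exponent H0 = c1 - c2 are modulated
    by exp(omega) with omega log-correlated of intermittency c2 and
    integral scale L (default n/8), normalised so E[e^{2 omega}] = 1.
    The cumulative walk then has tau(q) = -1 + c1 q - c2 q^2 / 2 for
    scales << L.
    """
    if c2 <= 0:
        raise ValueError("c2 must be positive (use simulate_fbm_1d for c2 = 0)")
    if L is None:
        L = n / 8
    if L >= n:
        raise ValueError("integral scale L must be << n")
    H0 = c1 - c2
    if not 0 < H0 < 1:
        raise ValueError("c1 - c2 must lie in (0, 1)")
    ss = np.random.SeedSequence(seed)
    rng_eps, rng_omega = (np.random.default_rng(s) for s in ss.spawn(2))
    eps = simulate_fbm_1d(n, H0, rng_eps.integers(2**31)).samples
    omega = _log_correlated_field(n, c2, L, rng_omega)
    mu = -c2 * np.log(L)
    return Signal1D(eps * np.exp(omega + mu))


# ----------------------------------------------------------------------
# phantoms
# ----------------------------------------------------------------------
def simulate_thermogram_phantom(
    shape: tuple[int, int] = (16, 16),
    region_map: np.ndarray | None = None,
    seed: int = 0,
    n_frames: int = 8192,
    sampling_rate: float = 50.0,
    c1_healthy: float = 0.55,
    c2_healthy: float = 0.05,
    H_tumor: float = 0.5,
    cardiac_freq: float = 1.1,
    vasomotor_freq: float = 0.1,
    oscillation_amp: float = 3.0,
    noise_std: float = 0.05,
):
    """Thermogram-like stack: per-pixel temperature dynamics.

    Each non-background pixel carries a cardiac sinusoid (~1 Hz), a
    vasomotor sinusoid (~0.1 Hz), a unit-variance scaling component
    (MRW with intermittency ``c2_healthy`` for healthy pixels, fGn with
    ``H_tumor`` for tumor pixels) and white instrumental noise; the
    oscillations are ``oscillation_amp`` times the scaling-component
    standard deviation.  Background pixels are constant.

    ``region_map``: int array of ``shape`` with 0 = background,
    1 = healthy, 2 = tumor (default: all healthy).

    Returns (stack (n_frames, rows, cols) float32, params dict).
    """
    rows, cols = shape
    if region_map is None:
        region_map = np.ones(shape, dtype=int)
    region_map = np.asarray(region_map)
    if region_map.shape != tuple(shape):
        raise ValueError("region_map shape mismatch")
    ss = np.random.SeedSequence(seed)
    pixel_seeds = ss.spawn(rows * cols)
    t = np.arange(n_frames) / sampling_rate
    stack = np.zeros((n_frames, rows, cols), dtype=np.float32)
    for r in range(rows):
        for c in range(cols):
            lab = int(region_map[r, c])
            if lab == 0:
                continue
            rng = np.random.default_rng(pixel_seeds[r * cols + c])
            sub = rng.integers(2**31)
            if lab == 1:
                x = simulate_mrw_1d(n_frames, c1_healthy, c2_healthy, seed=sub).samples
            else:
                x = simulate_fbm_1d(n_frames, H_tumor, sub).samples
            x = x / x.std()
            phase1, phase2 = rng.uniform(0, 2 * np.pi, 2)
            series = (
                x
                + oscillation_amp * np.sin(2 * np.pi * cardiac_freq * t + phase1)
                + oscillation_amp * np.sin(2 * np.pi * vasomotor_freq * t + phase2)
                + noise_std * rng.standard_normal(n_frames)
            )
            stack[:, r, c] = series
    params = dict(
        kind="thermo_phantom", shape=list(shape), seed=seed, n_frames=n_frames,
        sampling_rate=sampling_rate, c1_healthy=c1_healthy, c2_healthy=c2_healthy,
        H_tumor=H_tumor, cardiac_freq=cardiac_freq, vasomotor_freq=vasomotor_freq,
        oscillation_amp=oscillation_amp, noise_std=noise_std,
    )
    return stack, params


def simulate_mammogram_phantom(
    size: int = 1024,
    H_bg: float = 1.0 / 3.0,
    lesion_rect: tuple[int, int, int, int] | None = None,
    H_lesion: float = 0.5,
    seed: int = 0,
    feather: int = 16,
    core: int = 256,
):
    """Mammogram-like phantom: fBm background with an embedded lesion
    region of a different scaling class.

    ``lesion_rect`` is (row0, row1, col0, col1) in pixels (half-open);
    the lesion surface is independent, variance-matched and blended
    over a ``feather``-pixel band.  Returns (Image2D, truth) where
    ``truth`` is the per-core expected class grid ('yellow' for cores
    centred in the lesion when H_lesion = 0.5, 'blue' for an
    antipersistent background, etc.) on the ``core``-pixel tiling.
    """
    ss = np.random.SeedSequence(seed)
    s_bg, s_les = (np.random.default_rng(s).integers(2**31) for s in ss.spawn(2))
    bg = simulate_fbm_surface(size, H_bg, s_bg).pixels
    if lesion_rect is None:
        img = bg
    else:
        r0, r1, c0, c1 = lesion_rect
        if not (0 <= r0 < r1 <= size and 0 <= c0 < c1 <= size):
            raise ValueError("lesion_rect outside image")
        les = simulate_fbm_surface(size, H_lesion, s_les).pixels
        rows = np.arange(size)
        cols = np.arange(size)
        wr = np.clip(np.minimum(rows - (r0 - feather), (r1 - 1 + feather) - rows) / feather, 0, 1)
        wc = np.clip(np.minimum(cols - (c0 - feather), (c1 - 1 + feather) - cols) / feather, 0, 1)
        w = np.outer(wr, wc)
        img = bg * (1 - w) + les * w

    def expected_class(H):
        if H < 0.45:
            return "blue"
        if H <= 0.55:
            return "yellow"
        return "red"

    n_cores = size // core
    truth = np.empty((n_cores, n_cores), dtype=object)
    for i in range(n_cores):
        for j in range(n_cores):
            rc = i * core + core // 2
            cc = j * core + core // 2
            inside = (
                lesion_rect is not None
                and lesion_rect[0] <= rc < lesion_rect[1]
                and lesion_rect[2] <= cc < lesion_rect[3]
            )
            truth[i, j] = expected_class(H_lesion if inside else H_bg)
    return Image2D(img), truth


# ----------------------------------------------------------------------
@dataclass
class GeneratorSpec:
    """Serializable description of one synthetic dataset."""

    kind: str                    # fbm1d | fbm2d | mrw1d | thermo_phantom | mammo_phantom
    seed: int = 0
    params: dict = field(default_factory=dict)

    def generate(self):
        fns = {
            "fbm1d": lambda: simulate_fbm_1d(seed=self.seed, **self.params),
            "fbm2d": lambda: simulate_fbm_surface(seed=self.seed, **self.params),
            "mrw1d": lambda: simulate_mrw_1d(seed=self.seed, **self.params),
            "thermo_phantom": lambda: simulate_thermogram_phantom(seed=self.seed, **self.params),
            "mammo_phantom": lambda: simulate_mammogram_phantom(seed=self.seed, **self.params),
        }
        if self.kind not in fns:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        return fns[self.kind]()

    def to_dict(self) -> dict:
        return asdict(self)


# ----------------------------------------------------------------------
# independent oracles (moment/variogram based, no wavelets)
# ----------------------------------------------------------------------
def variogram_exponent(profile: np.ndarray, lags: np.ndarray | None = None, axis: int = 0) -> float:
    """Log-log slope of the second-order variogram E[(x(t+l) - x(t))^2]
    ~ l^{2H}; returns the slope (i.e. 2H) for a profile (1D) or for a
    surface along ``axis``."""
    x = np.asarray(profile, float)
    if lags is None:
        lags = np.unique(np.round(np.geomspace(1, max(4, x.shape[axis] // 8), 12)).astype(int))
    v = []
    for l in lags:
        if axis == 0:
            d = x[l:] - x[:-l]
        else:
            d = x[:, l:] - x[:, :-l]
        v.append(np.mean(d**2))
    slope = np.polyfit(np.log(lags), np.log(v), 1)[0]
    return float(slope)


def structure_function_exponents(increments: np.ndarray, q_values: np.ndarray,
                                 lags: np.ndarray | None = None) -> np.ndarray:
    """Direct moment-regression exponents zeta(q) of the cumulative
    walk: E|X(t+l) - X(t)|^q ~ l^{zeta(q)}.  Independent of the WTMM
    pathway; used as an oracle for the MRW generator."""
    x = np.cumsum(np.asarray(increments, float))
    if lags is None:
        lags = np.unique(np.round(np.geomspace(2, x.size // 16, 10)).astype(int))
    logl = np.log(lags)
    zetas = []
    for q in q_values:
        m = [np.mean(np.abs(x[l:] - x[:-l]) ** q) for l in lags]
        zetas.append(np.polyfit(logl, np.log(m), 1)[0])
    return np.asarray(zetas)
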