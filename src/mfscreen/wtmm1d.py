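"""1D WTMM analysis of temperature time series.

The raw series (a noise-like increment process) is first cumulatively
integrated; singularities with Holder exponent -1 < h < 0 in the raw
series become 0 < h_c = h + 1 < 1 in the cumulative, which is the
object the CWT analyses.  Maxima of the WT modulus are chained across
scales into a skeleton per series; the partition functions of the 64
series of an 8x8-pixel square are averaged at fixed (q, a) before the
log-log regressions.  The tile is diagnosed monofractal when the
fitted intermittency coefficient c2 < 0.03, multifractal when
c2 >= 0.03, and no-scaling when the quality gate fails.

The analysed frequency window, 0.3-4 Hz at 50 Hz sampling, spans the
scale-invariant background between the respiratory frequency and the
cross-over to instrumental white noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .partition import (
    PartitionFunctionSet,
    average_partition_functions,
    compute_partition_functions,
    default_q_grid,
)
from .scales import ScaleGrid
from .skeleton import Skeleton, link_maxima
from .spectra import ScalingSpectra, fit_scaling
from .wavelets import derivative_multiplier_1d, gauss_center_frequency
from .wtmm2d import MODULUS_FLOOR_REL, _degenerate_spectra

__all__ = [
    "Signal1D",
    "CumulativeSignal",
    "DynamicsDiagnosis",
    "TileAnalysisError",
    "cumulative_integrate",
    "cwt1d",
    "skeleton_1d",
    "averaged_partition_functions",
    "diagnose_dynamics",
    "WTMM1D",
]

#: intermittency threshold separating monofractal from multifractal
C2_THRESHOLD = 0.03
#: a tile of 64 series fails when more than this many series are excluded
MAX_EXCLUDED_SERIES = 16
#: cone-of-influence half-width, in units of the scale a (samples)
COI_RADIUS_SCALES = 5.0

MIN_ANALYSIS_LENGTH = 4096


class TileAnalysisError(RuntimeError):
    """Too many series of a tile failed skeleton construction."""


@dataclass(frozen=True)
class Signal1D:
    samples: np.ndarray
    sampling_rate: float = 50.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1:
            raise ValueError("samples must be 1D")
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite samples rejected")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CumulativeSignal:
    """Mean-removed running sum of a Signal1D.

    Differencing recovers the (mean-removed) source exactly; a Holder
    exponent h of the source maps to h_c = h + 1 here.
    """

    samples: np.ndarray
    sampling_rate: float
    source: str = "unknown"

    def __len__(self) -> int:
        return len(self.samples)


def cumulative_integrate(signal: Signal1D | np.ndarray, sampling_rate: float = 50.0,
                         source: str = "signal") -> CumulativeSignal:
    if isinstance(signal, Signal1D):
        samples, sampling_rate = signal.samples, signal.sampling_rate
    else:
        samples = np.asarray(signal, dtype=float)
    cum = np.cumsum(samples - samples.mean())
    return CumulativeSignal(cum, sampling_rate, source)


def remove_narrowband(
    x: np.ndarray,
    sampling_rate: float,
    search_band: tuple[float, float] = (0.03, 6.0),
    peak_factor: float = 10.0,
    smooth_bins: int = 201,
) -> np.ndarray:
    """Suppress narrowband oscillations (cardiogenic / vasomotor
    perfusion peaks) in a raw series before the scaling analysis.

    Periodogram peaks inside ``search_band`` exceeding ``peak_factor``
    times the local median continuum are removed by least-squares
    subtraction of a sinusoid at the refined peak frequency (the
    frequency maximising the DFT magnitude near the winning bin),
    iterating over up to 8 peaks.  The filter is deterministic; on
    broadband scaling noise no bin reaches the threshold, so plain
    fBm/MRW inputs pass through unchanged.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    t = np.arange(n)
    out = x.copy()
    for _ in range(8):                      # at most a few discrete peaks
        p = np.abs(np.fft.rfft(out)) ** 2
        f = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
        k = min(smooth_bins, 2 * (p.size // 2) - 1)
        cont = ndimage.median_filter(p, size=max(k, 3), mode="nearest")
        in_band = (f >= search_band[0]) & (f <= search_band[1])
        ratio = np.where(in_band, p / np.maximum(cont, 1e-300), 0.0)
        i = int(np.argmax(ratio))
        if ratio[i] <= peak_factor:
            break
        # refine the peak frequency: maximise the DFT magnitude at a
        # continuous frequency near the winning bin
        def neg_power(fbin):
            z = np.exp(-2j * np.pi * fbin * t / n)
            return -np.abs(z @ out)

        res = minimize_scalar(
            neg_power, bounds=(i - 1.0, i + 1.0), method="bounded",
            options={"xatol": 1e-4},
        )
        f0 = float(res.x) / n * sampling_rate
        w = 2.0 * np.pi * f0 / sampling_rate
        A = np.stack([np.sin(w * t), np.cos(w * t)], axis=1)
        coef, *_ = np.linalg.lstsq(A, out, rcond=None)
        out = out - A @ coef
    return out


# ----------------------------------------------------------------------
@dataclass
class CWT1D:
    """CWT modulus over (t, a) plus the cone-of-influence mask
    (True where coefficients are free of boundary contamination)."""

    modulus: np.ndarray          # (n_scales, n)
    grid: ScaleGrid
    coi: np.ndarray              # (n_scales, n) bool
    sampling_rate: float
    wavelet_order: int


def cwt1d(
    signal: CumulativeSignal | np.ndarray,
    grid: ScaleGrid,
    n_vanishing: int = 3,
) -> CWT1D:
    """Continuous WT with the order-n Gaussian derivative (1/a
    normalisation), mirror boundary handling.

    Scales are in samples (unit_scale = 1).  Scales exceeding n/8
    samples are rejected.
    """
    if n_vanishing < 2:
        raise ValueError("n_vanishing must be >= 2")
    x = signal.samples if isinstance(signal, CumulativeSignal) else np.asarray(signal, float)
    fs = signal.sampling_rate if isinstance(signal, CumulativeSignal) else 1.0
    n = x.size
    a_samples = grid.scales_physical
    if a_samples[-1] > n / 8:
        raise ValueError(
            f"largest scale {a_samples[-1]:.1f} samples exceeds n/8 = {n / 8:.0f}"
        )
    pad = int(min(np.ceil(COI_RADIUS_SCALES * a_samples[-1]), n - 1))
    xp = np.pad(x, pad, mode="reflect")
    spec = np.fft.rfft(xp)
    npad = xp.size
    mod = np.empty((grid.n_scales, n))
    coi = np.zeros((grid.n_scales, n), dtype=bool)
    t = np.arange(n)
    for i, a in enumerate(a_samples):
        mult = derivative_multiplier_1d(npad, a, n_vanishing)
        w = np.fft.irfft(spec * mult, n=npad)[pad : pad + n]
        mod[i] = np.abs(w)
        margin = COI_RADIUS_SCALES * a
        coi[i] = (t >= margin) & (t <= n - 1 - margin)
    return CWT1D(modulus=mod, grid=grid, coi=coi, sampling_rate=fs,
                 wavelet_order=n_vanishing)


def _maxima_row(m: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima of one modulus row (plateaus keep their left
    edge), restricted to the cone-of-influence, with sub-sample
    quadratic refinement."""
    peak = m.max()
    if peak <= 0:
        return np.empty((0, 1)), np.empty(0)
    left = np.empty_like(m)
    right = np.empty_like(m)
    left[0] = np.inf
    left[1:] = m[:-1]
    right[-1] = np.inf
    right[:-1] = m[1:]
    is_max = (m > left) & (m >= right) & (m > MODULUS_FLOOR_REL * peak) & valid
    idx = np.flatnonzero(is_max)
    if idx.size == 0:
        return np.empty((0, 1)), np.empty(0)
    inner = idx[(idx > 0) & (idx < m.size - 1)]
    delta = np.zeros(idx.size)
    if inner.size:
        ml = m[inner - 1]
        mr = m[inner + 1]
        denom = ml - 2 * m[inner] + mr
        d = np.where(np.abs(denom) > 1e-30, 0.5 * (ml - mr) / denom, 0.0)
        delta[(idx > 0) & (idx < m.size - 1)] = np.clip(d, -0.5, 0.5)
    pos = (idx + delta)[:, None]
    return pos, m[idx]


def skeleton_1d(cwt: CWT1D) -> Skeleton:
    """Chain the per-scale WTMM across scales into maxima lines
    (1D analogue of the 2D skeleton; same chaining-radius rule)."""
    points = [
        _maxima_row(cwt.modulus[i], cwt.coi[i]) for i in range(cwt.grid.n_scales)
    ]
    return link_maxima(points, cwt.grid)


# ----------------------------------------------------------------------
def averaged_partition_functions(
    signals,
    grid: ScaleGrid,
    q_grid: np.ndarray | None = None,
    n_vanishing: int = 3,
    max_excluded: int = MAX_EXCLUDED_SERIES,
) -> tuple[PartitionFunctionSet, int, int]:
    """Per-series partition functions, arithmetically averaged at fixed
    (q, a) over the series of one tile.

    ``signals`` is an iterable of CumulativeSignal (or arrays, taken as
    already-cumulated).  Series whose skeleton yields no line crossing
    every fit-range scale are excluded; more than ``max_excluded``
    exclusions raise :class:`TileAnalysisError`.

    Returns (averaged set, n_used, n_excluded).
    """
    if q_grid is None:
        q_grid = default_q_grid()
    parts = []
    excluded = 0
    for s in signals:
        try:
            cw = cwt1d(s, grid, n_vanishing)
            sk = skeleton_1d(cw)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pf = compute_partition_functions(sk, q_grid)
            if np.any(pf.counts == 0):
                raise ValueError("line count vanished inside fit window")
            parts.append(pf)
        except (ValueError, np.linalg.LinAlgError):
            excluded += 1
    if excluded > max_excluded or not parts:
        raise TileAnalysisError(
            f"{excluded} series excluded (limit {max_excluded}); tile fails"
        )
    return average_partition_functions(parts), len(parts), excluded


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class DynamicsDiagnosis:
    """Mono/multifractal classification of one tile's dynamics."""

    c2: float
    label: str                  # 'monofractal' | 'multifractal' | 'no_scaling'
    spectra: ScalingSpectra

    def to_dict(self) -> dict:
        return {
            "c0": float(self.spectra.c0),
            "c1": float(self.spectra.c1),
            "c2": float(self.c2),
            "class": self.label,
        }


def diagnose_dynamics(spectra: ScalingSpectra) -> DynamicsDiagnosis:
    """Threshold rule: monofractal iff scaling holds and c2 < 0.03;
    multifractal iff scaling holds and c2 >= 0.03 (the boundary value
    is multifractal); no_scaling otherwise."""
    if not spectra.scaling_ok:
        return DynamicsDiagnosis(c2=spectra.c2, label="no_scaling", spectra=spectra)
    label = "multifractal" if spectra.c2 >= C2_THRESHOLD else "monofractal"
    return DynamicsDiagnosis(c2=spectra.c2, label=label, spectra=spectra)


# ----------------------------------------------------------------------
class WTMM1D:
    """1D WTMM model for one tile of temperature time series.

    Parameters
    ----------
    signals : array (n_series, n) or (n,), or list of Signal1D
        Raw series; cumulative integration is applied unless
        ``integrate=False``.
    sampling_rate : float, Hz.
    frequency_window : (f_low, f_high) in Hz
        Fit window; default 0.3-4 Hz.
    wavelet_order : int
        Vanishing moments of the Gaussian-derivative wavelet.
    """

    def __init__(
        self,
        signals,
        sampling_rate: float = 50.0,
        frequency_window: tuple[float, float] = (0.3, 4.0),
        wavelet_order: int = 3,
        grid: ScaleGrid | None = None,
        q_grid: np.ndarray | None = None,
        integrate: bool = True,
        suppress_oscillations: bool = True,
    ) -> None:
        if isinstance(signals, Signal1D):
            signals = [signals]
        arr = [s.samples if isinstance(s, Signal1D) else np.asarray(s, float) for s in signals] \
            if isinstance(signals, (list, tuple)) else [r for r in np.atleast_2d(np.asarray(signals, float))]
        if any(len(s) < MIN_ANALYSIS_LENGTH for s in arr):
            raise ValueError(f"series shorter than {MIN_ANALYSIS_LENGTH} samples")
        self.sampling_rate = sampling_rate
        self.wavelet_order = wavelet_order
        fc = gauss_center_frequency(wavelet_order)
        self.grid = grid or ScaleGrid.from_frequency_window(
            sampling_rate, *frequency_window, center_frequency=fc
        )
        self.q_grid = default_q_grid() if q_grid is None else np.asarray(q_grid, float)
        if integrate:
            if suppress_oscillations:
                arr = [remove_narrowband(s, sampling_rate) for s in arr]
            self.signals = [cumulative_integrate(s, sampling_rate) for s in arr]
        else:
            self.signals = [CumulativeSignal(s, sampling_rate) for s in arr]
        self.n_series_used: int | None = None
        self.n_series_excluded: int | None = None

    def fit(self) -> ScalingSpectra:
        try:
            pf, used, excl = averaged_partition_functions(
                self.signals, self.grid, self.q_grid, self.wavelet_order
            )
        except TileAnalysisError:
            self.n_series_used = 0
            self.n_series_excluded = len(self.signals)
            return _degenerate_spectra(self.q_grid, self.grid, support_dim=1)
        self.n_series_used = used
        self.n_series_excluded = excl
        return fit_scaling(
            pf, self.grid, support_dim=1,
            hurst_q_range=(-1.0, 3.0), lognormal_q_range=(-2.0, 5.0),
        )

    def diagnose(self) -> DynamicsDiagnosis:
        return diagnose_dynamics(self.fit())
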