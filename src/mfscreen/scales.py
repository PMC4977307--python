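"""Geometric scale ladders with physical-unit bookkeeping.

The continuous wavelet transform is evaluated on a geometric ladder of
dimensionless scales ``a``.  ``unit_scale`` maps ``a = 1`` to a physical
extent: pixels for images (7 px = 0.35 mm at 50 um/px, so that the fit
window log2 a in [1, 3] is 0.7-2.8 mm) or samples for time series.
Scaling exponents are read off from log-log regressions restricted to
``fit_range``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScaleGrid"]

#: default mammographic pixel pitch, mm (50 um detectors)
DEFAULT_PIXEL_SIZE_MM = 0.05


@dataclass(frozen=True)
class ScaleGrid:
    """Strictly increasing geometric ladder of analysis scales.

    Parameters
    ----------
    scales : ndarray
        Dimensionless scale values ``a``, strictly increasing, > 0.
    unit_scale : float
        Physical extent (in pixels or samples) corresponding to ``a = 1``.
    fit_range : (float, float)
        Sub-interval of ``scales`` over which log-log regressions are
        performed.  Must contain at least 3 ladder points (>= 8 for the
        default ladders).
    """

    scales: np.ndarray
    unit_scale: float = 7.0
    fit_range: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=float)
        object.__setattr__(self, "scales", scales)
        if scales.ndim != 1 or scales.size < 2:
            raise ValueError("need at least two scales")
        if np.any(scales <= 0) or np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be positive and strictly increasing")
        if self.unit_scale <= 0:
            raise ValueError("unit_scale must be positive")
        lo, hi = self.fit_range
        if lo >= hi or lo < scales[0] - 1e-12 or hi > scales[-1] + 1e-12:
            raise ValueError("fit_range must be inside [min(scales), max(scales)]")

    # ------------------------------------------------------------------
    @classmethod
    def geometric(
        cls,
        a_min: float,
        a_max: float,
        n_scales: int,
        unit_scale: float = 7.0,
        fit_range: tuple[float, float] | None = None,
    ) -> "ScaleGrid":
        scales = np.geomspace(a_min, a_max, n_scales)
        if fit_range is None:
            fit_range = (a_min, a_max)
        return cls(scales, unit_scale=unit_scale, fit_range=fit_range)

    @classmethod
    def default_image(cls, n_scales: int = 26) -> "ScaleGrid":
        """Default 2D ladder: a in [1, 9.2], unit_scale 7 px.

        The fit window log2 a in [1, 3] (a in [2, 8]) corresponds to
        0.7-2.8 mm at 50 um/pixel; a handful of scales above the window
        stabilise the cross-scale chaining of maxima lines.
        """
        return cls.geometric(1.0, 9.2, n_scales, unit_scale=7.0, fit_range=(2.0, 8.0))

    @classmethod
    def tile_image(cls, n_scales: int = 20) -> "ScaleGrid":
        """Fine-scale ladder for per-tile classification studies:
        fit window a in [0.5, 2] (kernel width 3.5-14 px).

        A 256-pixel tile core holds ~16x more independent patches at
        these scales than at the coarse end of the default window,
        which cuts the per-tile Hurst noise to ~0.06 — what a planted
        lesion detection study needs.  The ladder extends well below
        the window so the supremum replacement saturates before the
        first fitted scale.
        """
        return cls.geometric(0.25, 2.3, n_scales, unit_scale=7.0, fit_range=(0.5, 2.0))

    @classmethod
    def from_frequency_window(
        cls,
        sampling_rate: float,
        f_low: float = 0.3,
        f_high: float = 4.0,
        center_frequency: float | None = None,
        n_scales: int = 24,
        margin: float = 1.25,
    ) -> "ScaleGrid":
        """Ladder for 1D analysis covering a frequency window in Hz.

        Uses the wavelet's spectral peak ``fc`` (cycles per sample at
        a = 1) to map frequency to scale, ``a = fc * fs / f``.  The
        ladder extends ``margin`` beyond the window on both sides so
        that maxima lines can be rooted below the window and chained
        slightly above it; ``unit_scale`` is 1 sample.
        """
        if center_frequency is None:
            from .wavelets import gauss_center_frequency

            center_frequency = gauss_center_frequency(3)
        a_hi = center_frequency * sampling_rate / f_low
        a_lo = center_frequency * sampling_rate / f_high
        return cls.geometric(
            a_lo / margin,
            a_hi * margin,
            n_scales,
            unit_scale=1.0,
            fit_range=(a_lo, a_hi),
        )

    # ------------------------------------------------------------------
    @property
    def n_scales(self) -> int:
        return self.scales.size

    @property
    def scales_physical(self) -> np.ndarray:
        """Scales in pixels (2D) or samples (1D)."""
        return self.scales * self.unit_scale

    @property
    def fit_mask(self) -> np.ndarray:
        lo, hi = self.fit_range
        return (self.scales >= lo * (1 - 1e-9)) & (self.scales <= hi * (1 + 1e-9))

    @property
    def fit_indices(self) -> np.ndarray:
        return np.flatnonzero(self.fit_mask)

    def index_of_first_fit_scale(self) -> int:
        idx = self.fit_indices
        if idx.size < 3:
            raise ValueError("fewer than 3 scales inside fit_range")
        return int(idx[0])

    def to_mm(self, pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM) -> np.ndarray:
        return self.scales_physical * pixel_size_mm

    def to_hz(self, sampling_rate: float, center_frequency: float) -> np.ndarray:
        return center_frequency * sampling_rate / self.scales
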