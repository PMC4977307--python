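"""Analyzing-wavelet kernels in the Fourier domain.

Two families are used:

* 2D: first-order partial derivatives of the isotropic Gaussian smoother
  ``phi(x, y) = exp(-(x^2 + y^2)/2)``, i.e. ``psi_1 = d(phi)/dx`` and
  ``psi_2 = d(phi)/dy``.  Convolving an image with the dilated pair
  yields the (scale-normalised) gradient of the Gaussian-smoothed image,
  exactly Canny's multiscale edge operator.

* 1D: n-th derivatives of the Gaussian, ``psi_n(t) = d^n/dt^n e^{-t^2/2}``
  (n = 2 is the Mexican hat).  The first n moments vanish, which makes
  the transform blind to polynomial trends of degree < n.

All transforms are applied spectrally: the dilated kernels have exact
closed-form Fourier transforms, so no truncation error beyond the mirror
padding of the data itself.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gauss_center_frequency",
    "gradient_multipliers_2d",
    "derivative_multiplier_1d",
]


def gauss_center_frequency(order: int) -> float:
    """Spectral-peak frequency (cycles/sample at a = 1) of the order-n
    Gaussian derivative: |psi_hat(w)| ~ |w|^n e^{-w^2/2} peaks at
    w = sqrt(n)."""
    if order < 1:
        raise ValueError("order must be >= 1")
    return float(np.sqrt(order) / (2.0 * np.pi))


def gradient_multipliers_2d(
    shape: tuple[int, int], a_pixels: float
) -> tuple[np.ndarray, np.ndarray]:
    """rfft2 multipliers producing the two WT components at scale ``a``.

    Multiplying ``rfft2(I)`` by the returned arrays and inverting gives
    ``W_1 = I * (1/a^2) psi_1(./a)`` and ``W_2`` (convolutions), with
    ``psi_hat_i(k) = i k_i * 2 pi exp(-|k|^2 / 2)`` so the dilated
    multiplier is ``i a k_i * 2 pi exp(-a^2 |k|^2 / 2)``.

    Axis convention: rows are y, columns are x; ``W_1`` is the x
    (column) component.
    """
    ny, nx = shape
    ky = 2.0 * np.pi * np.fft.fftfreq(ny)[:, None]
    kx = 2.0 * np.pi * np.fft.rfftfreq(nx)[None, :]
    envelope = 2.0 * np.pi * np.exp(-0.5 * a_pixels**2 * (kx**2 + ky**2))
    m1 = 1j * a_pixels * kx * envelope
    m2 = 1j * a_pixels * ky * envelope
    return m1, m2


def derivative_multiplier_1d(n: int, a_samples: float, order: int) -> np.ndarray:
    """rfft multiplier for the 1D WT (Eq. of the CWT with 1/a
    normalisation) at scale ``a`` with the order-``order`` Gaussian
    derivative.

    The correlation ``W(t0) = (1/a) sum_t S(t) psi((t - t0)/a)`` is
    computed as ``irfft(rfft(S) * conj(psi_hat(a w)))``.
    """
    w = 2.0 * np.pi * np.fft.rfftfreq(n)
    aw = a_samples * w
    psi_hat = (1j * aw) ** order * np.sqrt(2.0 * np.pi) * np.exp(-0.5 * aw**2)
    return np.conj(psi_hat)
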