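"""1D WTMM: cumulative integration, CWT, skeleton, tile averaging and
the mono/multifractal diagnosis rule."""

import numpy as np
import pytest

from mfscreen.scales import ScaleGrid
from mfscreen.simulate import simulate_fbm_1d
from mfscreen.spectra import ScalingSpectra
from mfscreen.wavelets import gauss_center_frequency
from mfscreen.wtmm1d import (
    WTMM1D,
    CumulativeSignal,
    Signal1D,
    TileAnalysisError,
    averaged_partition_functions,
    cumulative_integrate,
    cwt1d,
    diagnose_dynamics,
    skeleton_1d,
)


def _grid(n=8192, fs=50.0):
    return ScaleGrid.from_frequency_window(fs, 0.3, 4.0)


class TestCumulative:
    def test_zero_series_stays_zero(self):
        out = cumulative_integrate(Signal1D(np.zeros(4096)))
        assert np.all(out.samples == 0)

    def test_unit_impulse_becomes_step(self):
        x = np.zeros(4096)
        x[100] = 1.0
        out = cumulative_integrate(Signal1D(x))
        # mean-removed running sum: ramp down, jump at k, ramp down
        d = np.diff(out.samples)
        assert d[99] == pytest.approx(1.0 - 1.0 / 4096)
        assert np.allclose(np.delete(d, 99), -1.0 / 4096)

    def test_differencing_recovers_source(self, rng):
        x = rng.standard_normal(4096)
        out = cumulative_integrate(Signal1D(x))
        rec = np.diff(np.concatenate([[0.0], out.samples]))
        assert np.allclose(rec, x - x.mean(), atol=1e-12)


class TestCwt:
    def test_quadratic_trend_is_invisible_to_three_vanishing_moments(self):
        n = 8192
        t = np.arange(n, dtype=float)
        sig = CumulativeSignal(0.001 * t**2 - 0.3 * t + 7, 50.0)
        grid = _grid()
        cw = cwt1d(sig, grid, n_vanishing=3)
        inner = cw.modulus[:, 2000:-2000]
        assert inner.max() <= 1e-8 * np.abs(sig.samples).max()

    def test_sinusoid_modulus_peaks_at_mapped_scale(self):
        n = 16384
        fs = 50.0
        f0 = 1.0
        t = np.arange(n) / fs
        sig = CumulativeSignal(np.sin(2 * np.pi * f0 * t), fs)
        grid = ScaleGrid.geometric(3.0, 60.0, 40, unit_scale=1.0, fit_range=(4.0, 50.0))
        cw = cwt1d(sig, grid, n_vanishing=3)
        prof = cw.modulus[:, n // 2]
        a_peak = grid.scales_physical[int(np.argmax(prof))]
        fc = gauss_center_frequency(3)
        assert a_peak == pytest.approx(fc * fs / f0, rel=0.1)

    def test_cusp_wtmm_scales_with_holder_exponent(self):
        """|t - t0|^0.4 cusp: the WT modulus along the maxima line at
        t0 behaves as a^0.4 (textbook Holder scaling)."""
        n = 16384
        h = 0.4
        t = np.arange(n, dtype=float)
        sig = CumulativeSignal(-np.abs(t - n / 2) ** h, 50.0)
        grid = ScaleGrid.geometric(4.0, 128.0, 16, unit_scale=1.0, fit_range=(4.0, 128.0))
        cw = cwt1d(sig, grid, n_vanishing=3)
        # the modulus maxima flanking the cusp sit at |t - t0| ~ a
        mod_at_cusp = [
            cw.modulus[i, n // 2 - int(2 * a) : n // 2 + int(2 * a)].max()
            for i, a in enumerate(grid.scales)
        ]
        slope = np.polyfit(np.log(grid.scales), np.log(mod_at_cusp), 1)[0]
        assert slope == pytest.approx(h, abs=0.05)

    def test_overlarge_scale_rejected(self):
        sig = CumulativeSignal(np.zeros(4096), 50.0)
        grid = ScaleGrid.geometric(10.0, 1000.0, 10, unit_scale=1.0, fit_range=(10.0, 1000.0))
        with pytest.raises(ValueError, match="exceeds n/8"):
            cwt1d(sig, grid)


class TestSkeleton1D:
    def test_single_cusp_dominant_line_roots_at_cusp(self):
        n = 8192
        t = np.arange(n, dtype=float)
        sig = CumulativeSignal(-np.abs(t - 3000.0) ** 0.5, 50.0)
        grid = ScaleGrid.geometric(4.0, 64.0, 12, unit_scale=1.0, fit_range=(4.0, 64.0))
        sk = skeleton_1d(cwt1d(sig, grid))
        imax = int(np.nanargmax(np.nan_to_num(sk.modulus[:, -1], nan=-1)))
        line = sk.line(imax)
        assert abs(line.root_position[0] - 3000.0) <= 4.0

    def test_two_distant_cusps_give_two_lines(self):
        n = 8192
        t = np.arange(n, dtype=float)
        sig = CumulativeSignal(
            -np.abs(t - 2000.0) ** 0.5 - np.abs(t - 6000.0) ** 0.5, 50.0
        )
        grid = ScaleGrid.geometric(4.0, 64.0, 12, unit_scale=1.0, fit_range=(4.0, 64.0))
        sk = skeleton_1d(cwt1d(sig, grid))
        coarse = [sk.line(i) for i in range(sk.n_lines) if sk.death[i] == sk.grid.n_scales - 1]
        # the two dominant surviving lines flank the two cusps
        top2 = sorted(coarse, key=lambda l: -l.moduli[-1])[:2]
        roots = sorted(line.root_position[0] for line in top2)
        assert abs(roots[0] - 2000) <= 2 * grid.scales[0] + 2
        assert abs(roots[1] - 6000) <= 2 * grid.scales[0] + 2

    def test_fbm_maxima_density_decreases_with_scale(self):
        sig = cumulative_integrate(simulate_fbm_1d(16384, 1.0 / 3.0, seed=3))
        grid = ScaleGrid.geometric(4.0, 64.0, 12, unit_scale=1.0, fit_range=(4.0, 64.0))
        cw = cwt1d(sig, grid)
        sk = skeleton_1d(cw)
        counts = [sk.count_crossing(j) for j in range(grid.n_scales)]
        slope = np.polyfit(np.log(grid.scales), np.log(counts), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.25)


class TestAveraging:
    def test_identical_copies_equal_single_series(self):
        sig = cumulative_integrate(simulate_fbm_1d(8192, 0.5, seed=9))
        grid = _grid()
        pf1, n1, e1 = averaged_partition_functions([sig], grid)
        pf64, n64, e64 = averaged_partition_functions([sig] * 8, grid)
        assert (n64, e64) == (8, 0)
        assert np.allclose(pf1.log_z, pf64.log_z, atol=1e-10, equal_nan=True)
        assert np.allclose(pf1.h_pf, pf64.h_pf, atol=1e-10, equal_nan=True)

    def test_failing_series_excluded_and_tile_fails_above_limit(self):
        good = cumulative_integrate(simulate_fbm_1d(8192, 0.5, seed=9))
        flat = CumulativeSignal(np.zeros(8192), 50.0)
        grid = _grid()
        pf, used, excl = averaged_partition_functions([good] * 6 + [flat] * 2, grid)
        assert (used, excl) == (6, 2)
        with pytest.raises(TileAnalysisError):
            averaged_partition_functions([good] + [flat] * 17, grid, max_excluded=16)


class TestDiagnosis:
    @staticmethod
    def _spectra(c2, ok=True):
        nq = 5
        nan = np.full(nq, np.nan)
        return ScalingSpectra(
            q_grid=np.linspace(-1, 3, nq), tau=nan, tau_se=nan, h_q=nan, d_q=nan,
            c0=1.0, c1=0.5, c2=c2, c2_raw=c2, hurst=0.5, hurst_se=0.01,
            hurst_residual=0.0, quality_r2={0.0: 1.0, 1.0: 1.0, 2.0: 1.0},
            scaling_ok=ok, support_dim=1, fit_range=(3.0, 46.0),
        )

    def test_monofractal_below_threshold(self):
        assert diagnose_dynamics(self._spectra(0.029)).label == "monofractal"

    def test_boundary_value_is_multifractal(self):
        assert diagnose_dynamics(self._spectra(0.030)).label == "multifractal"

    def test_no_scaling_flag_dominates(self):
        assert diagnose_dynamics(self._spectra(0.001, ok=False)).label == "no_scaling"

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            WTMM1D(np.zeros((2, 1024)))
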