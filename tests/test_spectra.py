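"""Scaling-spectra fitting: exact power laws, Hurst estimation,
Legendre consistency, monofractal pdf collapse."""

import numpy as np
import pytest

from mfscreen.partition import (
    PartitionFunctionSet,
    boltzmann_weights,
    compute_partition_functions,
    default_q_grid,
)
from mfscreen.scales import ScaleGrid
from mfscreen.simulate import simulate_fbm_surface
from mfscreen.spectra import (
    NoScalingError,
    estimate_hurst,
    fit_scaling,
    modulus_collapse_ks,
)
from mfscreen.wtmm2d import WTMM2D


def synthetic_pf(tau_fn, grid=None, q_grid=None):
    """PartitionFunctionSet realising exact power laws Z(q,a) = a^tau(q)
    (h and D filled consistently for a monofractal with h = tau'(q))."""
    grid = grid or ScaleGrid.geometric(2.0, 8.0, 10, unit_scale=1.0, fit_range=(2.0, 8.0))
    q = default_q_grid() if q_grid is None else q_grid
    a = grid.scales
    tau = np.array([tau_fn(qq) for qq in q])
    dq = 1e-6
    hq = np.array([(tau_fn(qq + dq) - tau_fn(qq - dq)) / (2 * dq) for qq in q])
    log_z = tau[:, None] * np.log(a)[None, :]
    h_pf = hq[:, None] * np.log(a)[None, :]
    d_pf = q[:, None] * h_pf - log_z
    return PartitionFunctionSet(
        grid=grid, q_grid=q, scale_indices=np.arange(a.size),
        log_z=log_z, h_pf=h_pf, d_pf=d_pf, counts=np.ones(a.size, dtype=int),
    )


class TestFitScaling:
    def test_exact_power_law_recovered_to_machine_precision(self):
        pf = synthetic_pf(lambda q: 0.5 * q - 2.0)
        res = fit_scaling(pf, support_dim=2)
        assert np.allclose(res.tau, 0.5 * res.q_grid - 2.0, atol=1e-10)
        assert res.c2 == pytest.approx(0.0, abs=1e-8)
        assert res.hurst == pytest.approx(0.5, abs=1e-9)
        assert res.scaling_ok

    def test_lognormal_curvature_recovered(self):
        c0, c1, c2 = 1.0, 0.55, 0.06
        pf = synthetic_pf(lambda q: -c0 + c1 * q - c2 * q**2 / 2)
        res = fit_scaling(pf, support_dim=1, lognormal_q_range=(-2.0, 5.0))
        assert res.c0 == pytest.approx(c0, abs=1e-6)
        assert res.c1 == pytest.approx(c1, abs=1e-6)
        assert res.c2 == pytest.approx(c2, abs=1e-6)

    def test_too_few_scales_rejected(self):
        grid = ScaleGrid(np.array([2.0, 4.0]), unit_scale=1.0, fit_range=(2.0, 4.0))
        pf = synthetic_pf(lambda q: q - 2, grid=grid)
        with pytest.raises(ValueError, match="3 scales"):
            fit_scaling(pf)


class TestHurst:
    def test_exact_linear_tau_gives_h_and_zero_residual(self):
        pf = synthetic_pf(lambda q: 0.6 * q - 2.0)
        res = fit_scaling(pf, support_dim=2)
        est = estimate_hurst(res)
        assert est.value == pytest.approx(0.6, abs=1e-9)
        assert est.residual == pytest.approx(0.0, abs=1e-8)

    def test_no_scaling_refused(self):
        pf = synthetic_pf(lambda q: 0.6 * q - 2.0)
        res = fit_scaling(pf, support_dim=2)
        res.scaling_ok = False
        with pytest.raises(NoScalingError):
            estimate_hurst(res)


class TestPartitionInvariants:
    def test_boltzmann_weights_sum_to_one(self, rng):
        m = rng.lognormal(size=200)
        for q in (-2.0, -0.5, 0.0, 1.0, 3.0, 5.0):
            assert boltzmann_weights(m, q).sum() == pytest.approx(1.0, abs=1e-10)

    def test_z_at_q_zero_counts_lines_and_weights_normalise(self):
        img = simulate_fbm_surface(256, 0.5, seed=21)
        grid = ScaleGrid.geometric(1.0, 5.0, 10, unit_scale=7.0, fit_range=(2.0, 5.0))
        model = WTMM2D(img, grid=grid)
        pf = compute_partition_functions(model.build_skeleton(), model.q_grid)
        i0 = int(np.argmin(np.abs(pf.q_grid)))
        assert np.allclose(np.exp(pf.log_z[i0]), pf.counts, rtol=1e-9)
        for jj, m in enumerate(pf.line_moduli):
            if m.size:
                assert boltzmann_weights(m, 2.0).sum() == pytest.approx(1.0, abs=1e-10)

    def test_legendre_consistency_on_fbm(self):
        img = simulate_fbm_surface(512, 0.5, seed=8)
        res = WTMM2D(img).fit(margin=64)
        assert res.legendre_residual((-1.0, 3.0)) <= 0.05

    def test_monofractal_pdf_collapse(self):
        """Rescaled raw WTMM modulus distributions at two fit-range
        scales collapse for a monofractal surface (small KS distance;
        maxima pooled over seeds for statistical power)."""
        grid = ScaleGrid.geometric(2.0, 4.2, 6, unit_scale=7.0, fit_range=(2.0, 4.0))
        pool_i, pool_j = [], []
        for seed in range(10):
            img = simulate_fbm_surface(1024, 0.5, seed=40 + seed)
            model = WTMM2D(img, grid=grid)
            pts = model.wtmmm_by_scale()
            for pool, k in ((pool_i, 0), (pool_j, 2)):
                p, mo = pts[k]
                inner = (
                    (p[:, 0] >= 50) & (p[:, 0] < 974)
                    & (p[:, 1] >= 50) & (p[:, 1] < 974)
                )
                pool.append(mo[inner])
        ks = modulus_collapse_ks(
            np.concatenate(pool_i), grid.scales[0],
            np.concatenate(pool_j), grid.scales[2], hurst=0.5,
        )
        assert ks <= 0.05


def test_plot_returns_axes():
    import matplotlib
    matplotlib.use("Agg")
    pf = synthetic_pf(lambda q: 0.5 * q - 2.0)
    res = fit_scaling(pf, support_dim=2)
    ax1, ax2 = res.plot()
    assert ax1.get_xlabel() == "q"
    assert ax2.get_ylabel() == "D(h)"
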