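"""2D gradient-wavelet transform, maxima chains, WTMMM and skeleton."""

import numpy as np
import pytest
from scipy import signal

from mfscreen.scales import ScaleGrid
from mfscreen.simulate import simulate_fbm_surface
from mfscreen.skeleton import chaining_radius
from mfscreen.wtmm2d import (
    WTMM2D,
    Image2D,
    MaximaChain,
    build_skeleton,
    extract_maxima_chains,
    gradient_wavelet_transform,
    locate_wtmmm,
)

from conftest import gaussian_bump


class TestTransform:
    def test_constant_image_has_zero_modulus(self, small_grid):
        img = Image2D(np.full((64, 64), 7.0))
        for sl in gradient_wavelet_transform(img, small_grid):
            assert np.allclose(sl.modulus, 0.0, atol=1e-10)

    def test_planar_ramp_gradient_points_along_x(self, small_grid):
        y, x = np.indices((64, 64))
        img = Image2D(x.astype(float))
        sl = gradient_wavelet_transform(img, small_grid)[0]
        interior = sl.argument[16:-16, 16:-16]
        assert np.allclose(interior, 0.0, atol=1e-6)
        assert np.all(sl.modulus[16:-16, 16:-16] > 0)

    def test_modulus_squared_identity(self, small_grid, rng):
        img = Image2D(rng.standard_normal((64, 64)))
        for sl in gradient_wavelet_transform(img, small_grid):
            assert np.allclose(sl.modulus**2, sl.w1**2 + sl.w2**2, rtol=1e-12)

    def test_gaussian_bump_matches_dense_convolution_oracle(self):
        """Spectral evaluation equals brute-force spatial convolution
        with the truncated dilated kernel (interior of a 128^2 image),
        and the ring of maxima grows with scale."""
        n = 128
        img = gaussian_bump(n, sigma=5.0)
        grid = ScaleGrid(np.array([3.0, 4.5, 6.0]), unit_scale=1.0, fit_range=(3.0, 6.0))
        slices = gradient_wavelet_transform(Image2D(img), grid)
        radii = []
        for sl, a in zip(slices, grid.scales):
            # oracle: direct spatial convolution, kernel truncated at 5a
            r = int(np.ceil(5 * a))
            yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
            # kernel (1/a^2) psi1(x/a) with psi1(u) = d(phi)/du_x = -u_x e^{-|u|^2/2}
            u2 = (xx**2 + yy**2) / a**2
            k1 = (1.0 / a**2) * (-(xx / a)) * np.exp(-u2 / 2)
            w1_oracle = signal.convolve2d(img, k1, mode="same", boundary="symm")
            inner = slice(r, n - r)
            assert np.allclose(sl.w1[inner, inner], w1_oracle[inner, inner], atol=1e-5)
            # modulus maxima lie on a circle whose radius grows with a
            c = (n - 1) / 2
            mask = sl.modulus > 0.5 * sl.modulus.max()
            ry, rx = np.nonzero(mask)
            radii.append(np.hypot(ry - c, rx - c).mean())
        assert radii[0] < radii[1] < radii[2]

    def test_too_small_image_rejected_with_minimum_size(self):
        grid = ScaleGrid.default_image()
        with pytest.raises(ValueError, match="need >="):
            gradient_wavelet_transform(Image2D(np.zeros((64, 64))), grid)

    def test_non_finite_pixels_rejected(self):
        bad = np.zeros((64, 64))
        bad[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            Image2D(bad)


class TestChains:
    def test_constant_slice_yields_no_chains(self, small_grid):
        img = Image2D(np.zeros((64, 64)))
        sl = gradient_wavelet_transform(img, small_grid)[0]
        assert extract_maxima_chains(sl) == []

    def test_vertical_step_edge_gives_open_chain_on_edge_column(self, small_grid):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        sl = gradient_wavelet_transform(Image2D(img), small_grid)[0]
        chains = extract_maxima_chains(sl)
        big = max(chains, key=len)
        assert not big.closed
        cols = big.points[:, 1]
        assert np.all(np.abs(cols - 31.5) <= 1.0)
        # argument perpendicular to the edge (gradient along +x)
        assert np.allclose(np.cos(big.arguments), 1.0, atol=0.05)

    def test_gaussian_bump_gives_closed_ring_chain(self):
        img = gaussian_bump(96, sigma=6.0)
        grid = ScaleGrid(np.array([3.0, 4.0, 5.0]), unit_scale=1.0, fit_range=(3.0, 5.0))
        sl = gradient_wavelet_transform(Image2D(img), grid)[0]
        chains = extract_maxima_chains(sl)
        ring = max(chains, key=len)
        assert ring.closed
        c = (96 - 1) / 2
        rad = np.hypot(*(ring.points - c).T)
        assert rad.std() / rad.mean() < 0.1


class TestWtmmm:
    def test_open_chain_profile_has_maxima_at_interior_peaks(self):
        pts = np.stack([np.zeros(5), np.arange(5.0)], axis=1)
        chain = MaximaChain(scale=1.0, points=pts, moduli=np.array([1.0, 3, 2, 5, 4]),
                            arguments=np.zeros(5), closed=False)
        found = locate_wtmmm(chain)
        cols = sorted(p[1] for p, _ in found)
        assert cols == [1.0, 3.0]

    def test_constant_closed_chain_keeps_single_representative(self):
        pts = np.array([[0.0, 0], [0, 1], [1, 1], [1, 0]])
        chain = MaximaChain(scale=1.0, points=pts, moduli=np.ones(4),
                            arguments=np.zeros(4), closed=True)
        found = locate_wtmmm(chain)
        assert len(found) == 1
        assert tuple(found[0][0]) == (0.0, 0.0)  # lowest (row, col)

    def test_ring_with_spike_concentrates_wtmmm_near_spike(self):
        """A localized intensity spike on a bump breaks the ring's
        symmetry; the strongest WTMMM sits at the chain point nearest
        the spike (cross-checked by exhaustive scan of chain moduli)."""
        n = 96
        img = gaussian_bump(n, sigma=8.0)
        img += 0.2 * gaussian_bump(n, sigma=2.0, center=(47.5 + 9.0, 47.5))
        grid = ScaleGrid(np.array([3.0, 4.0]), unit_scale=1.0, fit_range=(3.0, 4.0))
        sl = gradient_wavelet_transform(Image2D(img), grid)[0]
        ring = max(extract_maxima_chains(sl), key=len)
        found = locate_wtmmm(ring)
        best = max(found, key=lambda pm: pm[1])
        brute = ring.points[int(np.argmax(ring.moduli))]
        assert np.hypot(*(best[0] - brute)) <= np.sqrt(2)


class TestSkeleton:
    def test_isolated_bump_roots_at_bump_position(self):
        """Maxima lines of a near-point bump converge on the bump as
        a -> 0; the gradient-maxima ring has radius ~ sqrt(a^2 + s^2),
        so the root sits within that ring of the center."""
        n = 128
        sigma = 1.0
        grid = ScaleGrid.geometric(1.5, 8.0, 10, unit_scale=1.0, fit_range=(1.5, 8.0))
        img = gaussian_bump(n, sigma=sigma, center=(70.0, 40.0))
        model = WTMM2D(Image2D(img), grid=grid)
        sk = model.build_skeleton()
        assert sk.n_lines >= 1
        # the strongest line points to the singularity as a -> 0
        imax = int(np.nanargmax(np.nan_to_num(sk.modulus[:, 0], nan=-1)))
        root = sk.positions[imax, sk.root[imax]]
        bound = np.hypot(grid.scales[0], sigma) + 0.5
        assert np.hypot(root[0] - 70.0, root[1] - 40.0) <= bound

    def test_two_distant_bumps_give_disjoint_line_families(self):
        n = 128
        img = gaussian_bump(n, 2.0, center=(32.0, 32.0)) + gaussian_bump(n, 2.0, center=(96.0, 96.0))
        grid = ScaleGrid.geometric(2.0, 6.0, 8, unit_scale=1.0, fit_range=(2.0, 6.0))
        sk = WTMM2D(Image2D(img), grid=grid).build_skeleton()
        for line in sk:
            d1 = np.hypot(*(line.positions - [32, 32]).T).min()
            d2 = np.hypot(*(line.positions - [96, 96]).T).min()
            # a line belongs entirely to one bump: it never wanders to
            # within a chaining radius of the other one
            r = chaining_radius(grid.scales[-1], grid.unit_scale)
            assert (d1 < d2 and d2 > 3 * r) or (d2 < d1 and d1 > 3 * r)

    def test_fbm_line_count_decreases_with_scale(self):
        img = simulate_fbm_surface(256, 0.5, seed=11)
        model = WTMM2D(img, grid=ScaleGrid.geometric(1.0, 6.0, 12, unit_scale=7.0, fit_range=(2.0, 6.0)))
        sk = model.build_skeleton()
        counts = [sk.count_crossing(j) for j in range(model.grid.n_scales)]
        # monotone within noise: allow small local inversions
        assert counts[0] > counts[-1]
        drops = sum(1 for a, b in zip(counts, counts[1:]) if b <= a + 2)
        assert drops >= len(counts) - 2


class TestInvariances:
    def test_affine_intensity_invariance_is_exact(self):
        img = simulate_fbm_surface(256, 0.5, seed=5)
        grid = ScaleGrid.geometric(1.0, 5.0, 10, unit_scale=7.0, fit_range=(2.0, 5.0))
        r1 = WTMM2D(img, grid=grid).fit()
        r2 = WTMM2D(3.5 * img.pixels - 11.0, grid=grid).fit()
        assert np.allclose(r1.tau, r2.tau, atol=1e-9, equal_nan=True)
        assert r1.hurst == pytest.approx(r2.hurst, abs=1e-9)

    def test_rotation_invariance_of_hurst(self):
        img = simulate_fbm_surface(512, 0.5, seed=2)
        grid = ScaleGrid.geometric(1.0, 6.0, 14, unit_scale=7.0, fit_range=(2.0, 6.0))
        h1 = WTMM2D(img, grid=grid).fit().hurst
        h2 = WTMM2D(np.rot90(img.pixels).copy(), grid=grid).fit().hurst
        assert abs(h1 - h2) <= 0.02
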