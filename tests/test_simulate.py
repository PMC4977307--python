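"""Synthetic-data generators: determinism and independent
(variogram / moment-regression) oracles."""

import numpy as np
import pytest

from mfscreen.simulate import (
    GeneratorSpec,
    simulate_fbm_1d,
    simulate_fbm_surface,
    simulate_mammogram_phantom,
    simulate_mrw_1d,
    simulate_thermogram_phantom,
    structure_function_exponents,
    variogram_exponent,
)


class TestFbm1d:
    def test_brownian_increments_are_white(self):
        x = simulate_fbm_1d(30000, 0.5, seed=1).samples
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) <= 2 / np.sqrt(len(x))

    @pytest.mark.parametrize("H", [0.3, 0.5, 0.8])
    def test_variogram_slope_recovers_2h(self, H):
        prof = np.cumsum(simulate_fbm_1d(2**15, H, seed=2).samples)
        slope = variogram_exponent(prof, lags=np.array([1, 2, 4, 8, 16, 32, 64]))
        assert slope == pytest.approx(2 * H, abs=0.1)

    def test_seed_determinism(self):
        a = simulate_fbm_1d(4096, 0.7, seed=9).samples
        b = simulate_fbm_1d(4096, 0.7, seed=9).samples
        assert np.array_equal(a, b)

    def test_invalid_h_rejected(self):
        with pytest.raises(ValueError):
            simulate_fbm_1d(1024, 1.2, seed=0)


class TestFbmSurface:
    @pytest.mark.parametrize("H", [1 / 3, 0.5, 2 / 3])
    def test_variogram_slope_and_isotropy(self, H):
        img = simulate_fbm_surface(512, H, seed=3).pixels
        lags = np.array([1, 2, 4, 8, 16, 32])
        s_rows = variogram_exponent(img, lags=lags, axis=0)
        s_cols = variogram_exponent(img, lags=lags, axis=1)
        assert abs(s_rows / 2 - H) <= 0.05
        assert abs(s_rows - s_cols) / 2 <= 0.05

    def test_seed_determinism_and_power_of_two(self):
        a = simulate_fbm_surface(128, 0.4, seed=5).pixels
        b = simulate_fbm_surface(128, 0.4, seed=5).pixels
        assert np.array_equal(a, b)
        with pytest.raises(ValueError, match="power of 2"):
            simulate_fbm_surface(100, 0.4, seed=5)


class TestMrw:
    def test_small_c2_limit_matches_fgn_variance(self):
        """As c2 -> 0 the MRW degenerates to fGn: marginal variances
        agree within 2% (averaged over seeds to beat realization
        noise)."""
        v_mrw = np.mean([
            simulate_mrw_1d(2**16, c1=0.501, c2=0.001, seed=s).samples.var()
            for s in range(4)
        ])
        v_fgn = np.mean([
            simulate_fbm_1d(2**16, 0.5, seed=100 + s).samples.var()
            for s in range(4)
        ])
        assert v_mrw == pytest.approx(v_fgn, rel=0.02)

    def test_magnitude_covariance_decays_logarithmically(self):
        """Cov(ln|dx(t)|, ln|dx(t+tau)|) ~ c2 ln(L/tau) by
        construction; the fitted log-slope recovers -c2."""
        c2, n = 0.08, 2**16
        L = n / 8
        x = simulate_mrw_1d(n, c1=0.55, c2=c2, L=L, seed=6).samples
        lm = np.log(np.abs(x) + 1e-12)
        lm -= lm.mean()
        taus = np.array([4, 8, 16, 32, 64, 128, 256, 512])
        cov = [np.mean(lm[:-t] * lm[t:]) for t in taus]
        slope = np.polyfit(np.log(taus), cov, 1)[0]
        assert slope == pytest.approx(-c2, abs=0.03)

    def test_structure_function_exponents_match_lognormal_shape(self):
        """Direct moment-regression zeta(q) (no wavelets) matches
        zeta(q) = c1 q - c2 q^2/2 within 0.05 for q in [0, 3]."""
        c1, c2 = 0.55, 0.05
        q = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        zs = [structure_function_exponents(
            simulate_mrw_1d(2**16, c1, c2, seed=70 + s).samples, q) for s in range(4)]
        zeta = np.mean(zs, axis=0)
        expect = c1 * q - c2 * q**2 / 2
        assert np.all(np.abs(zeta - expect) <= 0.05)


class TestPhantoms:
    def test_thermo_phantom_background_constant_and_deterministic(self):
        region = np.array([[0, 1], [2, 1]])
        s1, p1 = simulate_thermogram_phantom((2, 2), region, seed=5, n_frames=4096)
        s2, _ = simulate_thermogram_phantom((2, 2), region, seed=5, n_frames=4096)
        assert np.array_equal(s1, s2)
        assert np.ptp(s1[:, 0, 0]) == 0.0       # background pixel constant
        assert np.ptp(s1[:, 0, 1]) > 0.0
        assert p1["c2_healthy"] == 0.05

    def test_mammo_phantom_truth_map_marks_lesion_cores(self):
        img, truth = simulate_mammogram_phantom(
            size=1024, H_bg=1 / 3, lesion_rect=(256, 768, 256, 768),
            H_lesion=0.5, seed=7)
        assert truth.shape == (4, 4)
        assert truth[1, 1] == "yellow" and truth[2, 2] == "yellow"
        assert truth[0, 0] == "blue" and truth[3, 3] == "blue"
        img2, _ = simulate_mammogram_phantom(
            size=1024, H_bg=1 / 3, lesion_rect=(256, 768, 256, 768),
            H_lesion=0.5, seed=7)
        assert np.array_equal(img.pixels, img2.pixels)

    def test_lesion_region_variance_matched(self):
        img, _ = simulate_mammogram_phantom(
            size=1024, H_bg=1 / 3, lesion_rect=(256, 768, 256, 768),
            H_lesion=0.5, seed=8)
        inner = img.pixels[300:700, 300:700]
        outer = img.pixels[:200, :200]
        assert 0.3 <= inner.std() / outer.std() <= 3.0

    def test_generator_spec_roundtrip(self):
        spec = GeneratorSpec(kind="fbm1d", seed=3, params={"n": 2048, "H": 0.6})
        sig = spec.generate()
        assert len(sig) == 2048
        d = spec.to_dict()
        assert d["kind"] == "fbm1d" and d["params"]["H"] == 0.6
        with pytest.raises(ValueError):
            GeneratorSpec(kind="nope").generate()
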