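"""Parametric estimators vs. closed forms and numeric-likelihood oracles."""

import numpy as np
import pytest
from scipy import optimize, stats

from hifumap import (AcquisitionMeta, EnvelopeSequence, ValidationError,
                     WindowSpec, goodness_of_fit, grayscale_map, ibs_map,
                     lognormal_mle, lognormal_sigma_map, rayleigh_alpha_map,
                     rayleigh_alpha_mle)


def env_of(frames, **meta_kw):
    kw = dict(frame_rate_hz=11.0, time_origin_s=4.0, ablation_window_s=(4.5, 8.5))
    kw.update(meta_kw)
    return EnvelopeSequence(frames=np.asarray(frames, dtype=float),
                            meta=AcquisitionMeta(**kw))


# ---------------------------------------------------------------------------
# independent numeric likelihood-maximization oracles


def numeric_rayleigh_mle(x):
    nll = lambda a: -np.sum(stats.rayleigh.logpdf(x, scale=a))
    res = optimize.minimize_scalar(nll, bounds=(1e-6, 10 * x.max()), method="bounded",
                                   options={"xatol": 1e-12})
    return res.x


def numeric_lognormal_mle(x):
    def nll(p):
        mu, s = p
        if s <= 0:
            return np.inf
        return -np.sum(stats.lognorm.logpdf(x, s=s, scale=np.exp(mu)))
    res = optimize.minimize(nll, x0=[0.0, 1.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    return res.x


class TestClosedForms:
    def test_alpha_constant_window(self):
        assert rayleigh_alpha_mle(np.full(10, 3.0)) == pytest.approx(3.0 / np.sqrt(2))

    def test_alpha_hand_arithmetic(self):
        # Σ A² = 6, N = 4 → α̂ = sqrt(6/8)
        x = np.array([1.0, 1.0, np.sqrt(2), np.sqrt(2)])
        assert rayleigh_alpha_mle(x) == pytest.approx(np.sqrt(6 / 8), abs=1e-12)
        assert rayleigh_alpha_mle(x) == pytest.approx(numeric_rayleigh_mle(x), abs=1e-9)

    def test_sigma_constant_window_is_zero(self):
        _, s = lognormal_mle(np.full(10, 5.0))
        assert s == 0.0

    def test_sigma_hand_arithmetic(self):
        mu, s = lognormal_mle(np.array([1.0, np.e**2]))
        assert mu == pytest.approx(1.0, abs=1e-12)
        assert s == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("dist,n,tol", [("rayleigh", 100_000, 0.01),
                                            ("lognormal", 100_000, 0.01)])
    def test_monte_carlo_consistency(self, dist, n, tol):
        rng = np.random.default_rng(42)
        if dist == "rayleigh":
            x = rng.rayleigh(scale=1.0, size=n)
            assert abs(rayleigh_alpha_mle(x) - 1.0) < tol
        else:
            x = np.exp(0.5 * rng.standard_normal(n))
            _, s = lognormal_mle(x)
            assert abs(s - 0.5) < tol

    def test_agrees_with_numeric_oracle_on_random_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.rayleigh(scale=rng.uniform(0.5, 2.0), size=64)
            assert rayleigh_alpha_mle(x) == pytest.approx(numeric_rayleigh_mle(x), abs=1e-6)
            mu, s = lognormal_mle(x)
            mu_o, s_o = numeric_lognormal_mle(x)
            assert mu == pytest.approx(mu_o, abs=1e-6)
            assert s == pytest.approx(s_o, abs=1e-6)


class TestMaps:
    def test_gs_reference_identity_and_decade(self):
        env = env_of(np.full((2, 6, 6), 4.0))
        gs = grayscale_map(env, ref=4.0)
        np.testing.assert_allclose(gs.frames, 0.0, atol=1e-12)
        gs = grayscale_map(env, ref=40.0)
        np.testing.assert_allclose(gs.frames, -20.0, atol=1e-12)

    def test_gs_differences_scale_invariant(self):
        rng = np.random.default_rng(1)
        a = rng.random((3, 8, 8)) + 0.1
        g1 = grayscale_map(env_of(a)).frames
        g2 = grayscale_map(env_of(2 * a)).frames
        d1 = g1 - g1[:, :1, :1]
        d2 = g2 - g2[:, :1, :1]
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_gs_zero_maps_to_floor(self):
        a = np.full((1, 4, 4), 2.0)
        a[0, 0, 0] = 0.0
        gs = grayscale_map(env_of(a), ref=2.0)
        assert gs.frames[0, 0, 0] == -60.0

    def test_all_zero_sequence_errors(self):
        with pytest.raises(ValidationError):
            grayscale_map(env_of(np.zeros((2, 4, 4))))

    def test_ibs_constant_zero_db(self):
        env = env_of(np.full((1, 10, 10), 3.0))
        ibs = ibs_map(env, WindowSpec(5, 3), ref=3.0)
        np.testing.assert_allclose(ibs.frames, 0.0, atol=1e-10)

    def test_ibs_1x1_window_equals_gs(self):
        rng = np.random.default_rng(2)
        a = rng.random((2, 6, 6)) + 0.1
        env = env_of(a)
        ibs = ibs_map(env, WindowSpec(1, 1), ref=1.0).frames
        gs = grayscale_map(env, ref=1.0).frames
        np.testing.assert_allclose(ibs, gs, atol=1e-9)

    def test_ibs_rayleigh_expectation(self):
        # E[A²] = 2α² for Rayleigh; Monte-Carlo vs windowed estimate
        rng = np.random.default_rng(3)
        a = rng.rayleigh(scale=1.0, size=(1, 200, 200))
        ibs = ibs_map(env_of(a), WindowSpec(41, 41), ref=1.0).frames
        center = ibs[0, 100, 100]
        assert abs(center - 10 * np.log10(2.0)) < 0.2

    def test_alpha_map_constant_window(self):
        env = env_of(np.full((1, 8, 8), 2.0))
        am = rayleigh_alpha_map(env, WindowSpec(3, 3))
        np.testing.assert_allclose(am.frames, 2.0 / np.sqrt(2), atol=1e-12)

    def test_alpha_scale_equivariance(self):
        rng = np.random.default_rng(4)
        a = rng.rayleigh(1.0, size=(2, 12, 12))
        m1 = rayleigh_alpha_map(env_of(a), WindowSpec(5, 5)).frames
        m2 = rayleigh_alpha_map(env_of(3.0 * a), WindowSpec(5, 5)).frames
        np.testing.assert_allclose(m2, 3.0 * m1, rtol=1e-10)

    def test_sigma_scale_invariance(self):
        rng = np.random.default_rng(5)
        a = np.exp(0.4 * rng.standard_normal((2, 12, 12)))
        m1 = lognormal_sigma_map(env_of(a), WindowSpec(5, 5)).frames
        m2 = lognormal_sigma_map(env_of(7.0 * a), WindowSpec(5, 5)).frames
        np.testing.assert_allclose(m2, m1, atol=1e-10)

    def test_map_shapes_and_alignment_shared(self, speckle_phantom):
        _, env, _ = speckle_phantom
        w = WindowSpec(15, 7)
        shapes = {grayscale_map(env).frames.shape,
                  ibs_map(env, w).frames.shape,
                  rayleigh_alpha_map(env, w).frames.shape,
                  lognormal_sigma_map(env, w).frames.shape}
        assert shapes == {env.frames.shape}

    def test_window_must_fit(self):
        with pytest.raises(ValidationError):
            rayleigh_alpha_map(env_of(np.ones((1, 8, 8))), WindowSpec(100, 13))

    def test_windowed_estimates_match_direct_mle_at_interior(self):
        rng = np.random.default_rng(6)
        a = rng.rayleigh(1.0, size=(1, 20, 20))
        w = WindowSpec(5, 5)
        am = rayleigh_alpha_map(env_of(a), w).frames[0]
        sm = lognormal_sigma_map(env_of(a), w).frames[0]
        patch = a[0, 8:13, 8:13]
        assert am[10, 10] == pytest.approx(rayleigh_alpha_mle(patch), abs=1e-12)
        assert sm[10, 10] == pytest.approx(lognormal_mle(patch)[1], abs=1e-12)


class TestGoodnessOfFit:
    def test_matched_model_fits_well(self):
        rng = np.random.default_rng(7)
        ok = 0
        for s in range(20):
            x = np.random.default_rng(s).rayleigh(1.0, size=10_000)
            rep = goodness_of_fit(x, "rayleigh")
            ok += rep["r2_adj"] >= 0.98
            assert rep["dof"] == 43
        assert ok == 20

    def test_constant_data_degenerate(self):
        with pytest.raises(ValidationError):
            goodness_of_fit(np.full(200, 1.0), "rayleigh")

    def test_model_mismatch_lowers_fit(self):
        wins = 0
        for s in range(20):
            x = np.random.default_rng(100 + s).rayleigh(1.0, size=5_000)
            r_ray = goodness_of_fit(x, "rayleigh")["r2_adj"]
            r_log = goodness_of_fit(x, "lognormal")["r2_adj"]
            wins += r_ray > r_log
        assert wins >= 18
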