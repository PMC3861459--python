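"""EP feature extraction against generative truth and closed forms."""

import numpy as np
import pytest

from hifumap import (AcquisitionMeta, OpticalMovie, ValidationError,
                     bandpass_traces, conduction_velocity, correct_drift,
                     extract_features, preprocess, simulate_ap_movie,
                     spatial_bin)
from hifumap.synthetic import ap_template

from conftest import small_ap_config


def movie_of(frames, fs=1000.0, cl=1000.0, spacing=(250.0, 250.0)):
    return OpticalMovie(frames=np.asarray(frames, dtype=float),
                        meta=AcquisitionMeta(frame_rate_hz=fs,
                                             pixel_spacing_um=spacing,
                                             ablation_window_s=(4.5, 8.5)),
                        pacing_cycle_ms=cl)


class TestPreprocess:
    def test_dc_removed_by_bandpass(self):
        tr = np.full((4000, 1), 5.0)
        out = bandpass_traces(tr, 1000.0, (1.0, 100.0))
        assert np.max(np.abs(out[500:-500])) < 0.05  # < 1% of the DC level

    def test_passband_gain_unity_at_10hz(self):
        t = np.arange(8000) / 1000.0
        tr = np.sin(2 * np.pi * 10 * t)[:, None]
        out = bandpass_traces(tr, 1000.0, (1.0, 100.0))[:, 0]
        gain = out[2000:6000].std() / tr[2000:6000, 0].std()
        assert abs(gain - 1.0) < 0.01

    def test_spatial_binning_flattens_checkerboard(self):
        frame = np.indices((10, 10)).sum(axis=0) % 2
        out = spatial_bin(frame[None].astype(float), 3)[0]
        interior = out[1:-1, 1:-1]
        assert np.ptp(interior) <= 1 / 9 + 1e-12  # pattern attenuated 9x

    def test_low_frame_rate_rejected(self):
        mv = movie_of(np.ones((500, 4, 4)), fs=150.0)
        with pytest.raises(ValidationError):
            preprocess(mv)

    def test_short_movie_rejected(self):
        mv = movie_of(np.ones((100, 4, 4)))
        with pytest.raises(ValidationError):
            preprocess(mv)


class TestDriftCorrection:
    def test_linear_drift_exactly_removed(self):
        t = np.arange(5000) / 1000.0
        tr = 0.2 * t  # pure drift on a flat trace
        out = correct_drift(tr, 1000.0, 1000.0, model="linear")
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_zero_drift_input_unchanged(self):
        rng = np.random.default_rng(0)
        tr = 0.001 * rng.standard_normal(5000)
        out = correct_drift(tr, 1000.0, 1000.0, model="linear")
        np.testing.assert_allclose(out, tr - tr.mean(), atol=5e-4)

    def test_photobleach_on_ap_train_corrected(self):
        # exponential bleach under a paced train: residual diastolic drift
        # after auto-model correction < 2% of the AP amplitude
        cfg = small_ap_config(noise_sd=0.0, drift_linear_per_s=-0.01,
                              drift_exp_amp=0.05, drift_exp_tau_s=4.0,
                              lesion_semiaxes=(0.0, 0.0))
        movie, _, _ = simulate_ap_movie(cfg, seed=0)
        tr = movie.frames[:, 10, 10]
        df = tr / tr.mean() - 1.0
        out = correct_drift(df, 1000.0, 1000.0, model="auto")
        dia = np.array([np.median(out[i * 1000 + 900: (i + 1) * 1000])
                        for i in range(12)])
        apa = 0.05
        assert np.ptp(dia) < 0.02 * apa

    def test_too_few_baseline_samples_rejected(self):
        with pytest.raises(ValidationError):
            correct_drift(np.ones(50), 1000.0, 1000.0, model="poly")


class TestFeatureRecovery:
    def test_noiseless_recovery_is_exact(self, clean_ap_movie):
        cfg, movie, truth, mask = clean_ap_movie
        f = extract_features(movie, band_hz=None, spatial=1, drift_model=None)
        dt = 1000.0 / cfg.frame_rate_hz
        act_err = np.abs(f.baseline_mean("activation_ms") - truth["activation_ms"])
        assert np.nanmax(act_err) <= dt  # within one frame period
        for k in ("apd50_ms", "apd80_ms"):
            assert np.nanmax(np.abs(f.baseline_mean(k) - truth[k])) < 0.5
        np.testing.assert_allclose(f.final("dapa")[mask.mask],
                                   truth["dapa_final"][mask.mask], atol=0.02)
        np.testing.assert_allclose(f.final("dapa")[~mask.mask], 0.0, atol=0.02)

    def test_activation_shift_equivariance(self):
        # identical traces shifted by k frames → activation differs by k
        t = np.arange(1000.0)
        v = ap_template(t - 100.0, 8.0, 160.0, 200.0)
        k = 17
        frames = np.zeros((1000, 2, 1))
        frames[:, 0, 0] = 1.0 + 0.05 * v
        frames[:, 1, 0] = 1.0 + 0.05 * np.roll(v, k)
        f = extract_features(movie_of(frames), band_hz=None, spatial=1,
                             drift_model=None, baseline_window_s=(0.0, 1.0))
        d = f.activation_ms[0, 1, 0] - f.activation_ms[0, 0, 0]
        assert d == pytest.approx(k, abs=1e-6)

    def test_apd_closed_form_crossing(self):
        # exponential repolarization: crossing times follow the template's
        # closed form (APD50/80 are the configured values by construction)
        t = np.arange(2000.0)
        v = ap_template(np.mod(t, 1000.0) - 30.0, 8.0, 137.0, 181.0)
        frames = (1.0 + 0.05 * v)[:, None, None]
        f = extract_features(movie_of(frames), band_hz=None, spatial=1,
                             drift_model=None, baseline_window_s=(0.0, 2.0))
        assert f.apd50_ms[0, 0, 0] == pytest.approx(137.0, abs=0.5)
        assert f.apd80_ms[0, 0, 0] == pytest.approx(181.0, abs=0.5)

    def test_apd80_not_less_than_apd50_everywhere(self, noisy_ap_movie):
        _, movie, _, _ = noisy_ap_movie
        f = extract_features(movie)
        ok = np.isfinite(f.apd50_ms) & np.isfinite(f.apd80_ms)
        assert np.all(f.apd80_ms[ok] >= f.apd50_ms[ok])
        tri = f.tri_ratio[ok]
        assert np.nanmax(tri) <= 1.0 + 1e-12

    def test_gain_invariance(self, clean_ap_movie):
        _, movie, _, _ = clean_ap_movie
        kw = dict(band_hz=None, spatial=1, drift_model=None)
        f1 = extract_features(movie, **kw)
        f2 = extract_features(movie.copy_with(3.7 * movie.frames), **kw)
        np.testing.assert_allclose(f1.apa, f2.apa, atol=1e-9)
        np.testing.assert_allclose(f1.apd50_ms, f2.apd50_ms, atol=1e-6)

    def test_lesion_apd_shortening_recovered(self, clean_ap_movie):
        cfg, movie, truth, mask = clean_ap_movie
        f = extract_features(movie, band_hz=None, spatial=1, drift_model=None)
        rel = (f.final("apd50_ms") - f.baseline_mean("apd50_ms")) \
            / f.baseline_mean("apd50_ms")
        # APD50 scale 0.67 → −33% shortening inside the lesion
        assert np.nanmedian(rel[mask.mask]) == pytest.approx(-0.33, abs=0.03)
        assert np.nanmedian(np.abs(rel[~mask.mask])) < 0.01

    def test_triangulation_decreases_in_lesion(self, clean_ap_movie):
        cfg, movie, truth, mask = clean_ap_movie
        f = extract_features(movie, band_hz=None, spatial=1, drift_model=None)
        tri_pre = f.baseline_mean("tri_ratio")
        tri_post = f.final("tri_ratio")
        assert np.nanmedian(tri_pre) == pytest.approx(0.8, abs=0.01)
        assert np.nanmedian(tri_post[mask.mask]) < np.nanmedian(tri_pre[mask.mask]) - 0.05

    def test_upstroke_linear_ramp_slope(self):
        # linear upstroke of slope s → measured [dΔF/dt]max = s within 2%
        s = 0.004  # ΔF per ms
        t = np.arange(1000.0)
        v = np.clip((t - 100.0) * s / 0.05, 0.0, 1.0) * np.exp(
            -np.clip(t - 300.0, 0.0, None) / 50.0)
        frames = (1.0 + 0.05 * v)[:, None, None]
        f = extract_features(movie_of(frames), band_hz=None, spatial=1,
                             drift_model=None, baseline_window_s=(0.0, 1.0))
        assert f.upstroke_df_per_ms[0, 0, 0] == pytest.approx(s, rel=0.02)

    def test_upstroke_offset_invariance(self, clean_ap_movie):
        _, movie, _, _ = clean_ap_movie
        kw = dict(band_hz=None, spatial=1, drift_model=None)
        f1 = extract_features(movie, **kw)
        shifted = movie.copy_with(movie.frames + 0.5)
        f2 = extract_features(shifted, **kw)
        # ΔF normalization rescales with the background level; the upstroke
        # map must change only by that uniform factor
        r = f2.upstroke_df_per_ms / f1.upstroke_df_per_ms
        assert np.nanstd(r) / np.nanmean(r) < 1e-3
        np.testing.assert_allclose(f1.apa, f2.apa, atol=1e-6)

    def test_upstroke_slowing_ratio_recovered(self):
        cfg = small_ap_config(noise_sd=0.0, drift_linear_per_s=0.0,
                              drift_exp_amp=0.0, apa_scale=1.0,
                              apd50_scale=1.0, apd80_scale=1.0,
                              upstroke_scale=0.5)
        movie, truth, mask = simulate_ap_movie(cfg, seed=0)
        f = extract_features(movie, band_hz=None, spatial=1, drift_model=None)
        ratio = f.final("upstroke_df_per_ms") / f.baseline_mean("upstroke_df_per_ms")
        assert np.nanmedian(ratio[mask.mask]) == pytest.approx(0.5, abs=0.05)


class TestConductionVelocity:
    def test_plane_wave_recovery(self, clean_ap_movie):
        cfg, movie, truth, mask = clean_ap_movie
        f = extract_features(movie, band_hz=None, spatial=1, drift_model=None)
        cv = conduction_velocity(f.activation_ms[1], movie.meta.pixel_spacing_um)
        ok = cv["valid"]
        assert ok.sum() > 100
        assert np.nanmedian(cv["speed"][ok]) == pytest.approx(0.5, rel=0.05)
        ang = np.nanmedian(cv["angle_deg"][ok])
        assert abs(ang - cfg.cv_direction_deg) < 5.0

    def test_simultaneous_activation_masked(self):
        act = np.full((20, 20), 7.0)
        cv = conduction_velocity(act, (250.0, 250.0))
        assert not cv["valid"].any()
        assert np.all(np.isnan(cv["speed"]))

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        act = np.add.outer(np.arange(20) * 0.3, np.arange(20) * 0.5)
        cv = conduction_velocity(act, (250.0, 250.0))
        cv_rot = conduction_velocity(np.rot90(act), (250.0, 250.0))
        s = cv["speed"][cv["valid"]]
        s_rot = cv_rot["speed"][cv_rot["valid"]]
        assert np.nanmedian(s) == pytest.approx(np.nanmedian(s_rot), rel=1e-9)
        a = np.nanmedian(cv["angle_deg"][cv["valid"]])
        a_rot = np.nanmedian(cv_rot["angle_deg"][cv_rot["valid"]])
        assert (a - a_rot) % 360 == pytest.approx(90.0, abs=1e-6)
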