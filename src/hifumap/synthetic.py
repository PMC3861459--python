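"""Synthetic envelope sequences, paced AP movies, and histology images.

These generators emulate the acquisition geometry of a transmural cardiac
wedge experiment — M2D ultrasound speckle at 11 frames/s during a 4 s
ablation exposure, optical-mapping fluorescence at 1000 frames/s with
1000 ms pacing, and two-color gross/histology photographs — with exact,
analytically known ground truth, so every downstream estimator can be
validated without experimental data.

Speckle is modeled directly at the envelope-statistics level: amplitudes are
drawn i.i.d. per pixel from a Rayleigh or log-normal law whose parameters
ramp linearly inside the lesion ellipse across the ablation window.  The AP
movie renders, per pacing cycle, a piecewise template (half-cosine upstroke,
flat plateau, exponential repolarization solved to hit the configured APD50
and APD80 simultaneously) propagated as a plane wave, with lesion pixels
losing amplitude and shortening APD along the same ramp, plus multiplicative
photobleaching drift and additive sensor noise.  Ground-truth feature maps
are always computed from the generative parameters, never from the rendered
frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import (AcquisitionMeta, EnvelopeSequence, LesionMask, OpticalMovie,
                 ValidationError)

__all__ = [
    "SpecklePhantomConfig",
    "APMovieConfig",
    "lesion_ellipse_mask",
    "ablation_ramp",
    "ap_template_shape",
    "ap_template",
    "simulate_speckle_sequence",
    "simulate_ap_movie",
    "simulate_histology_image",
    "simulate_delta_apa_map",
]


def lesion_ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                        semiaxes: tuple[float, float]) -> np.ndarray:
    """Boolean ellipse mask; zero semi-axes give an empty mask."""
    a, b = semiaxes
    if a <= 0 or b <= 0:
        return np.zeros(shape, dtype=bool)
    r, c = np.ogrid[: shape[0], : shape[1]]
    return ((r - center[0]) / a) ** 2 + ((c - center[1]) / b) ** 2 <= 1.0


def ablation_ramp(t_s: np.ndarray | float, window_s: tuple[float, float]) -> np.ndarray:
    """Linear 0→1 ramp across the ablation window, clipped outside it."""
    a, b = window_s
    return np.clip((np.asarray(t_s, dtype=float) - a) / (b - a), 0.0, 1.0)


# ---------------------------------------------------------------------------
# ultrasound speckle phantom


@dataclass
class SpecklePhantomConfig:
    """Envelope speckle phantom with a time-progressive lesion.

    Defaults mirror the imaged conditions: 11 frames/s M2D imaging from
    t = 4 s to ~8.64 s with the ablation exposure at 4.5–8.5 s, so the first
    ~6 frames form the pre-ablation baseline.  The lesion ellipse ramps the
    local amplitude-distribution parameters linearly from identity at
    ablation onset to the configured final shift at ablation end.
    """

    shape: tuple[int, int] = (200, 80)
    frame_rate_hz: float = 11.0
    n_frames: int = 51
    time_origin_s: float = 4.0
    ablation_window_s: tuple[float, float] = (4.5, 8.5)
    pixel_spacing_um: tuple[float, float] = (50.0, 100.0)
    model: str = "lognormal"            # "lognormal" or "rayleigh"
    alpha0: float = 1.0                 # Rayleigh scale (model="rayleigh")
    mu0: float = 0.0                    # log-normal log-mean
    sigma0: float = 0.3                 # log-normal shape
    lesion_center: tuple[float, float] = (100.0, 40.0)
    lesion_semiaxes: tuple[float, float] = (60.0, 14.0)  # (axial, lateral) px; 0 => none
    lesion_alpha_gain: float = 1.6      # final α multiplier inside lesion
    lesion_sigma_gain: float = 1.8      # final σ multiplier inside lesion
    lesion_mu_shift: float = 0.4        # final additive shift of µ inside lesion
    noise_floor: float = 0.0            # additive amplitude offset

    def __post_init__(self) -> None:
        if self.model not in ("lognormal", "rayleigh"):
            raise ValidationError("model must be 'lognormal' or 'rayleigh'")
        if self.alpha0 <= 0:
            raise ValidationError("alpha0 must be > 0")
        if self.sigma0 < 0:
            raise ValidationError("sigma0 must be >= 0")
        a, b = self.lesion_semiaxes
        if a > 0 and b > 0:
            cr, cc = self.lesion_center
            if (cr - a < 0 or cr + a > self.shape[0] - 1
                    or cc - b < 0 or cc + b > self.shape[1] - 1):
                raise ValidationError("lesion ellipse must lie inside the grid")
        start, stop = self.ablation_window_s
        t_last = self.time_origin_s + (self.n_frames - 1) / self.frame_rate_hz
        if self.time_origin_s >= start:
            raise ValidationError("no baseline frames before ablation onset")
        if t_last < stop:
            raise ValidationError("sequence must span the ablation window")

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            frame_rate_hz=self.frame_rate_hz,
            pixel_spacing_um=self.pixel_spacing_um,
            time_origin_s=self.time_origin_s,
            ablation_window_s=self.ablation_window_s,
        )


def simulate_speckle_sequence(cfg: SpecklePhantomConfig, seed: int = 0
                              ) -> tuple[EnvelopeSequence, LesionMask]:
    """Draw the envelope sequence and return it with the generative mask.

    Amplitudes are i.i.d. within each region and frame; inside the lesion
    the distribution parameters follow the linear ablation ramp.  Bitwise
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    mask = lesion_ellipse_mask(cfg.shape, cfg.lesion_center, cfg.lesion_semiaxes)
    times = cfg.time_origin_s + np.arange(cfg.n_frames) / cfg.frame_rate_hz
    ramps = ablation_ramp(times, cfg.ablation_window_s)
    frames = np.empty((cfg.n_frames,) + tuple(cfg.shape), dtype=np.float64)
    n_lesion = int(mask.sum())
    for t, r in enumerate(ramps):
        if cfg.model == "rayleigh":
            frame = rng.rayleigh(scale=cfg.alpha0, size=cfg.shape)
            if n_lesion:
                alpha = cfg.alpha0 * (1.0 + r * (cfg.lesion_alpha_gain - 1.0))
                frame[mask] = rng.rayleigh(scale=alpha, size=n_lesion)
        else:
            frame = np.exp(cfg.mu0 + cfg.sigma0 * rng.standard_normal(cfg.shape))
            if n_lesion:
                mu = cfg.mu0 + r * cfg.lesion_mu_shift
                sig = cfg.sigma0 * (1.0 + r * (cfg.lesion_sigma_gain - 1.0))
                frame[mask] = np.exp(mu + sig * rng.standard_normal(n_lesion))
        frames[t] = frame + cfg.noise_floor
    env = EnvelopeSequence(frames=frames, meta=cfg.meta())
    return env, LesionMask(mask=mask, provenance="synthetic-truth",
                           pixel_spacing_um=cfg.pixel_spacing_um)


# ---------------------------------------------------------------------------
# paced AP movie


def ap_template_shape(upstroke_ms: float, apd50_ms: float, apd80_ms: float
                      ) -> tuple[float, float]:
    """Plateau duration and repolarization time constant hitting both APDs.

    The template is a half-cosine upstroke (duration u, max slope at u/2 =
    the activation time), a flat plateau at 1, and exponential decay
    ``exp(−t/τ)``.  Measuring APD from the activation time, the 50% and 80%
    repolarization crossings give ``τ = (APD80 − APD50)/ln 2.5`` and
    ``plateau = APD50 − u/2 − τ·ln 2``.
    """
    if not 0 < apd50_ms < apd80_ms:
        raise ValidationError("need 0 < APD50 < APD80")
    tau = (apd80_ms - apd50_ms) / math.log(2.5)
    plateau = apd50_ms - upstroke_ms / 2.0 - tau * math.log(2.0)
    if plateau < 0:
        raise ValidationError("APD50 too short for the configured upstroke/τ")
    return plateau, tau


def ap_template(t_ms: np.ndarray, upstroke_ms: float, apd50_ms: float,
                apd80_ms: float) -> np.ndarray:
    """Normalized AP waveform (0→1 amplitude) sampled at ``t_ms`` past onset."""
    plateau, tau = ap_template_shape(upstroke_ms, apd50_ms, apd80_ms)
    t = np.asarray(t_ms, dtype=np.float64)
    v = np.zeros_like(t)
    up = (t >= 0) & (t < upstroke_ms)
    v[up] = 0.5 * (1.0 - np.cos(np.pi * t[up] / upstroke_ms))
    flat = (t >= upstroke_ms) & (t < upstroke_ms + plateau)
    v[flat] = 1.0
    rep = t >= upstroke_ms + plateau
    v[rep] = np.exp(-(t[rep] - upstroke_ms - plateau) / tau)
    return v


@dataclass
class APMovieConfig:
    """Paced optical-mapping movie with a plane wave and a ramped lesion.

    Defaults are the experiment's acquisition conditions: 100×100 pixels at
    1000 frames/s for 32 s, pacing cycle 1000 ms, 250 µm pixels, conduction
    at 0.5 mm/ms, baseline APD50/APD80 = 160/200 ms (ratio 0.8), an 8 ms
    upstroke (max normalized slope ≈ 0.196/ms), and lesion end-state effects
    of APA×0.2, APD50×0.67, APD80×0.79, upstroke rate×0.58 ramped linearly
    over the 4.5–8.5 s ablation window.  Fluorescence is rendered as
    ``drift(t)·[F0 + A0·APA(x,y;cycle)·V(t − activation)] + noise`` with
    fractional AP amplitude A0 = 5% of background and noise sd 0.005
    (20 dB amplitude SNR).
    """

    shape: tuple[int, int] = (100, 100)
    frame_rate_hz: float = 1000.0
    duration_s: float = 32.0
    pacing_cycle_ms: float = 1000.0
    pixel_spacing_um: tuple[float, float] = (250.0, 250.0)
    upstroke_ms: float = 8.0
    apd50_ms: float = 160.0
    apd80_ms: float = 200.0
    cv_mm_per_ms: float = 0.5
    cv_direction_deg: float = 0.0       # 0 => propagation along +columns
    lesion_center: tuple[float, float] = (50.0, 50.0)
    lesion_semiaxes: tuple[float, float] = (20.0, 12.0)  # px; 0 => no lesion
    apa_scale: float = 0.2              # final lesion amplitude multiplier
    apd50_scale: float = 0.67
    apd80_scale: float = 0.79
    upstroke_scale: float = 0.58        # final lesion upstroke-rate multiplier
    ablation_window_s: tuple[float, float] = (4.5, 8.5)
    f0: float = 1.0                     # background fluorescence
    apa_df: float = 0.05                # fractional AP amplitude ΔF/F0
    drift_linear_per_s: float = -0.003
    drift_exp_amp: float = 0.02
    drift_exp_tau_s: float = 8.0
    noise_sd: float = 0.005
    time_origin_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.apd50_ms < self.apd80_ms < self.pacing_cycle_ms:
            raise ValidationError("need 0 < APD50 < APD80 < pacing cycle")
        if not 0.0 <= self.apa_scale <= 1.0:
            raise ValidationError("apa_scale must lie in [0, 1]")
        if self.cv_mm_per_ms <= 0:
            raise ValidationError("conduction velocity must be > 0")
        if not (0 < self.apd50_scale and 0 < self.apd80_scale <= 1.0
                and self.apd50_ms * self.apd50_scale < self.apd80_ms * self.apd80_scale):
            raise ValidationError("lesion APD scales must keep 0 < APD50 < APD80")
        # both extreme templates must be constructible
        ap_template_shape(self.upstroke_ms, self.apd50_ms, self.apd80_ms)
        ap_template_shape(self.lesion_upstroke_ms(1.0),
                          self.apd50_ms * self.apd50_scale,
                          self.apd80_ms * self.apd80_scale)

    def lesion_upstroke_ms(self, ramp: float) -> float:
        rate_factor = 1.0 - ramp * (1.0 - self.upstroke_scale)
        return self.upstroke_ms / rate_factor

    def activation_offset_ms(self) -> np.ndarray:
        """Plane-wave activation offset (ms) of each pixel, min-zeroed."""
        th = math.radians(self.cv_direction_deg)
        unit = np.array([math.sin(th), math.cos(th)])   # (row, col) components
        ax_mm = self.pixel_spacing_um[0] * 1e-3
        lat_mm = self.pixel_spacing_um[1] * 1e-3
        r, c = np.meshgrid(np.arange(self.shape[0]) * ax_mm,
                           np.arange(self.shape[1]) * lat_mm, indexing="ij")
        proj = r * unit[0] + c * unit[1]
        proj -= proj.min()
        return proj / self.cv_mm_per_ms

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            frame_rate_hz=self.frame_rate_hz,
            pixel_spacing_um=self.pixel_spacing_um,
            time_origin_s=self.time_origin_s,
            ablation_window_s=self.ablation_window_s,
        )


def _movie_truth(cfg: APMovieConfig, mask: np.ndarray, r_final: float) -> dict:
    """Ground-truth feature maps from the generative parameters only."""
    act = cfg.activation_offset_ms() + cfg.upstroke_ms / 2.0
    apd50 = np.full(cfg.shape, cfg.apd50_ms)
    apd80 = np.full(cfg.shape, cfg.apd80_ms)
    dapa = np.zeros(cfg.shape)
    up = np.full(cfg.shape, cfg.apa_df * np.pi / (2.0 * cfg.upstroke_ms))
    apd50_f, apd80_f, dapa_f, up_f = (apd50.copy(), apd80.copy(), dapa.copy(), up.copy())
    a_f = 1.0 - r_final * (1.0 - cfg.apa_scale)
    s50 = 1.0 - r_final * (1.0 - cfg.apd50_scale)
    s80 = 1.0 - r_final * (1.0 - cfg.apd80_scale)
    u_f = cfg.lesion_upstroke_ms(r_final)
    apd50_f[mask] = cfg.apd50_ms * s50
    apd80_f[mask] = cfg.apd80_ms * s80
    dapa_f[mask] = a_f - 1.0
    up_f[mask] = a_f * cfg.apa_df * np.pi / (2.0 * u_f)
    return {
        "activation_ms": act,
        "apd50_ms": apd50, "apd80_ms": apd80,
        "tri_ratio": apd50 / apd80,
        "upstroke_df_per_ms": up,
        "apd50_final_ms": apd50_f, "apd80_final_ms": apd80_f,
        "tri_ratio_final": apd50_f / apd80_f,
        "dapa_final": dapa_f,
        "upstroke_final_df_per_ms": up_f,
        "cv_mm_per_ms": cfg.cv_mm_per_ms,
        "cv_direction_deg": cfg.cv_direction_deg,
        "ramp_final": r_final,
    }


def simulate_ap_movie(cfg: APMovieConfig, seed: int = 0
                      ) -> tuple[OpticalMovie, dict, LesionMask]:
    """Render the fluorescence movie; return it with analytic truth and mask.

    Lesion effects are evaluated at each cycle's stimulus time on the linear
    ablation ramp, so within a cycle the waveform is stationary.  The truth
    dict holds per-pixel baseline and end-state feature maps (see
    :func:`_movie_truth`) computed from the config, not from the frames.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))
    dt_ms = 1000.0 / cfg.frame_rate_hz
    times_ms = np.arange(n_frames) * dt_ms
    mask = lesion_ellipse_mask(cfg.shape, cfg.lesion_center, cfg.lesion_semiaxes)
    act = cfg.activation_offset_ms()
    n_cycles = int(n_frames * dt_ms // cfg.pacing_cycle_ms)
    if n_cycles < 1:
        raise ValidationError("movie shorter than one pacing cycle")

    npx = cfg.shape[0] * cfg.shape[1]
    act_flat = act.ravel()
    mask_flat = mask.ravel()
    signal = np.zeros((n_frames, npx), dtype=np.float64)
    fine = np.arange(0.0, cfg.pacing_cycle_ms + dt_ms, 0.1)
    r_c = 0.0
    for c in range(n_cycles):
        stim = c * cfg.pacing_cycle_ms
        r_c = float(ablation_ramp(cfg.time_origin_s + stim / 1000.0,
                                  cfg.ablation_window_s))
        sel = (times_ms >= stim) & (times_ms < stim + cfg.pacing_cycle_ms)
        tloc = times_ms[sel] - stim
        v_bg = ap_template(fine, cfg.upstroke_ms, cfg.apd50_ms, cfg.apd80_ms)
        q = tloc[None, :] - act_flat[:, None]
        vals = np.interp(q, fine, v_bg, left=0.0, right=0.0)
        if mask_flat.any() and r_c > 0:
            a_c = 1.0 - r_c * (1.0 - cfg.apa_scale)
            v_le = ap_template(fine, cfg.lesion_upstroke_ms(r_c),
                               cfg.apd50_ms * (1.0 - r_c * (1.0 - cfg.apd50_scale)),
                               cfg.apd80_ms * (1.0 - r_c * (1.0 - cfg.apd80_scale)))
            vals[mask_flat] = a_c * np.interp(q[mask_flat], fine, v_le,
                                              left=0.0, right=0.0)
        signal[sel] = (cfg.f0 + cfg.apa_df * vals).T
    # trailing partial cycle stays at diastolic level
    signal[signal == 0.0] = cfg.f0

    t_s = times_ms / 1000.0
    drift = (1.0 + cfg.drift_linear_per_s * t_s
             + cfg.drift_exp_amp * (np.exp(-t_s / cfg.drift_exp_tau_s) - 1.0))
    frames = signal * drift[:, None]
    if cfg.noise_sd > 0:
        frames = frames + cfg.noise_sd * rng.standard_normal(frames.shape)
    movie = OpticalMovie(frames=frames.reshape((n_frames,) + tuple(cfg.shape)),
                         meta=cfg.meta(), pacing_cycle_ms=cfg.pacing_cycle_ms)
    truth = _movie_truth(cfg, mask, r_c)
    lesion = LesionMask(mask=mask, provenance="synthetic-truth",
                        pixel_spacing_um=cfg.pixel_spacing_um)
    return movie, truth, lesion


# ---------------------------------------------------------------------------
# histology photograph


def simulate_histology_image(shape: tuple[int, int] = (120, 160),
                             lesion_center: tuple[float, float] = (60.0, 80.0),
                             lesion_semiaxes: tuple[float, float] = (25.0, 45.0),
                             lesion_rgb: tuple[int, int, int] = (232, 222, 205),
                             background_rgb: tuple[int, int, int] = (125, 45, 60),
                             noise_sd: float = 8.0,
                             outlier_frac: float = 0.01,
                             seed: int = 0) -> tuple[np.ndarray, LesionMask]:
    """Two-class RGB phantom: pale lesion on dark-red myocardium.

    Gaussian color noise plus a fraction of single-pixel class-color
    outliers (to exercise the MRF label smoothing).  Identical class colors
    with zero noise trigger a degenerate-segmentation warning.
    """
    if tuple(lesion_rgb) == tuple(background_rgb) and noise_sd == 0:
        warnings.warn("identical class colors with zero noise: segmentation degenerate")
    rng = np.random.default_rng(seed)
    mask = lesion_ellipse_mask(shape, lesion_center, lesion_semiaxes)
    img = np.empty(shape + (3,), dtype=np.float64)
    img[~mask] = background_rgb
    img[mask] = lesion_rgb
    if outlier_frac > 0:
        flip = rng.random(shape) < outlier_frac
        img[flip & mask] = background_rgb
        img[flip & ~mask] = lesion_rgb
    img += noise_sd * rng.standard_normal(img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, LesionMask(mask=mask, provenance="synthetic-truth")


# ---------------------------------------------------------------------------
# ΔAPA score-map cohort (lesion core / border rim / unchanged background)


def simulate_delta_apa_map(shape: tuple[int, int] = (60, 60),
                           lesion_center: tuple[float, float] = (30.0, 30.0),
                           lesion_semiaxes: tuple[float, float] = (14.0, 9.0),
                           border_width_px: float = 4.0,
                           lesion_effect: float = -0.5,
                           border_effect: float = -0.31,
                           noise_sd: float = 0.1,
                           seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray, LesionMask]:
    """ΔAPA map phantom: lesion core, border rim, and unchanged background.

    Returns ``(noisy_map, mean_field, LesionMask)`` where the mean field is
    the noiseless generative ΔAPA (lesion_effect inside the lesion ellipse,
    border_effect in a surrounding rim, 0 elsewhere).
    """
    rng = np.random.default_rng(seed)
    core = lesion_ellipse_mask(shape, lesion_center, lesion_semiaxes)
    outer = lesion_ellipse_mask(shape, lesion_center,
                                (lesion_semiaxes[0] + border_width_px,
                                 lesion_semiaxes[1] + border_width_px))
    rim = outer & ~core
    mean = np.zeros(shape, dtype=np.float64)
    mean[core] = lesion_effect
    mean[rim] = border_effect
    noisy = mean + noise_sd * rng.standard_normal(shape)
    return noisy, mean, LesionMask(mask=core, provenance="synthetic-truth")
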