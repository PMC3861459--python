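"""Per-pixel parametric ultrasound images from envelope frames.

Four parameters are estimated from the envelope amplitude A:

* GS  — grayscale, ``20·log10(A/ref)`` in dB (per pixel, no window);
* IBS — integrated backscatter, ``10·log10(<A²>_w / ref²)`` in dB over a
  sliding window w;
* α   — Rayleigh scale, closed-form MLE ``sqrt(Σ A² / 2N)`` over the window;
* σ   — log-normal shape, closed-form MLE ``sqrt(mean(ln A²) − mean(ln A)²)``
  over the strictly positive window samples.

The window (default 100×13 pixels, axial×lateral) slides with stride 1 and
shrinks at the frame border, so every parametric map has the same shape as
the source frame and all four maps share pixel alignment.  The dB reference
is the maximum envelope amplitude over the pre-ablation baseline frames
unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .io import AcquisitionMeta, EnvelopeSequence, ValidationError

__all__ = [
    "WindowSpec",
    "ParametricMapSequence",
    "grayscale_map",
    "ibs_map",
    "rayleigh_alpha_map",
    "lognormal_sigma_map",
    "parametric_map",
    "goodness_of_fit",
    "rayleigh_alpha_mle",
    "lognormal_mle",
]

PARAM_UNITS = {"GS": "dB", "IBS": "dB", "alpha": "linear", "sigma": "dimensionless"}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding estimation window (axial height × lateral width, in pixels)."""

    height_px: int = 100
    width_px: int = 13
    stride: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValidationError("window dimensions must be >= 1")
        if any(s < 1 for s in self.stride):
            raise ValidationError("stride must be >= 1")

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.height_px > shape[0] or self.width_px > shape[1]:
            raise ValidationError(
                f"window {self.height_px}x{self.width_px} does not fit frame {shape}")


@dataclass
class ParametricMapSequence:
    """Stack of per-pixel parameter frames X(row, col; t) for one parameter."""

    param: str
    frames: np.ndarray
    units: str
    meta: AcquisitionMeta
    window: Optional[WindowSpec] = None

    def __post_init__(self) -> None:
        if self.param not in PARAM_UNITS:
            raise ValidationError(f"param must be one of {tuple(PARAM_UNITS)}")
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be 3D (t, row, col)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.meta.time_origin_s + np.arange(self.n_frames) / self.meta.frame_rate_hz

    def baseline_indices(self) -> np.ndarray:
        if self.meta.ablation_window_s is None:
            raise ValidationError("no ablation window in metadata")
        idx = np.nonzero(self.times_s < self.meta.ablation_window_s[0])[0]
        if idx.size == 0:
            raise ValidationError("no frames precede ablation onset")
        return idx


# ---------------------------------------------------------------------------
# sliding truncated-window sums (integral image; window shrinks at borders)


def _window_sum(img: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sum of ``img`` over an h×w window anchored at each pixel's center.

    The window covers rows ``[i - (h-1)//2, i + h//2]`` clipped to the frame
    (shrink-at-border policy), so the output has the same shape as ``img``.
    """
    H, W = img.shape
    ii = np.zeros((H + 1, W + 1), dtype=np.float64)
    ii[1:, 1:] = np.cumsum(np.cumsum(img, axis=0), axis=1)
    h0, h1 = (h - 1) // 2, h // 2
    w0, w1 = (w - 1) // 2, w // 2
    r = np.arange(H)
    c = np.arange(W)
    r0 = np.clip(r - h0, 0, H)
    r1 = np.clip(r + h1 + 1, 0, H)
    c0 = np.clip(c - w0, 0, W)
    c1 = np.clip(c + w1 + 1, 0, W)
    return (ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)]
            - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)])


def _window_count(shape: tuple[int, int], h: int, w: int) -> np.ndarray:
    return _window_sum(np.ones(shape), h, w)


def _reference_amplitude(A: EnvelopeSequence, ref: Optional[float]) -> float:
    if ref is not None:
        if ref <= 0:
            raise ValidationError("reference amplitude must be > 0")
        return float(ref)
    try:
        idx = A.baseline_indices()
    except Exception:
        idx = np.arange(A.n_frames)
    r = float(A.frames[idx].max())
    if r <= 0:
        raise ValidationError("all-zero sequence: no usable dB reference")
    return r


def _subsample(frames: np.ndarray, stride: tuple[int, int]) -> np.ndarray:
    sr, sc = stride
    return frames[:, ::sr, ::sc] if (sr, sc) != (1, 1) else frames


def grayscale_map(A: EnvelopeSequence, ref: Optional[float] = None,
                  floor_db: float = -60.0) -> ParametricMapSequence:
    """Grayscale (log-compressed envelope) in dB: ``20·log10(A/ref)``.

    Zero amplitudes map to ``floor_db``.  ``ref`` defaults to the maximum
    envelope over the pre-ablation baseline frames.
    """
    r = _reference_amplitude(A, ref)
    with np.errstate(divide="ignore"):
        gs = 20.0 * np.log10(A.frames / r)
    gs = np.maximum(gs, floor_db)
    return ParametricMapSequence("GS", gs, "dB", A.meta)


def ibs_map(A: EnvelopeSequence, window: WindowSpec = WindowSpec(),
            ref: Optional[float] = None, floor_db: float = -60.0) -> ParametricMapSequence:
    """Integrated backscatter in dB: windowed mean squared envelope over ref²."""
    window.validate_for(A.frames.shape[1:])
    r = _reference_amplitude(A, ref)
    cnt = _window_count(A.frames.shape[1:], window.height_px, window.width_px)
    out = np.empty_like(A.frames)
    for t in range(A.n_frames):
        ms = _window_sum(A.frames[t] ** 2, window.height_px, window.width_px) / cnt
        with np.errstate(divide="ignore"):
            out[t] = 10.0 * np.log10(ms / r**2)
    out = np.maximum(out, floor_db)
    return ParametricMapSequence("IBS", _subsample(out, window.stride), "dB", A.meta, window)


def rayleigh_alpha_map(A: EnvelopeSequence, window: WindowSpec = WindowSpec()) -> ParametricMapSequence:
    """Rayleigh scale MLE per window: ``α̂ = sqrt(Σ A² / (2N))``."""
    window.validate_for(A.frames.shape[1:])
    cnt = _window_count(A.frames.shape[1:], window.height_px, window.width_px)
    out = np.empty_like(A.frames)
    degenerate = False
    for t in range(A.n_frames):
        s2 = _window_sum(A.frames[t] ** 2, window.height_px, window.width_px)
        out[t] = np.sqrt(s2 / (2.0 * cnt))
        if np.any(s2 == 0):
            degenerate = True
            out[t][s2 == 0] = np.nan
    if degenerate:
        warnings.warn("all-zero windows: Rayleigh alpha undefined, set to NaN")
    return ParametricMapSequence("alpha", _subsample(out, window.stride), "linear", A.meta, window)


def lognormal_sigma_map(A: EnvelopeSequence, window: WindowSpec = WindowSpec()) -> ParametricMapSequence:
    """Log-normal shape MLE per window on strictly positive samples.

    ``σ̂ = sqrt((1/N)·Σ (ln Aᵢ − µ̂)²)`` with ``µ̂ = mean(ln Aᵢ)``; windows
    with fewer than 2 positive samples get a NaN sentinel (zero counts are
    excluded, their number is reported via warning).
    """
    window.validate_for(A.frames.shape[1:])
    h, w = window.height_px, window.width_px
    out = np.empty_like(A.frames)
    n_zero = 0
    for t in range(A.n_frames):
        frame = A.frames[t]
        pos = frame > 0
        n_zero += int(pos.size - pos.sum())
        ln = np.where(pos, np.log(frame, where=pos, out=np.zeros_like(frame)), 0.0)
        n = _window_sum(pos.astype(np.float64), h, w)
        s1 = _window_sum(ln, h, w)
        s2 = _window_sum(ln**2, h, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = s1 / n
            var = s2 / n - mu**2
        sig = np.sqrt(np.maximum(var, 0.0))
        sig[n < 2] = np.nan
        out[t] = sig
    if n_zero:
        warnings.warn(f"{n_zero} zero-amplitude samples excluded from log-normal fit")
    return ParametricMapSequence("sigma", _subsample(out, window.stride), "dimensionless", A.meta, window)


def parametric_map(A: EnvelopeSequence, param: str,
                   window: WindowSpec = WindowSpec(), **kw) -> ParametricMapSequence:
    """Dispatch to the estimator for ``param`` in {GS, IBS, alpha, sigma}."""
    if param == "GS":
        return grayscale_map(A, **kw)
    if param == "IBS":
        return ibs_map(A, window, **kw)
    if param == "alpha":
        return rayleigh_alpha_map(A, window)
    if param == "sigma":
        return lognormal_sigma_map(A, window)
    raise ValidationError(f"unknown parameter {param!r}")


# ---------------------------------------------------------------------------
# direct MLEs on sample vectors (used by goodness_of_fit and tests)


def rayleigh_alpha_mle(samples: np.ndarray) -> float:
    """Closed-form Rayleigh scale MLE on a 1D sample vector."""
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 2 or np.all(x == 0):
        raise ValidationError("need >= 2 nonzero samples")
    return float(np.sqrt(np.sum(x**2) / (2.0 * x.size)))


def lognormal_mle(samples: np.ndarray) -> tuple[float, float]:
    """Closed-form log-normal (µ̂, σ̂) MLE on strictly positive samples."""
    x = np.asarray(samples, dtype=np.float64).ravel()
    x = x[x > 0]
    if x.size < 2:
        raise ValidationError("need >= 2 strictly positive samples")
    ln = np.log(x)
    mu = float(ln.mean())
    sigma = float(np.sqrt(np.mean((ln - mu) ** 2)))
    return mu, sigma


def goodness_of_fit(samples: np.ndarray, model: str, n_bins: int = 45) -> dict:
    """Fit quality of the MLE pdf against the binned amplitude histogram.

    Bins are ``n_bins`` equal-width intervals over [0, max(samples)].
    Returns adjusted R² on the normalized histogram, Pearson χ² on counts,
    and ``dof = n_bins − n_params − 1``.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 100:
        raise ValidationError("need >= 100 samples for a histogram fit")
    if x.max() <= x.min():
        raise ValidationError("degenerate (constant) sample histogram")
    counts, edges = np.histogram(x, bins=n_bins, range=(0.0, float(x.max())))
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (x.size * np.diff(edges))
    if model == "rayleigh":
        alpha = rayleigh_alpha_mle(x)
        pdf = stats.rayleigh.pdf(centers, scale=alpha)
        cdf = stats.rayleigh.cdf(edges, scale=alpha)
        n_params = 1
    elif model == "lognormal":
        mu, sigma = lognormal_mle(x)
        pdf = stats.lognorm.pdf(centers, s=sigma, scale=np.exp(mu))
        cdf = stats.lognorm.cdf(edges, s=sigma, scale=np.exp(mu))
        n_params = 2
    else:
        raise ValidationError("model must be 'rayleigh' or 'lognormal'")
    ss_res = float(np.sum((density - pdf) ** 2))
    ss_tot = float(np.sum((density - density.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    dof = n_bins - n_params - 1
    r2_adj = 1.0 - (1.0 - r2) * (n_bins - 1) / dof
    expected = x.size * np.diff(cdf)
    ok = expected > 0
    chi2 = float(np.sum((counts[ok] - expected[ok]) ** 2 / expected[ok]))
    return {"model": model, "r2_adj": float(r2_adj), "chi2": chi2, "dof": int(dof),
            "n_bins": int(n_bins), "n": int(x.size)}
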