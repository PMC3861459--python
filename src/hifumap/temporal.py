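"""Temporal-evolution images of a parametric map sequence.

Three operators turn a parameter stack X(row, col; t) into lesion-tracking
images:

* transient  |ΔX|_t — absolute difference of adjacent frames;
* cumulative ΔX_c   — difference from the mean of the pre-ablation baseline
  frames (signed and absolute variants);
* cumulative extrema |ΔX|_max — per-pixel running maximum of |ΔX_c|,
  normalized to [0, 1] by one global constant over the whole sequence.

The global normalization keeps the extrema map monotone per pixel and gives
a single dimensionless detection threshold per parameter; the normalization
scale is kept so a threshold trained on one sequence can be applied to
another in common units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import ValidationError
from .usparams import ParametricMapSequence

__all__ = [
    "BaselineSpec",
    "TemporalMaps",
    "transient_change",
    "cumulative_change",
    "cumulative_extrema",
    "temporal_maps",
]


@dataclass(frozen=True)
class BaselineSpec:
    """Frame indices forming the pre-ablation baseline average."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValidationError("baseline must contain at least one frame")

    @classmethod
    def from_sequence(cls, X: ParametricMapSequence) -> "BaselineSpec":
        """All frames acquired before ablation onset (the default baseline)."""
        return cls(tuple(int(i) for i in X.baseline_indices()))

    def validate_for(self, X: ParametricMapSequence) -> None:
        if max(self.indices) >= X.n_frames or min(self.indices) < 0:
            raise ValidationError("baseline indices outside sequence")
        if X.meta.ablation_window_s is not None:
            onset = X.meta.ablation_window_s[0]
            if np.any(X.times_s[list(self.indices)] >= onset):
                raise ValidationError("baseline frames must precede ablation onset")


@dataclass
class TemporalMaps:
    """Bundle of the three temporal operators applied to one parameter."""

    param: str
    transient: np.ndarray            # |ΔX|_t, frame 0 is NaN
    cumulative_signed: np.ndarray    # ΔX_c
    cumulative_abs: np.ndarray       # |ΔX|_c
    extrema_raw: np.ndarray          # running max of |ΔX|_c, original units
    extrema: np.ndarray              # extrema_raw / norm_scale, in [0, 1]
    norm_scale: float                # global max used for normalization
    baseline: BaselineSpec


def _frames_of(X) -> np.ndarray:
    return X.frames if isinstance(X, ParametricMapSequence) else np.asarray(X, dtype=float)


def transient_change(X, signed: bool = False) -> np.ndarray:
    """Adjacent-frame difference ``X(t) − X(t−1)``; frame 0 is a NaN sentinel.

    Returns the absolute value by default (the detection-map convention);
    ``signed=True`` keeps the sign.
    """
    frames = _frames_of(X)
    if frames.shape[0] < 2:
        raise ValidationError("transient change needs >= 2 frames")
    out = np.full_like(frames, np.nan)
    d = np.diff(frames, axis=0)
    out[1:] = d if signed else np.abs(d)
    return out


def _resolve_baseline(X, baseline) -> BaselineSpec:
    if baseline is None:
        if not isinstance(X, ParametricMapSequence):
            raise ValidationError("baseline required for bare arrays")
        return BaselineSpec.from_sequence(X)
    if isinstance(baseline, BaselineSpec):
        return baseline
    return BaselineSpec(tuple(int(i) for i in baseline))


def cumulative_change(X, baseline: Optional[BaselineSpec | Sequence[int]] = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Difference of every frame from the baseline-frame average.

    Returns ``(signed, absolute)`` stacks.  The signed stack averages to
    exactly zero over the baseline frames by construction.
    """
    frames = _frames_of(X)
    b = _resolve_baseline(X, baseline)
    if isinstance(X, ParametricMapSequence):
        b.validate_for(X)
    ref = frames[list(b.indices)].mean(axis=0)
    signed = frames - ref[None]
    return signed, np.abs(signed)


def cumulative_extrema(X, baseline: Optional[BaselineSpec | Sequence[int]] = None,
                       norm_scale: Optional[float] = None
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-pixel running maximum of |ΔX_c|, normalized to [0, 1].

    Returns ``(normalized, raw, scale)``.  ``scale`` is the global maximum of
    the raw map over all pixels and frames (one constant per sequence); pass
    ``norm_scale`` to reuse a scale trained on another sequence so that a
    dimensionless threshold transfers.  An all-zero raw map skips
    normalization and returns zeros with a warning.
    """
    _, absc = cumulative_change(X, baseline)
    raw = np.fmax.accumulate(absc, axis=0)
    if norm_scale is None:
        scale = float(np.nanmax(raw))
        if scale == 0.0:
            warnings.warn("all-zero cumulative map: normalization skipped")
            return raw.copy(), raw, 0.0
    else:
        scale = float(norm_scale)
        if scale <= 0:
            raise ValidationError("norm_scale must be > 0")
    return raw / scale, raw, scale


def temporal_maps(X, baseline: Optional[BaselineSpec | Sequence[int]] = None) -> TemporalMaps:
    """All three temporal operators for one parametric map sequence."""
    b = _resolve_baseline(X, baseline)
    signed, absc = cumulative_change(X, b)
    norm, raw, scale = cumulative_extrema(X, b)
    return TemporalMaps(
        param=X.param if isinstance(X, ParametricMapSequence) else "X",
        transient=transient_change(X),
        cumulative_signed=signed,
        cumulative_abs=absc,
        extrema_raw=raw,
        extrema=norm,
        norm_scale=scale,
        baseline=b,
    )
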