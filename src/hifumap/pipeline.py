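"""End-to-end convenience wrappers: phantom → parametric maps → detection.

These functions chain the synthetic generators, windowed estimators,
temporal operators and ROC machinery into the study workflows: a per-subject
speckle analysis, a multi-subject detection cohort with leave-one-out
validation, and threshold transfer onto new sequences in the trained
normalization units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .io import LesionMask
from .roc import ScoredPixels, detection_timecourse, loo_cv, roc_curve
from .synthetic import SpecklePhantomConfig, simulate_speckle_sequence
from .temporal import TemporalMaps, temporal_maps
from .usparams import WindowSpec, parametric_map

__all__ = [
    "SpeckleAnalysis",
    "analyze_speckle_phantom",
    "speckle_cohort",
    "apply_trained_threshold",
]


@dataclass
class SpeckleAnalysis:
    """One subject's parametric-map analysis with ground truth attached."""

    subject: str
    param: str
    maps: TemporalMaps
    mask: LesionMask
    window: WindowSpec

    def interior(self) -> tuple[slice, slice]:
        """Pixels whose estimation window was never truncated at the border.

        Truncated windows have fewer samples, hence noisier estimates whose
        running maxima are inflated; they are excluded from ROC scoring.
        """
        h, w = self.window.height_px, self.window.width_px
        H, W = self.mask.mask.shape
        return (slice((h - 1) // 2, H - h // 2), slice((w - 1) // 2, W - w // 2))

    def scores(self, kind: str = "extrema") -> ScoredPixels:
        """Final-frame score map as lesion-oriented scored pixels.

        ``kind`` ∈ {extrema, cumulative, transient}: the normalized
        cumulative extrema, |ΔX|_c, or |ΔX|_t at the last frame, restricted
        to the full-window interior.
        """
        frames = {"extrema": self.maps.extrema,
                  "cumulative": self.maps.cumulative_abs,
                  "transient": self.maps.transient}[kind]
        sl = self.interior()
        return ScoredPixels.from_maps(frames[-1][sl], self.mask.mask[sl],
                                      subject=self.subject)


def analyze_speckle_phantom(cfg: SpecklePhantomConfig, seed: int,
                            window: WindowSpec, param: str = "sigma",
                            subject: Optional[str] = None) -> SpeckleAnalysis:
    """Simulate one speckle phantom and compute its temporal parameter maps."""
    env, mask = simulate_speckle_sequence(cfg, seed=seed)
    pm = parametric_map(env, param, window)
    return SpeckleAnalysis(subject=subject or f"phantom-{seed}", param=param,
                           maps=temporal_maps(pm), mask=mask, window=window)


def speckle_cohort(cfg: SpecklePhantomConfig, window: WindowSpec,
                   n_subjects: int = 13, base_seed: int = 0,
                   param: str = "sigma") -> list[SpeckleAnalysis]:
    """Independent phantoms sharing the acquisition/lesion conditions."""
    return [analyze_speckle_phantom(cfg, seed=base_seed + i, window=window,
                                    param=param, subject=f"phantom-{i}")
            for i in range(n_subjects)]


def apply_trained_threshold(analysis: SpeckleAnalysis, threshold: float,
                            trained_scale: float) -> np.ndarray:
    """Predicted lesion mask of a new sequence under a trained threshold.

    The dimensionless threshold was trained on extrema maps normalized by
    ``trained_scale`` (the training sequences' global maximum), so the new
    sequence's raw extrema are divided by the same scale before comparison —
    normalizing a null sequence by its own noise maximum would make any
    fixed threshold meaningless.
    """
    sl = analysis.interior()
    scores = analysis.maps.extrema_raw[-1][sl] / trained_scale
    return scores >= threshold
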