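"""On-disk containers and domain types shared by the whole pipeline.

Image stacks live in multi-page TIFF files with a JSON sidecar carrying the
acquisition metadata; RGB histology/gross photographs are PNG or TIFF; masks
are 0/255 PNG; tables are CSV.  Array convention throughout the package:
``frames[t, row, col]`` with row = axial/depth and col = lateral, 0-based
indices at pixel centers.  Absolute experiment time of frame ``t`` is
``meta.time_origin_s + t / meta.frame_rate_hz``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.signal import hilbert

__all__ = [
    "MetadataError",
    "ValidationError",
    "AcquisitionMeta",
    "EnvelopeSequence",
    "OpticalMovie",
    "LesionMask",
    "MASK_PROVENANCES",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_table",
    "envelope_from_rf",
]


class MetadataError(ValueError):
    """Missing or inconsistent acquisition metadata (e.g. absent JSON sidecar)."""


class ValidationError(ValueError):
    """Data violates a container invariant (shape, sign, ordering)."""


MASK_PROVENANCES = ("gross", "MT", "TTC", "predicted", "synthetic-truth")


@dataclass
class AcquisitionMeta:
    """Acquisition metadata shared by ultrasound and optical stacks.

    Parameters
    ----------
    frame_rate_hz : float
        Frames per second (11 for M2D ultrasound, ~1000 for optical mapping).
    pixel_spacing_um : (float, float)
        (axial, lateral) pixel spacing in micrometres.
    rf_sample_rate_hz : float, optional
        RF digitizer sample rate, if the stack derives from RF data.
    time_origin_s : float
        Absolute time of frame 0 on the shared experiment clock.
    ablation_window_s : (float, float), optional
        (start, stop) of the ablation exposure on the same clock.
    """

    frame_rate_hz: float
    pixel_spacing_um: tuple[float, float] = (250.0, 250.0)
    rf_sample_rate_hz: Optional[float] = None
    time_origin_s: float = 0.0
    ablation_window_s: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ValidationError("frame_rate_hz must be > 0")
        if len(self.pixel_spacing_um) != 2 or any(s <= 0 for s in self.pixel_spacing_um):
            raise ValidationError("pixel_spacing_um must be two positive values")
        self.pixel_spacing_um = (float(self.pixel_spacing_um[0]), float(self.pixel_spacing_um[1]))
        if self.ablation_window_s is not None:
            a, b = self.ablation_window_s
            if not a < b:
                raise ValidationError("ablation window start must precede stop")
            self.ablation_window_s = (float(a), float(b))

    def to_dict(self) -> dict:
        return {
            "frame_rate_hz": self.frame_rate_hz,
            "pixel_spacing_um": list(self.pixel_spacing_um),
            "rf_sample_rate_hz": self.rf_sample_rate_hz,
            "time_origin_s": self.time_origin_s,
            "ablation_window_s": (
                list(self.ablation_window_s) if self.ablation_window_s is not None else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(
            frame_rate_hz=d["frame_rate_hz"],
            pixel_spacing_um=tuple(d.get("pixel_spacing_um", (250.0, 250.0))),
            rf_sample_rate_hz=d.get("rf_sample_rate_hz"),
            time_origin_s=d.get("time_origin_s", 0.0),
            ablation_window_s=(
                tuple(d["ablation_window_s"]) if d.get("ablation_window_s") else None
            ),
        )


def _check_stack(frames: np.ndarray, what: str) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValidationError(f"{what} frames must be a 3D (t, row, col) array")
    if not np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float64)
    return frames


@dataclass
class EnvelopeSequence:
    """Time-ordered stack of non-negative envelope frames A(row, col; t)."""

    frames: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.frames = _check_stack(self.frames, "envelope")
        if np.any(self.frames < 0):
            raise ValidationError("envelope amplitudes must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        """Absolute acquisition time of each frame (strictly increasing)."""
        return self.meta.time_origin_s + np.arange(self.n_frames) / self.meta.frame_rate_hz

    def baseline_indices(self) -> np.ndarray:
        """Frames acquired before ablation onset (the pre-exposure baseline)."""
        if self.meta.ablation_window_s is None:
            raise MetadataError("no ablation window in metadata")
        idx = np.nonzero(self.times_s < self.meta.ablation_window_s[0])[0]
        if idx.size == 0:
            raise MetadataError("no frames precede ablation onset")
        return idx


@dataclass
class OpticalMovie:
    """Fluorescence movie F(row, col; t) with pacing metadata."""

    frames: np.ndarray
    meta: AcquisitionMeta
    pacing_cycle_ms: float

    def __post_init__(self) -> None:
        self.frames = _check_stack(self.frames, "optical")
        if not self.pacing_cycle_ms > 0:
            raise ValidationError("pacing_cycle_ms must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.meta.time_origin_s + np.arange(self.n_frames) / self.meta.frame_rate_hz

    def copy_with(self, frames: np.ndarray) -> "OpticalMovie":
        return OpticalMovie(frames=frames, meta=replace(self.meta), pacing_cycle_ms=self.pacing_cycle_ms)


@dataclass
class LesionMask:
    """Binary lesion mask with its provenance (histology modality or prediction)."""

    mask: np.ndarray
    provenance: str = "predicted"
    pixel_spacing_um: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2D")
        if self.provenance not in MASK_PROVENANCES:
            raise ValidationError(f"provenance must be one of {MASK_PROVENANCES}")

    @property
    def area_mm2(self) -> Optional[float]:
        if self.pixel_spacing_um is None:
            return None
        ax, lat = self.pixel_spacing_um
        return float(self.mask.sum() * ax * lat * 1e-6)


# ---------------------------------------------------------------------------
# stack / table I/O


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(obj: EnvelopeSequence | OpticalMovie, path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, obj.frames, photometric="minisblack")
    side = {"kind": "envelope" if isinstance(obj, EnvelopeSequence) else "optical",
            "meta": obj.meta.to_dict()}
    if isinstance(obj, OpticalMovie):
        side["pacing_cycle_ms"] = obj.pacing_cycle_ms
    _sidecar(path).write_text(json.dumps(side, indent=1))
    return path


def read_stack(path, kind: str):
    """Read a stack (``envelope`` or ``optical``) or an ``rgb`` image.

    Stacks require the JSON sidecar written by :func:`write_stack`; RGB
    images are plain PNG/TIFF and return a bare array.
    """
    path = Path(path)
    if kind == "rgb":
        img = np.asarray(iio.imread(path))
        if img.ndim != 3 or img.shape[2] < 3:
            raise ValidationError("rgb image must have 3 channels")
        return img[..., :3]
    if kind not in ("envelope", "optical"):
        raise ValueError(f"unknown kind {kind!r}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    side_path = _sidecar(path)
    if not side_path.exists():
        raise MetadataError(f"missing metadata sidecar {side_path}")
    side = json.loads(side_path.read_text())
    meta = AcquisitionMeta.from_dict(side["meta"])
    if kind == "envelope":
        if np.any(frames < 0):
            raise ValidationError("negative envelope values on disk")
        return EnvelopeSequence(frames=frames, meta=meta)
    return OpticalMovie(frames=frames, meta=meta,
                        pacing_cycle_ms=side.get("pacing_cycle_ms", 1000.0))


def write_mask(mask: LesionMask, path) -> Path:
    """Write a lesion mask as a 0/255 PNG."""
    path = Path(path)
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    return path


def read_mask(path, provenance: str = "predicted",
              pixel_spacing_um=None) -> LesionMask:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return LesionMask(mask=img > 127, provenance=provenance,
                      pixel_spacing_um=pixel_spacing_um)


def write_table(records: Sequence[dict], path, columns: Optional[Sequence[str]] = None) -> Path:
    """Write per-pixel or per-frame feature rows as CSV with a header.

    Column order is the key order of the first record (or ``columns``), so
    output is deterministic.  An empty record list yields a header-only file.
    """
    path = Path(path)
    if columns is None:
        columns = list(records[0].keys()) if len(records) else []
    df = pd.DataFrame.from_records(list(records), columns=list(columns))
    df.to_csv(path, index=False)
    return path


def envelope_from_rf(rf_frames: np.ndarray, sample_rate_hz: float,
                     meta: Optional[AcquisitionMeta] = None) -> EnvelopeSequence:
    """Envelope detection: magnitude of the analytic signal of each A-line.

    ``rf_frames`` is ``(t, scan_line, depth_sample)`` (a single frame may be
    passed as 2D).  The Hilbert transform runs along the depth-sample axis
    over the full line with no tapering; edge samples are retained.
    """
    rf = np.asarray(rf_frames, dtype=np.float64)
    if rf.ndim == 2:
        rf = rf[None]
    if rf.ndim != 3:
        raise ValidationError("rf_frames must be (t, line, sample) or (line, sample)")
    if rf.shape[-1] < 4:
        raise ValidationError("need at least 4 samples per A-line")
    env = np.abs(hilbert(rf, axis=-1))
    if meta is None:
        meta = AcquisitionMeta(frame_rate_hz=1.0, rf_sample_rate_hz=sample_rate_hz)
    else:
        meta = replace(meta, rf_sample_rate_hz=sample_rate_hz)
    return EnvelopeSequence(frames=env, meta=meta)
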