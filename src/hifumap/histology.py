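"""Lesion segmentation from RGB histology/gross images and co-registration.

Segmentation follows the color-clustering recipe used for Masson's
trichrome, TTC, and gross photographs: convert to L*a*b*, 2-class k-means on
the (a*, b*) chromaticity features, pick the lesion cluster by a color prior
(the paler / higher-L* class for MT and gross images, white necrosis for
TTC), then regularize the binary labels with an Ising-type Markov random
field smoothed by iterated conditional modes and a morphological closing.

Modalities are co-registered through fiducial landmark pairs with a
similarity transform (rotation + isotropic scale + translation); masks are
resampled nearest-neighbor, intensity images bilinearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import morphology
from skimage import transform as sktransform
from sklearn.cluster import KMeans

from .io import LesionMask, ValidationError

__all__ = [
    "LandmarkSet",
    "RigidTransform",
    "segment_lesion",
    "mrf_smooth",
    "compare_masks",
    "fit_landmark_transform",
    "apply_transform",
]


# ---------------------------------------------------------------------------
# segmentation


def mrf_smooth(labels: np.ndarray, unary: np.ndarray, beta: float = 1.0,
               max_iter: int = 10) -> np.ndarray:
    """Ising-prior label smoothing by iterated conditional modes.

    ``unary[k]`` is the data cost of assigning class k at each pixel (here
    the normalized squared distance to the k-means centroid); the pairwise
    term penalizes 4-neighbor disagreement with weight ``beta``.  Runs
    synchronous ICM sweeps until the labeling is stable.
    """
    lab = labels.astype(np.int8).copy()
    kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.float64)
    for _ in range(max_iter):
        n1 = ndimage.convolve(lab.astype(np.float64), kernel, mode="constant")
        n_nb = ndimage.convolve(np.ones_like(lab, dtype=np.float64), kernel,
                                mode="constant")
        e0 = unary[0] + beta * n1            # neighbors disagreeing with 0
        e1 = unary[1] + beta * (n_nb - n1)   # neighbors disagreeing with 1
        # ties (within float tolerance) keep the current label so clean
        # labelings are fixed points of the smoothing
        tol = 1e-9 * (1.0 + np.abs(e0) + np.abs(e1))
        new = np.where(e1 < e0 - tol, 1,
                       np.where(e0 < e1 - tol, 0, lab)).astype(np.int8)
        if np.array_equal(new, lab):
            break
        lab = new
    return lab.astype(bool)


def segment_lesion(rgb: np.ndarray, smoothing_weight: float = 1.0,
                   seed: int = 0, lesion_prior: str = "light",
                   closing_radius: int = 1, provenance: str = "predicted"
                   ) -> LesionMask:
    """Two-class lesion segmentation of an RGB histology/gross image.

    ``lesion_prior`` picks which k-means cluster is the lesion: ``light``
    (higher mean L*, the pale necrotic class — MT, gross, TTC white) or
    ``dark``.  ``smoothing_weight`` is the MRF pairwise weight; 0 disables
    the smoothing.  Deterministic for fixed ``seed``.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValidationError("need a 3-channel RGB image")
    lab = skcolor.rgb2lab(rgb[..., :3])
    feats = lab[..., 1:].reshape(-1, 2)           # (a*, b*)
    if float(np.ptp(feats, axis=0).max()) < 1e-6:
        raise ValidationError("single-color image: degenerate clustering")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(feats).reshape(rgb.shape[:2])
    d2 = km.transform(feats) ** 2
    unary = (d2 / d2.mean()).T.reshape(2, *rgb.shape[:2])
    if smoothing_weight > 0:
        smooth = mrf_smooth(labels, unary, beta=smoothing_weight)
    else:
        smooth = labels.astype(bool)
    l_mean = [lab[..., 0][smooth == k].mean() if np.any(smooth == k) else -np.inf
              for k in (False, True)]
    lesion_is_one = l_mean[1] > l_mean[0]
    if lesion_prior == "dark":
        lesion_is_one = not lesion_is_one
    elif lesion_prior != "light":
        raise ValidationError("lesion_prior must be 'light' or 'dark'")
    mask = smooth if lesion_is_one else ~smooth
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    return LesionMask(mask=mask, provenance=provenance)


def compare_masks(m1: LesionMask | np.ndarray, m2: LesionMask | np.ndarray,
                  pixel_spacing_um: Optional[tuple[float, float]] = None) -> dict:
    """Pixel-by-pixel match fraction, Dice on the lesion class, and areas.

    Areas are in mm² when a pixel spacing is available (from the masks or
    the argument); otherwise they are pixel counts under ``area*_px``.
    """
    a = m1.mask if isinstance(m1, LesionMask) else np.asarray(m1, dtype=bool)
    b = m2.mask if isinstance(m2, LesionMask) else np.asarray(m2, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("masks must share a grid (register first)")
    match = float(np.mean(a == b))
    inter = float(np.sum(a & b))
    denom = float(a.sum() + b.sum())
    dice = 2.0 * inter / denom if denom > 0 else 1.0
    out = {"match": match, "dice": dice,
           "area1_px": int(a.sum()), "area2_px": int(b.sum())}
    spacing = pixel_spacing_um
    for m in (m1, m2):
        if spacing is None and isinstance(m, LesionMask):
            spacing = m.pixel_spacing_um
    if spacing is not None:
        px_mm2 = spacing[0] * spacing[1] * 1e-6
        out["area1_mm2"] = out["area1_px"] * px_mm2
        out["area2_mm2"] = out["area2_px"] * px_mm2
    return out


# ---------------------------------------------------------------------------
# landmark registration


@dataclass
class LandmarkSet:
    """Ordered fiducial point pairs (row, col) linking two modalities."""

    source: np.ndarray
    target: np.ndarray
    source_modality: str = ""
    target_modality: str = ""

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=np.float64))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=np.float64))
        if self.source.shape != self.target.shape or self.source.shape[1] != 2:
            raise ValidationError("source/target must be matching (N, 2) arrays")
        if self.source.shape[0] < 2:
            raise ValidationError("need >= 2 landmark pairs for a similarity fit")
        if not (np.isfinite(self.source).all() and np.isfinite(self.target).all()):
            raise ValidationError("landmarks must be finite")
        if np.allclose(self.source, self.source[0]):
            raise ValidationError("source landmarks are coincident")


@dataclass
class RigidTransform:
    """Similarity transform: rotation, isotropic scale, translation (row, col)."""

    rotation_rad: float
    scale: float
    translation: tuple[float, float]
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("scale must be > 0")

    def _skimage(self) -> sktransform.SimilarityTransform:
        # skimage works in (x=col, y=row) coordinates
        return sktransform.SimilarityTransform(
            rotation=self.rotation_rad, scale=self.scale,
            translation=(self.translation[1], self.translation[0]))

    def apply_points(self, pts_rc: np.ndarray) -> np.ndarray:
        xy = np.asarray(pts_rc, dtype=np.float64)[:, ::-1]
        return self._skimage()(xy)[:, ::-1]

    def inverse(self) -> "RigidTransform":
        inv = sktransform.SimilarityTransform(matrix=np.linalg.inv(self._skimage().params))
        return RigidTransform(rotation_rad=float(inv.rotation), scale=float(inv.scale),
                              translation=(float(inv.translation[1]), float(inv.translation[0])))


def fit_landmark_transform(landmarks: LandmarkSet) -> RigidTransform:
    """Least-squares similarity transform from source to target landmarks.

    Exact (zero residual) whenever the landmark sets are truly related by a
    rotation + isotropic scale + translation.
    """
    src_xy = landmarks.source[:, ::-1]
    dst_xy = landmarks.target[:, ::-1]
    if hasattr(sktransform.SimilarityTransform, "from_estimate"):
        tf = sktransform.SimilarityTransform.from_estimate(src_xy, dst_xy)
        failed = not tf
    else:  # older scikit-image
        tf = sktransform.SimilarityTransform()
        failed = not tf.estimate(src_xy, dst_xy)
    if failed or not np.isfinite(tf.params).all():
        raise ValidationError("landmark fit failed (degenerate configuration)")
    resid = tf(landmarks.source[:, ::-1]) - landmarks.target[:, ::-1]
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(rotation_rad=float(tf.rotation), scale=float(tf.scale),
                          translation=(float(tf.translation[1]), float(tf.translation[0])),
                          residual_rms=rms)


def apply_transform(image: np.ndarray | LesionMask, tf: RigidTransform,
                    output_shape: Optional[tuple[int, int]] = None):
    """Resample an image or mask into the target grid under ``tf``.

    Masks use nearest-neighbor resampling, intensity images bilinear;
    out-of-bounds pixels become background (0 / False).
    """
    is_mask = isinstance(image, LesionMask)
    arr = image.mask.astype(np.float64) if is_mask else np.asarray(image, dtype=np.float64)
    if output_shape is None:
        output_shape = arr.shape[:2]
    if output_shape[0] < 1 or output_shape[1] < 1:
        raise ValidationError("empty target grid")
    warped = sktransform.warp(arr, inverse_map=tf._skimage().inverse,
                              output_shape=output_shape,
                              order=0 if is_mask else 1,
                              mode="constant", cval=0.0, preserve_range=True)
    if is_mask:
        return LesionMask(mask=warped > 0.5, provenance=image.provenance,
                          pixel_spacing_um=image.pixel_spacing_um)
    return warped
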