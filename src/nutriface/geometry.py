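"""Face alignment and cropping from 68-point landmarks.

Alignment rotates the image (and landmarks) about the midpoint between the
eye centers so that the line joining the eyes becomes horizontal.  Cropping
then applies a single similarity transform into a 300x300 frame: the face
midline (midpoint of the leftmost and rightmost landmarks) maps to x = 150,
the eye center to y = 30% of the height (row 90) and the mouth center to
y = 35% above the bottom (row 195).  Those three constraints determine the
uniform scale and translation exactly, so no intermediate crop box is needed.

Coordinates are 0-based with pixel centers at integer positions, x rightward
and y downward.  Raster warps use bilinear resampling with black fill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import SimilarityTransform, warp

__all__ = [
    "OUTPUT_SIZE",
    "EYE_ROW",
    "MOUTH_ROW",
    "AlignedFace",
    "eye_centers",
    "interocular_angle",
    "align",
    "crop",
]

OUTPUT_SIZE = 300
EYE_ROW = 0.30 * OUTPUT_SIZE  # 90
MOUTH_ROW = OUTPUT_SIZE - 0.35 * OUTPUT_SIZE  # 195

LEFT_EYE = slice(36, 42)
RIGHT_EYE = slice(42, 48)
MOUTH = slice(48, 68)


@dataclass
class AlignedFace:
    """A 300x300 face raster with landmarks in the same frame."""

    image: np.ndarray  # float in [0, 1], shape (300, 300) or (300, 300, 3)
    landmarks: np.ndarray  # (68, 2)


def _check_landmarks(landmarks: np.ndarray) -> np.ndarray:
    pts = np.asarray(landmarks, dtype=np.float64)
    if pts.shape != (68, 2):
        raise ValueError(f"expected 68 landmarks, got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("landmarks contain non-finite coordinates")
    return pts


def eye_centers(landmarks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroids of the two eye landmark groups, image-left first.

    Points 36-41 are the image-left eye and 42-47 the image-right eye; if a
    detector delivered them swapped, the pair is reordered so that the first
    returned center has the smaller x.
    """
    pts = _check_landmarks(landmarks)
    left = pts[LEFT_EYE].mean(axis=0)
    right = pts[RIGHT_EYE].mean(axis=0)
    if np.allclose(left, right):
        raise ValueError("eye centroids coincide: degenerate landmarks")
    if left[0] > right[0]:
        left, right = right, left
    return left, right


def interocular_angle(left: np.ndarray, right: np.ndarray) -> float:
    """Angle in degrees between the eye line and the horizontal.

    Positive when the image-right eye sits lower (larger y); folded to
    (-90, 90].
    """
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if np.allclose(left, right):
        raise ValueError("eye centers coincide")
    theta = np.degrees(np.arctan2(right[1] - left[1], right[0] - left[0]))
    if theta > 90.0:
        theta -= 180.0
    elif theta <= -90.0:
        theta += 180.0
    return float(theta)


def _warp(image: np.ndarray, tform: SimilarityTransform, output_shape=None):
    if image.size == 0:
        raise ValueError("empty image")
    return warp(
        image,
        tform.inverse,
        output_shape=output_shape,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )


def align(image: np.ndarray, landmarks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image and landmarks so the interocular line is horizontal.

    The rotation is rigid, about the midpoint between the eye centers, and is
    applied identically to the raster (bilinear, black fill) and to all 68
    landmark points.
    """
    pts = _check_landmarks(landmarks)
    image = np.asarray(image, dtype=np.float64)
    diag = float(np.hypot(*image.shape[:2]))
    if (pts.min() < -diag) or (pts.max() > max(image.shape[:2]) + diag):
        raise ValueError("landmarks lie implausibly far outside the image")
    left, right = eye_centers(pts)
    theta = interocular_angle(left, right)
    pivot = 0.5 * (left + right)
    phi = np.deg2rad(-theta)  # undo the measured tilt
    tform = (
        SimilarityTransform(translation=-pivot)
        + SimilarityTransform(rotation=phi)
        + SimilarityTransform(translation=pivot)
    )
    out = _warp(image, tform)
    return out, tform(pts)


def crop(image: np.ndarray, landmarks: np.ndarray) -> AlignedFace:
    """Map an aligned face into the canonical 300x300 frame.

    Requires a horizontal eye line (run :func:`align` first) and the mouth
    centroid below the eye centroid.  The uniform scale is fixed by the
    eye-to-mouth span covering 35% of the output height.
    """
    pts = _check_landmarks(landmarks)
    image = np.asarray(image, dtype=np.float64)
    left, right = eye_centers(pts)
    eye_c = 0.5 * (left + right)
    mouth_c = pts[MOUTH].mean(axis=0)
    if mouth_c[1] <= eye_c[1]:
        raise ValueError("mouth centroid not below eye centroid")
    mid_x = 0.5 * (pts[:, 0].min() + pts[:, 0].max())

    s = (MOUTH_ROW - EYE_ROW) / (mouth_c[1] - eye_c[1])
    # x' = s (x - mid_x) + 150 ; y' = s (y - eye_y) + 90
    translation = (
        OUTPUT_SIZE / 2.0 - s * mid_x,
        EYE_ROW - s * eye_c[1],
    )
    tform = SimilarityTransform(scale=s, translation=translation)
    out = _warp(image, tform, output_shape=(OUTPUT_SIZE, OUTPUT_SIZE))
    return AlignedFace(image=out, landmarks=tform(pts))


def crop_transform_mask(mask: np.ndarray, landmarks: np.ndarray) -> np.ndarray:
    """Carry a {0,255} mask through the same transform as :func:`crop`.

    Nearest-equivalent binarization: warp the {0,1} mask bilinearly and
    re-threshold at 0.5 so the output stays strictly binary.
    """
    pts = _check_landmarks(landmarks)
    warped = crop((np.asarray(mask) > 0).astype(np.float64), pts).image
    return np.where(warped >= 0.5, 255, 0).astype(np.uint8)
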