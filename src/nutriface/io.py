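"""File formats shared across the pipeline.

Images and masks are 8-bit PNG; masks are strictly binary {0, 255}.
Landmarks travel as CSV with header ``index,x,y`` (68 rows, pixel units,
origin top-left, x rightward, y downward).  Cohort metadata is a single CSV
with one row per subject.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

METADATA_COLUMNS = [
    "sample_id",
    "image_path",
    "mask_path",
    "landmarks_path",
    "nrs_score",
    "age_group",
    "gender",
    "site",
    "split",
]


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as float in [0, 1]; RGB(A) is kept, alpha dropped."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.astype(np.float64) / 255.0


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0, 1] (or uint8) array as an 8-bit PNG."""
    if image.dtype != np.uint8:
        image = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, image)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG, enforcing values in {0, 255}."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    arr = arr.astype(np.uint8)
    validate_mask(arr)
    return arr


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask, dtype=np.uint8)
    validate_mask(mask)
    iio.imwrite(path, mask)


def validate_mask(mask: np.ndarray) -> None:
    vals = np.unique(mask)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(f"mask is not binary {{0,255}}: found values {vals[:10]}")


def load_landmarks(path: str | Path) -> np.ndarray:
    """Read a 68x2 landmark array from ``index,x,y`` CSV, ordered by index."""
    df = pd.read_csv(path)
    df = df.sort_values("index")
    pts = df[["x", "y"]].to_numpy(dtype=np.float64)
    if pts.shape != (68, 2):
        raise ValueError(f"expected 68 landmarks, got {pts.shape[0]} in {path}")
    return pts


def save_landmarks(path: str | Path, points: np.ndarray) -> None:
    points = np.asarray(points, dtype=np.float64)
    if points.shape != (68, 2):
        raise ValueError(f"expected shape (68, 2), got {points.shape}")
    df = pd.DataFrame(
        {"index": np.arange(68), "x": points[:, 0], "y": points[:, 1]}
    )
    df.to_csv(path, index=False)


def load_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


def save_metadata(path: str | Path, df: pd.DataFrame) -> None:
    df[METADATA_COLUMNS].to_csv(path, index=False)
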