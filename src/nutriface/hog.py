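"""Dense histogram-of-oriented-gradients descriptor.

Dalal-Triggs style HOG with the parameterization used throughout this
package: 8x8-pixel cells, 2x2-cell blocks at 1-cell stride, 9 unsigned
orientation bins with centers at i*pi/9, bilinear splitting of each pixel's
magnitude vote between the two nearest bin centers, and L2-Hys block
normalization (L2-normalize, clip at 0.2, renormalize).  Partial cells at
the image border are truncated.  For a 300x300 image this yields
37 cells -> 36 overlapping blocks per axis and 36*36*36 = 46,656 features.

Gradients use centered differences [-1, 0, 1] with replicated borders.
Blocks are concatenated row-major; within a block, cells row-major, bins
ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HogParams", "hog_length", "hog"]

_EPS = 1e-12


@dataclass(frozen=True)
class HogParams:
    cell_px: int = 8
    cells_per_block_side: int = 2
    bins: int = 9
    block_stride_cells: int = 1
    clip: float = 0.2

    def __post_init__(self) -> None:
        if self.cell_px < 2:
            raise ValueError("cell_px must be >= 2")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.block_stride_cells != 1:
            raise ValueError("only 1-cell block stride is supported")


def hog_length(width: int, height: int, params: HogParams = HogParams()) -> int:
    """Descriptor length for a width x height image.

    Cells that do not fit entirely are truncated; blocks slide one cell at a
    time, so there are ``n_cells - cells_per_block + 1`` block positions per
    axis, each contributing ``cells_per_block**2 * bins`` features.
    """
    c, b = params.cell_px, params.cells_per_block_side
    if width < c * b or height < c * b:
        raise ValueError("image smaller than one block")
    nbx = width // c - b + 1
    nby = height // c - b + 1
    return nbx * nby * b * b * params.bins


def _gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    padded = np.pad(image, 1, mode="edge")
    gx = 0.5 * (padded[1:-1, 2:] - padded[1:-1, :-2])
    gy = 0.5 * (padded[2:, 1:-1] - padded[:-2, 1:-1])
    return gx, gy


def _cell_histograms(image: np.ndarray, params: HogParams) -> np.ndarray:
    c, nbins = params.cell_px, params.bins
    h, w = image.shape
    ncy, ncx = h // c, w // c
    gx, gy = _gradients(image)
    gx = gx[: ncy * c, : ncx * c]
    gy = gy[: ncy * c, : ncx * c]

    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)  # unsigned, [0, pi)
    binw = np.pi / nbins
    f = ang / binw
    i0 = np.floor(f).astype(np.int64)
    frac = f - i0
    i0 = np.mod(i0, nbins)
    i1 = np.mod(i0 + 1, nbins)

    rows, cols = np.indices(mag.shape)
    cell_idx = (rows // c) * ncx + (cols // c)
    base = cell_idx * nbins
    size = ncy * ncx * nbins
    hist = np.bincount(
        (base + i0).ravel(), weights=(mag * (1.0 - frac)).ravel(), minlength=size
    )
    hist += np.bincount(
        (base + i1).ravel(), weights=(mag * frac).ravel(), minlength=size
    )
    return hist.reshape(ncy, ncx, nbins)


def _l2_hys(blocks: np.ndarray, clip: float) -> np.ndarray:
    norm = np.linalg.norm(blocks, axis=-1, keepdims=True)
    out = np.divide(blocks, norm, out=np.zeros_like(blocks), where=norm > _EPS)
    out = np.minimum(out, clip)
    norm2 = np.linalg.norm(out, axis=-1, keepdims=True)
    return np.divide(out, norm2, out=np.zeros_like(out), where=norm2 > _EPS)


def hog(image: np.ndarray, params: HogParams = HogParams()) -> np.ndarray:
    """Compute the HOG descriptor of a grayscale image in [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("hog expects a single-channel image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    b = params.cells_per_block_side
    if min(image.shape) < params.cell_px * b:
        raise ValueError("image smaller than one block")

    hist = _cell_histograms(image, params)
    # sliding 2x2-cell windows, row-major: axes (by, bx, cell_y, cell_x, bin)
    windows = np.lib.stride_tricks.sliding_window_view(hist, (b, b), axis=(0, 1))
    # sliding_window_view puts window axes last: (by, bx, bin, cy, cx)
    windows = np.moveaxis(windows, 2, -1)  # (by, bx, cy, cx, bin)
    nby, nbx = windows.shape[:2]
    blocks = windows.reshape(nby * nbx, b * b * params.bins)
    return _l2_hys(blocks, params.clip).ravel()
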