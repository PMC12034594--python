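"""Frame preprocessing: border cropping, Gaussian denoising, CLAHE.

The fixed pipeline order is crop -> Gaussian blur -> CLAHE: denoising
must precede local contrast enhancement, otherwise CLAHE amplifies the
very noise the blur is meant to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.exposure import equalize_adapthist

_CLAHE_BINS = 256  # histogram bins assumed by the clip-limit convention


class UniformImageError(ValueError):
    """The image is entirely uniform: there is no content to crop to."""


@dataclass
class PreprocessParams:
    """Tunables for the preprocessing stage.

    ``clahe_clip_limit`` uses the familiar OpenCV-style convention (a
    multiple of the mean histogram bin height); it is converted to the
    histogram-fraction convention internally.
    """

    blur_sigma: float = 1.5  # px
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    border_uniformity_tol: float = 2.0  # intensity units on the 8-bit scale

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.clahe_tile_grid[0] < 1 or self.clahe_tile_grid[1] < 1:
            raise ValueError("clahe_tile_grid must be at least (1, 1)")


def _uniform_run(arr2d: np.ndarray, tol: float) -> int:
    """Number of leading rows of ``arr2d`` whose intensity range is <= tol."""
    if arr2d.size == 0:
        return 0
    rng = arr2d.max(axis=1) - arr2d.min(axis=1)
    uniform = rng <= tol
    if uniform.all():
        return len(uniform)
    return int(np.argmin(uniform))


def crop_borders(
    image: np.ndarray, tol: float = 2.0
) -> tuple[np.ndarray, tuple[int, int]]:
    """Strip maximal uniform margins from the four image edges.

    A margin row/column counts as uniform when its intensity range is at
    most ``tol``.  Edges are re-scanned until a fixed point, which makes
    the operation idempotent even when removing columns turns an edge row
    uniform.  Returns the cropped view and the (row, col) offset mapping
    cropped coordinates back to the original image.

    Raises :class:`UniformImageError` for an entirely uniform image.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    work = img.astype(float)
    r0, c0 = 0, 0
    r1, c1 = img.shape
    changed = True
    while changed:
        changed = False
        view = work[r0:r1, c0:c1]
        if view.size == 0:
            raise UniformImageError("image is entirely uniform; nothing to crop to")
        top = _uniform_run(view, tol)
        if top == view.shape[0]:
            raise UniformImageError("image is entirely uniform; nothing to crop to")
        bottom = _uniform_run(view[::-1], tol)
        r0 += top
        r1 -= bottom
        view = work[r0:r1, c0:c1]
        left = _uniform_run(view.T, tol)
        if left == view.shape[1]:
            raise UniformImageError("image is entirely uniform; nothing to crop to")
        right = _uniform_run(view.T[::-1], tol)
        c0 += left
        c1 -= right
        changed = bool(top or bottom or left or right)
    return img[r0:r1, c0:c1], (r0, c0)


def enhance(image: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """Gaussian blur followed by CLAHE, preserving the input's range convention.

    uint8 input yields uint8 output; float input (assumed in [0, 1]) yields
    float output in [0, 1].  Shape is always preserved.
    """
    if params is None:
        params = PreprocessParams()
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    is_int = np.issubdtype(img.dtype, np.integer)
    work = img.astype(float) / 255.0 if is_int else img.astype(float)
    work = np.clip(work, 0.0, 1.0)
    if params.blur_sigma > 0:
        work = gaussian_filter(work, params.blur_sigma)
    gr, gc = params.clahe_tile_grid
    kernel = (max(1, img.shape[0] // gr), max(1, img.shape[1] // gc))
    out = equalize_adapthist(
        work, kernel_size=kernel, clip_limit=params.clahe_clip_limit / _CLAHE_BINS
    )
    if is_int:
        return np.clip(out * 255.0, 0, 255).round().astype(np.uint8)
    return out
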