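"""Elementary geometry operators on square particle images.

Conventions (fixed project-wide):

* Images are ``m x m`` float arrays, row index = y (down), column index = x
  (right).
* The rotation/polar center is the pixel at 0-based index ``(m//2, m//2)``.
* Positive rotation angles are counter-clockwise in the mathematical frame
  (y up); because rows grow downward this is realized by the ``-sin`` term in
  the polar sampler.
* Positive ``dx`` moves content toward higher columns, positive ``dy`` toward
  higher rows.
* Subpixel translation is exact Fourier phase modulation (circular); rotation
  is real-space bilinear resampling with zero fill outside the source.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.fft import fft2, ifft2

__all__ = [
    "as_square",
    "center_index",
    "rotate_image",
    "shift_image",
    "polar_resample",
    "rotate_shift_vector",
]


def as_square(img) -> np.ndarray:
    """Validate and return a square, finite, float image."""
    a = np.asarray(img, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def center_index(m: int) -> int:
    """0-based index of the rotation center along each axis."""
    return m // 2


def rotate_image(img, angle_deg: float) -> np.ndarray:
    """Rotate ``img`` by ``angle_deg`` (counter-clockwise) about its center.

    Bilinear interpolation; samples falling outside the source are zero.
    """
    a = as_square(img)
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    m = a.shape[0]
    c = center_index(m)
    t = np.deg2rad(float(angle_deg))
    ct, st = np.cos(t), np.sin(t)
    # Inverse map from output (row, col) to source coordinates, derived from
    # the y-up rotation x' = x cos - y sin, y' = x sin + y cos.
    matrix = np.array([[ct, st], [-st, ct]])
    offset = np.array([c * (1.0 - ct - st), c * (1.0 - ct + st)])
    return ndimage.affine_transform(
        a, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )


def shift_image(img, dx: float, dy: float) -> np.ndarray:
    """Translate ``img`` by (+dx columns, +dy rows) via Fourier phase shift.

    Exact for band-limited content and circular at the borders, so integer
    shifts coincide with ``np.roll`` of the pixel grid.
    """
    a = as_square(img)
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("shift components must be finite")
    if dx == 0 and dy == 0:
        return a.copy()
    f = ndimage.fourier_shift(fft2(a), (float(dy), float(dx)))
    return ifft2(f).real


def polar_resample(img) -> np.ndarray:
    """Resample ``img`` onto a polar grid of shape ``(m//2, 360)``.

    Row ``r`` holds radius ``r + 1`` pixels (the center sample is excluded:
    it carries no angular information); column ``t`` holds angle ``t`` degrees,
    sampled at ``(cx + r cos t, cy - r sin t)`` with bilinear interpolation and
    zero outside the image. Rotating the source by an integer number of
    degrees circularly permutes the columns.
    """
    a = as_square(img)
    m = a.shape[0]
    if m < 16:
        raise ValueError(f"image side must be >= 16 pixels, got {m}")
    c = center_index(m)
    radii = np.arange(1, m // 2 + 1, dtype=float)
    theta = np.deg2rad(np.arange(360, dtype=float))
    cols = c + radii[:, None] * np.cos(theta)[None, :]
    rows = c - radii[:, None] * np.sin(theta)[None, :]
    return ndimage.map_coordinates(
        a, [rows, cols], order=1, mode="constant", cval=0.0
    )


def rotate_shift_vector(dx: float, dy: float, angle_deg: float) -> tuple[float, float]:
    """Rotate a pixel-space shift vector by ``angle_deg``.

    Matches the action of ``rotate_image`` on translations, i.e.
    ``rotate(shift(I, dx, dy), a) == shift(rotate(I, a), *rotate_shift_vector(dx, dy, a))``
    for content away from the borders.
    """
    t = np.deg2rad(float(angle_deg))
    ct, st = np.cos(t), np.sin(t)
    # y is down in pixel coordinates, hence the sign flip versus the y-up form
    return ct * dx + st * dy, -st * dx + ct * dy
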