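"""Frequency-domain rotational, translational and joint image alignment.

Rotation is estimated from the cross-correlation of the 2-D FFTs of the polar
resamplings of the two images (a rotation becomes a circular shift along the
angular axis, so the correlation peak column encodes the angle).  Translation
is estimated from standard FFT cross-correlation of the images themselves.
In both cases the integer-resolution peak can be refined to 0.1 grid units by
not-a-knot bicubic spline interpolation of the 11x11 patch around the peak
onto a 101x101 grid — the interpolated variant (``interpolate=True``) versus
the plain integer readout.

Joint alignment alternates the two estimates, warping a working copy and
accumulating parameters so the final aligned image is produced in a single
rotate-then-shift composition from the *original* input, avoiding accumulated
interpolation blur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft2, ifft2
from scipy.interpolate import CubicSpline

from .imageops import (
    as_square,
    center_index,
    polar_resample,
    rotate_image,
    rotate_shift_vector,
    shift_image,
)

__all__ = [
    "CrossCorrelationMatrix",
    "RefinedPeak",
    "AlignmentParams",
    "Aligner",
    "polar_spectrum",
    "rotation_cross_correlation",
    "translation_cross_correlation",
    "refine_peak",
    "correct_angle",
    "peak_to_shifts",
    "estimate_rotation",
    "estimate_shift",
    "joint_align",
]

REFINE_WINDOW = 11
REFINE_UPSAMPLED = 101  # 11 nodes re-gridded at 0.1 steps


@dataclass(frozen=True)
class CrossCorrelationMatrix:
    """Discrete correlation surface whose peak encodes the alignment."""

    values: np.ndarray
    centered: bool = True

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cross-correlation surface contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class RefinedPeak:
    """Subgrid peak location after spline refinement (0-based grid units)."""

    row: float
    col: float
    patch: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class AlignmentParams:
    """Accumulated alignment of a test image onto a reference."""

    theta: float  # degrees in [-180, 180]
    dx: float  # pixels, + = rightward
    dy: float  # pixels, + = downward
    n_iter: int
    converged: bool


def polar_spectrum(img) -> np.ndarray:
    """2-D FFT of the polar resampling of ``img`` (shape ``(m//2, 360)``)."""
    return fft2(polar_resample(img))


def rotation_cross_correlation(Fi, Fj) -> CrossCorrelationMatrix:
    """Rotational correlation surface ``abs(ifft2(Fi * conj(Fj)))``.

    Rows (the radial axis) are circularly shifted by half their count to
    center the large values; the rotation angle is read from the column axis,
    which is left uncentered so column 0 corresponds to 0 degrees.
    """
    Fi = np.asarray(Fi)
    Fj = np.asarray(Fj)
    if Fi.shape != Fj.shape:
        raise ValueError(f"spectrum shapes differ: {Fi.shape} vs {Fj.shape}")
    c = np.abs(ifft2(Fi * np.conj(Fj)))
    c = np.roll(c, c.shape[0] // 2, axis=0)
    return CrossCorrelationMatrix(c, centered=True)


def translation_cross_correlation(Mi, Mj) -> CrossCorrelationMatrix:
    """Translational correlation surface ``ifft2(fft2(Mi) * conj(fft2(Mj)))``.

    The real part is taken (the imaginary part of the inverse transform of a
    real-image cross-spectrum is floating noise) and the surface is
    fftshift-centered so zero displacement peaks at ``(m//2, m//2)``.
    """
    a = as_square(Mi)
    b = as_square(Mj)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    c = ifft2(fft2(a) * np.conj(fft2(b))).real
    c = np.fft.fftshift(c)
    return CrossCorrelationMatrix(c, centered=True)


def _spline_upsample(patch: np.ndarray, fine_r: np.ndarray, fine_c: np.ndarray,
                     node_r: np.ndarray, node_c: np.ndarray) -> np.ndarray:
    """Tensor-product not-a-knot cubic spline evaluation (MATLAB interp2 'spline')."""
    along_rows = CubicSpline(node_r, patch, axis=0, bc_type="not-a-knot")(fine_r)
    return CubicSpline(node_c, along_rows, axis=1, bc_type="not-a-knot")(fine_c)


def refine_peak(C: CrossCorrelationMatrix, window: int = REFINE_WINDOW,
                upsample_to: int = REFINE_UPSAMPLED, wrap_cols: bool = False,
                ) -> RefinedPeak:
    """Refine the integer argmax of ``C`` to 0.1-grid-unit resolution.

    An ``window x window`` patch centered on the argmax (ties broken toward
    the smallest row, then column) is spline-interpolated onto a grid with
    0.1-unit steps and the interpolated argmax is mapped back to grid
    coordinates.  The angular (column) axis wraps circularly when
    ``wrap_cols``; otherwise the window slides inward at borders.  A flat
    patch is reported degenerate and the coarse peak is returned unchanged.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    v = C.values
    nrows, ncols = v.shape
    pr, pc = np.unravel_index(int(np.argmax(v)), v.shape)  # row-major: smallest row, col

    half = window // 2
    # radial / non-periodic axes: slide the window so it stays on-grid
    wr = min(window, nrows)
    r0 = int(np.clip(pr - wr // 2, 0, nrows - wr))
    row_nodes = np.arange(r0, r0 + wr, dtype=float)

    if wrap_cols:
        col_nodes = np.arange(pc - half, pc + half + 1, dtype=float)  # unwrapped
        col_idx = np.mod(col_nodes.astype(int), ncols)
    else:
        wc = min(window, ncols)
        c0 = int(np.clip(pc - wc // 2, 0, ncols - wc))
        col_nodes = np.arange(c0, c0 + wc, dtype=float)
        col_idx = col_nodes.astype(int)

    patch = v[np.ix_(np.arange(r0, r0 + wr), col_idx)]
    if np.ptp(patch) == 0.0:
        return RefinedPeak(float(pr), float(pc % ncols), patch, degenerate=True)

    fine_r = row_nodes[0] + 0.1 * np.arange(10 * (len(row_nodes) - 1) + 1)
    fine_c = col_nodes[0] + 0.1 * np.arange(10 * (len(col_nodes) - 1) + 1)
    fine = _spline_upsample(patch, fine_r, fine_c, row_nodes, col_nodes)

    fr, fc = np.unravel_index(int(np.argmax(fine)), fine.shape)
    row, col = fine_r[fr], fine_c[fc]
    if abs(row - pr) > 0.5 or abs(col - pc) > 0.5:
        # spline overshoot away from the peak cell: keep the refinement local
        rmask = np.abs(fine_r - pr) <= 0.5
        cmask = np.abs(fine_c - pc) <= 0.5
        local = fine[np.ix_(rmask, cmask)]
        fr, fc = np.unravel_index(int(np.argmax(local)), local.shape)
        row, col = fine_r[rmask][fr], fine_c[cmask][fc]
    return RefinedPeak(float(row), float(np.mod(col, ncols)), fine)


def correct_angle(raw_deg: float) -> float:
    """Fold a raw peak angle in [0, 360) into the signed range [-180, 180]."""
    if not (0.0 <= raw_deg < 360.0):
        raise ValueError(f"raw angle must lie in [0, 360), got {raw_deg}")
    return raw_deg if raw_deg <= 180.0 else raw_deg - 360.0


def peak_to_shifts(x: float, y: float, m: int) -> tuple[float, float]:
    """Map a 1-based correlation-peak position to pixel displacements.

    ``dx = m//2 - x + 1`` and likewise for y: the center position
    ``(m//2 + 1, m//2 + 1)`` maps to zero displacement.
    """
    half = m // 2
    return half - x + 1.0, half - y + 1.0


def _check_structured(img: np.ndarray, what: str) -> None:
    if np.ptp(img) == 0.0:
        raise ValueError(f"{what} image is constant; alignment peak is undefined")


class Aligner:
    """Alignment of test images onto one fixed reference.

    Caches the reference's polar and plain spectra so that aligning many
    images (or iterating) does not recompute them.
    """

    def __init__(self, reference, interpolate: bool = True):
        self.reference = as_square(reference)
        _check_structured(self.reference, "reference")
        self.m = self.reference.shape[0]
        self.interpolate = bool(interpolate)
        self._f_polar = polar_spectrum(self.reference)
        self._f = fft2(self.reference)

    # -- single-parameter estimates ------------------------------------

    def rotation(self, img) -> float:
        """Angle (degrees) to rotate ``img`` by so it matches the reference."""
        a = as_square(img)
        if a.shape[0] != self.m:
            raise ValueError("image size differs from the reference")
        _check_structured(a, "test")
        c = rotation_cross_correlation(self._f_polar, polar_spectrum(a))
        ncols = c.shape[1]
        if self.interpolate:
            peak = refine_peak(c, wrap_cols=True)
            raw = round(peak.col * (360.0 / ncols), 1) % 360.0
        else:
            pc = int(np.unravel_index(int(np.argmax(c.values)), c.shape)[1])
            raw = float(pc) * (360.0 / ncols)
        return correct_angle(raw)

    def shift(self, img) -> tuple[float, float]:
        """(dx, dy) in pixels to shift ``img`` by so it matches the reference."""
        a = as_square(img)
        if a.shape[0] != self.m:
            raise ValueError("image size differs from the reference")
        _check_structured(a, "test")
        c = translation_cross_correlation(self.reference, a)
        if self.interpolate:
            peak = refine_peak(c, wrap_cols=False)
            row, col = peak.row, peak.col
        else:
            row, col = np.unravel_index(int(np.argmax(c.values)), c.shape)
        # 1-based peak position; the raw result is the displacement of the
        # test image relative to the reference, so negate it to correct
        sx, sy = peak_to_shifts(col + 1.0, row + 1.0, self.m)
        dx, dy = -sx, -sy
        if self.interpolate:
            dx, dy = round(dx, 1), round(dy, 1)
        return float(dx), float(dy)

    # -- joint alignment -----------------------------------------------

    def align(self, img, max_iter: int = 10) -> tuple[AlignmentParams, np.ndarray]:
        """Alternate rotation/translation estimates until they stop changing.

        Returns the accumulated parameters and the aligned image produced
        from the original input by one shift(rotate(.)) composition.
        """
        if max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        a = as_square(img)
        work = a
        theta, dx, dy = 0.0, 0.0, 0.0
        prev = None
        n_iter = 0
        converged = False
        for _ in range(max_iter):
            n_iter += 1
            dth = self.rotation(work)
            work = rotate_image(work, dth)
            ddx, ddy = self.shift(work)
            work = shift_image(work, ddx, ddy)
            # rotate the running shift into the new frame before accumulating
            dx, dy = rotate_shift_vector(dx, dy, dth)
            dx, dy = dx + ddx, dy + ddy
            theta += dth
            cur = (dth, ddx, ddy)
            if prev is not None and all(abs(u - v) < 1e-6 for u, v in zip(cur, prev)):
                converged = True
                break
            prev = cur
        theta = (theta + 180.0) % 360.0 - 180.0
        if theta == -180.0:
            theta = 180.0
        aligned = shift_image(rotate_image(a, theta), dx, dy)
        params = AlignmentParams(theta, dx, dy, n_iter, converged)
        return params, aligned


def estimate_rotation(Mi, Mj, interpolate: bool = True) -> float:
    """Angle (degrees, [-180, 180]) rotating ``Mj`` onto the reference ``Mi``."""
    return Aligner(Mi, interpolate=interpolate).rotation(Mj)


def estimate_shift(Mi, Mj, interpolate: bool = True) -> tuple[float, float]:
    """(dx, dy) in pixels shifting ``Mj`` onto the reference ``Mi``."""
    return Aligner(Mi, interpolate=interpolate).shift(Mj)


def joint_align(Mref, M, max_iter: int = 10, interpolate: bool = True,
                ) -> tuple[AlignmentParams, np.ndarray]:
    """Rotational + translational alignment of ``M`` onto ``Mref``."""
    return Aligner(Mref, interpolate=interpolate).align(M, max_iter=max_iter)
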