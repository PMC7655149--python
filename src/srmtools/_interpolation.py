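"""Shared bicubic-spline sampling helpers.

One interpolation convention is used everywhere in the toolkit: cubic
B-spline (``order=3``) evaluation via :func:`scipy.ndimage.map_coordinates`,
pixel centres at integer (row, col) coordinates, x = col and y = row, and
samples outside the image domain evaluating to 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["bicubic_sample", "translate", "spline_coefficients", "sample_prefiltered"]


def spline_coefficients(image: np.ndarray) -> np.ndarray:
    """Precompute cubic-spline coefficients for repeated sampling."""
    return ndimage.spline_filter(np.asarray(image, dtype=float), order=3, mode="mirror")


def sample_prefiltered(coeffs: np.ndarray, rows, cols) -> np.ndarray:
    """Evaluate a prefiltered image at continuous (row, col) positions.

    Out-of-domain positions return 0.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    out = ndimage.map_coordinates(
        coeffs, [rows.ravel(), cols.ravel()], order=3, prefilter=False, mode="mirror"
    ).reshape(rows.shape)
    h, w = coeffs.shape
    inside = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    return np.where(inside, out, 0.0)


def bicubic_sample(image: np.ndarray, rows, cols) -> np.ndarray:
    """Bicubic sample of ``image`` at continuous (row, col) positions; 0 outside."""
    return sample_prefiltered(spline_coefficients(image), rows, cols)


def translate(frame: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Translate frame content by (+dx, +dy) pixels with bicubic interpolation.

    ``out[r, c] = frame[r - dy, c - dx]``; regions translated in from outside
    the original domain are 0. A zero shift returns an unmodified copy.
    """
    frame = np.asarray(frame, dtype=float)
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("translation shift must be finite")
    if dx == 0.0 and dy == 0.0:
        return frame.copy()
    h, w = frame.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    return bicubic_sample(frame, rr - dy, cc - dx)
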