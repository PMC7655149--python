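"""Super-resolution radial fluctuations (SRRF) reconstruction.

A PSF-sized fluorescent spot is radially symmetric: the intensity gradient
everywhere in its neighbourhood points at its centre. *Radiality* quantifies
this convergence on a grid magnified M-fold relative to the camera pixels:
around each magnified-grid point a ring of gradient samples is taken, and
each sample votes by how close the line through it along its gradient passes
to the point, positively when the gradient points inward and negatively when
it points outward. Diffraction cannot stop the radiality peak from being
much sharper than the PSF, so when fluorophores blink, per-frame radiality
maps fluctuate with the underlying emitters and a temporal projection of the
radiality stack (mean, maximum, or a lag-1 auto-cumulant that suppresses
temporally uncorrelated noise) yields a super-resolved image from a short
movie — no localisation step required.

Drift is consumed during analysis by offsetting each frame's sampling grid
with the drift-table entry; the raw frames are never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._interpolation import sample_prefiltered, spline_coefficients
from .exceptions import ValidationError
from .image_io import DriftTable, ImageStack

__all__ = [
    "SRRFParams",
    "RadialityStack",
    "gradient_field",
    "radiality_frame",
    "temporal_projection",
    "srrf_reconstruct",
]


@dataclass
class SRRFParams:
    magnification: int = 5
    ring_radius_px: float = 0.5  # in source-pixel units
    n_ring_samples: int = 12
    temporal_mode: str = "TRA"  # TRA | TRM | TRAC2
    intensity_weighting: bool = False
    drift_table: DriftTable | None = None

    def __post_init__(self) -> None:
        if self.magnification < 1:
            raise ValidationError("magnification must be >= 1")
        if not self.ring_radius_px > 0:
            raise ValidationError("ring_radius_px must be positive")
        if self.n_ring_samples < 4:
            raise ValidationError("need at least 4 ring samples")
        if self.temporal_mode not in ("TRA", "TRM", "TRAC2"):
            raise ValidationError("temporal_mode must be TRA, TRM or TRAC2")


@dataclass
class RadialityStack:
    frames: np.ndarray  # (t, rows*M, cols*M)
    params: SRRFParams = field(default_factory=SRRFParams)


def gradient_field(frame: np.ndarray):
    """Centred-difference intensity gradients plus a continuous evaluator.

    Returns ``(gx, gy, evaluate)`` where ``evaluate(x, y)`` gives
    bicubic-interpolated ``(gx, gy)`` at continuous positions. Borders are
    edge-replicated, so a linear ramp has its exact gradient at every
    interior point and a constant frame has zero gradient everywhere.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise ValidationError("frame must be 2D and at least 3x3")
    p = np.pad(frame, 1, mode="edge")
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    cx = spline_coefficients(gx)
    cy = spline_coefficients(gy)

    def evaluate(x, y):
        return (sample_prefiltered(cx, np.asarray(y, float), np.asarray(x, float)),
                sample_prefiltered(cy, np.asarray(y, float), np.asarray(x, float)))

    return gx, gy, evaluate


def _magnified_grid(shape: tuple[int, int], magnification: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Source-space (y, x) coordinates of the magnified grid's pixel centres."""
    h, w = shape
    m = magnification
    ys = (np.arange(h * m, dtype=float) + 0.5) / m - 0.5
    xs = (np.arange(w * m, dtype=float) + 0.5) / m - 0.5
    return np.meshgrid(ys, xs, indexing="ij")


def radiality_frame(frame: np.ndarray, params: SRRFParams,
                    grid_offset_xy: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Radiality of one frame on the magnification-times-finer grid.

    For each magnified-grid point p, ``n_ring_samples`` points are taken on
    a circle of ``ring_radius_px`` around it. A sample with gradient g votes
    ``s * max(0, 1 - d/R)`` where d is the perpendicular distance from p to
    the line through the sample along g and s is +1 if g points toward p,
    -1 otherwise; zero-gradient samples abstain. Radiality is the mean vote,
    clipped below at 0 (diverging gradients mark dark spots, not emitters).

    ``grid_offset_xy`` shifts the sampling grid in source-pixel units; drift
    correction passes the frame's drift here so the output grids of all
    frames coincide without resampling the raw data.
    """
    frame = np.asarray(frame, dtype=float)
    gx_r, gy_r, grad = gradient_field(frame)
    py, px = _magnified_grid(frame.shape, params.magnification)
    px = px + grid_offset_xy[0]
    py = py + grid_offset_xy[1]

    R = params.ring_radius_px
    votes = np.zeros_like(px)
    angles = 2.0 * np.pi * np.arange(params.n_ring_samples) / params.n_ring_samples
    # samples whose gradient is zero at working precision abstain: their
    # direction (and hence the inward test) would be numerical noise
    floor = 1e-9 * max(np.abs(gx_r).max(), np.abs(gy_r).max())
    for a in angles:
        sx = px + R * np.cos(a)
        sy = py + R * np.sin(a)
        gxs, gys = grad(sx, sy)
        gm = np.hypot(gxs, gys)
        dx = px - sx
        dy = py - sy
        perp = np.abs(gxs * dy - gys * dx) / np.maximum(gm, 1e-300)
        inward = (gxs * dx + gys * dy) > 0
        vote = np.where(inward, 1.0, -1.0) * np.maximum(0.0, 1.0 - perp / R)
        votes += np.where(gm > floor, vote, 0.0)
    rad = np.clip(votes / params.n_ring_samples, 0.0, None)

    if params.intensity_weighting:
        coeffs = spline_coefficients(frame)
        rad = rad * np.clip(sample_prefiltered(coeffs, py, px), 0.0, None)
    return rad


def temporal_projection(rad: RadialityStack | np.ndarray,
                        mode: str = "TRA") -> np.ndarray:
    """Project a radiality time series into one super-resolved image.

    TRA is the per-pixel temporal mean, TRM the temporal maximum, and TRAC2
    the lag-1 temporal auto-cumulant ``mean_t[(R_t - mean(R))(R_{t+1} -
    mean(R))]`` clipped below at 0 — fluorophore-driven fluctuations survive
    it while temporally uncorrelated noise averages out.
    """
    frames = rad.frames if isinstance(rad, RadialityStack) else np.asarray(rad, float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValidationError("need a (t, rows, cols) radiality stack")
    if mode == "TRA":
        return frames.mean(axis=0)
    if mode == "TRM":
        return frames.max(axis=0)
    if mode == "TRAC2":
        if frames.shape[0] < 2:
            raise ValidationError("TRAC2 needs at least 2 frames")
        centred = frames - frames.mean(axis=0)
        return np.clip((centred[:-1] * centred[1:]).mean(axis=0), 0.0, None)
    raise ValidationError(f"unknown temporal mode {mode!r}")


def srrf_reconstruct(stack: ImageStack, params: SRRFParams | None = None
                     ) -> ImageStack:
    """SRRF reconstruction of a fluctuation movie.

    Computes per-frame radiality on the magnified grid (offset by each
    frame's drift when a drift table is supplied) and applies the temporal
    projection. The result is a single-frame stack whose pixel size is the
    input pixel size divided by the magnification.
    """
    params = params or SRRFParams()
    if stack.n_frames < 2:
        raise ValidationError("SRRF needs at least 2 frames")
    if params.drift_table is not None:
        rad = []
        for t in range(stack.n_frames):
            dx, dy = params.drift_table.shift(t)  # raises on missing frames
            rad.append(radiality_frame(stack.frames[t], params,
                                       grid_offset_xy=(dx, dy)))
        rad = np.stack(rad)
    else:
        rad = np.stack([radiality_frame(f, params) for f in stack.frames])
    sr = temporal_projection(RadialityStack(rad, params), params.temporal_mode)
    return ImageStack(sr[None],
                      pixel_size_nm=stack.pixel_size_nm / params.magnification,
                      name=(stack.name + " (SRRF)") if stack.name else "SRRF")
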