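"""Super-resolution image quality (error mapping) and resolution (FRC) maps.

Quality assessment rests on one observation: a super-resolution (SR) image
and a diffraction-limited widefield (WF) image of the same field contain the
same structure at different resolutions, so some blurring function turns the
SR image into its diffraction-limited equivalent. The resolution scaling
function (RSF) is modelled here as an isotropic Gaussian with a linear
intensity mapping: ``WF ≈ G_sigma * (alpha·SR + beta)``. After fitting
(sigma, alpha, beta), the per-pixel absolute discrepancy between the blurred
SR estimate and the reference is the *error map*, and two global scores
summarise it: RSP (Pearson correlation of estimate vs reference; 1 = perfect
structural match) and RSE (root-mean-square discrepancy; 0 = perfect
intensity match).

Resolution is measured by Fourier ring correlation (FRC) between two
independent realisations of the same image (e.g. odd/even-frame
reconstructions): the spatial frequency where the ring-wise spectral
correlation first drops below a threshold (1/7 by convention) defines the
resolution. Because resolution varies across a field of view, the FRC can
also be mapped block-wise, with failed blocks filled in from neighbours.

A low FRC resolution does not certify that structures are depicted
correctly — it only measures reproducibility between the two realisations.
Error mapping and FRC mapping are therefore reported together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .channel_registration import idw_interpolate
from .exceptions import DegenerateInputError, ValidationError
from .image_io import ImageStack

__all__ = [
    "RSFFit",
    "ErrorMapResult",
    "FRCResult",
    "ResolutionMap",
    "match_scales",
    "fit_rsf",
    "error_map",
    "frc_curve",
    "frc_map",
    "split_halves",
]

FRC_THRESHOLD = 1.0 / 7.0
SIGMA_BOUNDS = (0.5, 20.0)  # RSF sigma search range, SR-grid pixels


@dataclass
class RSFFit:
    sigma_px: float
    alpha: float
    beta: float
    residual_norm: float
    at_bound: bool = False  # sigma pinned at a search bound (e.g. WF == SR)


@dataclass
class ErrorMapResult:
    error_map: np.ndarray
    rsp: float
    rse: float
    fit: RSFFit


@dataclass
class FRCResult:
    frequencies: np.ndarray  # cycles / pixel, ring centres
    correlations: np.ndarray
    resolution_nm: float | None
    threshold: float = FRC_THRESHOLD


@dataclass
class ResolutionMap:
    block_grid: np.ndarray  # resolution_nm per block
    interpolated_mask: np.ndarray  # True where filled from neighbours


def match_scales(sr_image: np.ndarray, wf_image: np.ndarray) -> np.ndarray:
    """Resample the widefield reference onto the SR grid (bicubic).

    The SR shape must be an integer multiple of the WF shape. Pixel values
    are preserved (a constant image stays that constant), i.e. intensity per
    unit physical area is conserved.
    """
    sr_image = np.asarray(sr_image)
    wf_image = np.asarray(wf_image, dtype=float)
    if sr_image.shape == wf_image.shape:
        return wf_image.copy()
    scales = [s // w for s, w in zip(sr_image.shape, wf_image.shape)]
    if (scales[0] != scales[1]
            or any(s != w * k for s, w, k in zip(sr_image.shape, wf_image.shape, scales))
            or scales[0] < 1):
        raise ValidationError(
            f"SR shape {sr_image.shape} is not an integer multiple of "
            f"WF shape {wf_image.shape}")
    return zoom(wf_image, scales[0], order=3, mode="nearest", grid_mode=True)


def _blur_design(sr: np.ndarray, sigma: float) -> np.ndarray:
    return gaussian_filter(sr, sigma, mode="nearest")


def _solve_alpha_beta(blurred_sr: np.ndarray, wf: np.ndarray
                      ) -> tuple[float, float, float]:
    """Closed-form least squares of wf ≈ alpha·blurred_sr + beta."""
    x = blurred_sr.ravel()
    y = wf.ravel()
    xm, ym = x.mean(), y.mean()
    denom = float(((x - xm) ** 2).sum())
    alpha = float(((x - xm) * (y - ym)).sum() / denom) if denom > 0 else 0.0
    beta = float(ym - alpha * xm)
    resid = float(np.linalg.norm(y - alpha * x - beta))
    return alpha, beta, resid


def fit_rsf(sr_image: np.ndarray, wf_on_sr_grid: np.ndarray,
            sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
            sigma_tol: float = 1e-6) -> RSFFit:
    """Fit the Gaussian resolution scaling function.

    Minimises ``|| wf − G_sigma * (alpha·sr + beta) ||₂``. Because the
    Gaussian kernel is normalised, the blur commutes with the affine map and
    (alpha, beta) have a closed-form solution for each sigma; sigma itself
    is found by golden-section search, which is reliable because the 1D
    residual profile is unimodal for this model.
    """
    sr = np.asarray(sr_image, dtype=float)
    wf = np.asarray(wf_on_sr_grid, dtype=float)
    if sr.shape != wf.shape:
        raise ValidationError("images must share a grid; use match_scales first")
    if sr.std() == 0:
        raise DegenerateInputError("constant SR image: blurring function undefined")

    def objective(sigma: float) -> float:
        return _solve_alpha_beta(_blur_design(sr, sigma), wf)[2]

    lo, hi = sigma_bounds
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = objective(c), objective(d)
    while b - a > sigma_tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = objective(d)
    sigma = (a + b) / 2.0
    alpha, beta, resid = _solve_alpha_beta(_blur_design(sr, sigma), wf)
    at_bound = (sigma - lo) < 10 * sigma_tol or (hi - sigma) < 10 * sigma_tol
    return RSFFit(sigma_px=float(sigma), alpha=alpha, beta=beta,
                  residual_norm=resid, at_bound=at_bound)


def error_map(sr_image: np.ndarray, wf_image: np.ndarray,
              fit: RSFFit | None = None) -> ErrorMapResult:
    """Error map plus the RSP / RSE global quality scores.

    The widefield reference is resampled to the SR grid if needed, the RSF
    is fitted (unless supplied), and the blurred estimate
    ``G_sigma * (alpha·SR + beta)`` is compared with the reference:
    ``error_map = |wf − estimate|``, RSP = Pearson(estimate, wf),
    RSE = RMS(error_map).
    """
    sr = np.asarray(sr_image, dtype=float)
    wf = match_scales(sr, wf_image)
    if fit is None:
        fit = fit_rsf(sr, wf)
    estimate = _blur_design(fit.alpha * sr + fit.beta, fit.sigma_px)
    emap = np.abs(wf - estimate)
    if estimate.std() == 0 or wf.std() == 0:
        raise DegenerateInputError("constant image: RSP undefined")
    rsp = float(np.corrcoef(estimate.ravel(), wf.ravel())[0, 1])
    rse = float(np.sqrt(np.mean(emap**2)))
    return ErrorMapResult(error_map=emap, rsp=rsp, rse=rse, fit=fit)


def _ring_sums(f1: np.ndarray, f2: np.ndarray) -> tuple[np.ndarray, ...]:
    n = f1.shape[0]
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    r = np.sqrt(fy**2 + fx**2) * n  # ring index in FFT-sample units
    ring = np.minimum(np.round(r).astype(int), n)  # 1-pixel-wide rings
    num = np.bincount(ring.ravel(), (f1 * np.conj(f2)).real.ravel(), minlength=n + 1)
    p1 = np.bincount(ring.ravel(), np.abs(f1.ravel()) ** 2, minlength=n + 1)
    p2 = np.bincount(ring.ravel(), np.abs(f2.ravel()) ** 2, minlength=n + 1)
    return num, p1, p2


def frc_curve(img1: np.ndarray, img2: np.ndarray,
              pixel_size_nm: float = 100.0,
              threshold: float = FRC_THRESHOLD) -> FRCResult:
    """Fourier ring correlation between two realisations of one image.

    ``FRC(q) = Re Σ_ring F1·conj(F2) / sqrt(Σ_ring |F1|² · Σ_ring |F2|²)``
    over 1-pixel-wide frequency rings up to Nyquist (the DC term is
    excluded). The resolution is ``pixel_size_nm / q*`` with q* the first
    crossing below the threshold (from above), linearly interpolated between
    rings; ``resolution_nm`` is None when the curve never crosses from above
    — either always above (identical images) or already below at the lowest
    ring (no resolvable correlation at all).
    """
    a = np.asarray(img1, dtype=float)
    b = np.asarray(img2, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValidationError("images must be 2D with identical shape")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("constant image: FRC undefined")
    n = max(a.shape)
    if a.shape[0] != a.shape[1]:
        pad = [(0, n - s) for s in a.shape]
        a = np.pad(a, pad)
        b = np.pad(b, pad)
    num, p1, p2 = _ring_sums(np.fft.fft2(a), np.fft.fft2(b))
    n_rings = n // 2
    rings = np.arange(1, n_rings + 1)
    den = np.sqrt(p1[rings] * p2[rings])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num[rings] / np.maximum(den, 1e-300), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    freqs = rings / float(n)  # cycles per pixel

    # a genuine crossing must come from above: a curve already below the
    # threshold at the lowest frequency carries no resolvable correlation
    resolution = None
    below = np.nonzero(corr < threshold)[0]
    if below.size and below[0] > 0:
        i = below[0]
        c0, c1 = corr[i - 1], corr[i]
        frac = (c0 - threshold) / (c0 - c1)
        q_star = freqs[i - 1] + frac * (freqs[i] - freqs[i - 1])
        resolution = float(pixel_size_nm / q_star)
    return FRCResult(frequencies=freqs, correlations=corr,
                     resolution_nm=resolution, threshold=threshold)


def frc_map(img1: np.ndarray, img2: np.ndarray, blocks_per_axis: int = 8,
            pixel_size_nm: float = 100.0,
            threshold: float = FRC_THRESHOLD) -> ResolutionMap:
    """Block-wise FRC resolution map.

    The images are tiled into ``blocks_per_axis²`` blocks and the FRC is run
    on each tile pair. Blocks with no threshold crossing or with degenerate
    content get a resolution interpolated from the valid blocks
    (inverse-distance weighting, power 2) and are flagged in
    ``interpolated_mask``.
    """
    from .channel_registration import _block_slices

    a = np.asarray(img1, dtype=float)
    b = np.asarray(img2, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("images must have identical shape")
    if blocks_per_axis < 2:
        raise ValidationError("blocks_per_axis must be >= 2")
    grid = np.full((blocks_per_axis, blocks_per_axis), np.nan)
    centres = np.zeros((blocks_per_axis, blocks_per_axis, 2))
    for k, (rs, cs) in enumerate(_block_slices(a.shape, blocks_per_axis)):
        i, j = divmod(k, blocks_per_axis)
        centres[i, j] = ((cs.start + cs.stop - 1) / 2.0,
                         (rs.start + rs.stop - 1) / 2.0)
        try:
            res = frc_curve(a[rs, cs], b[rs, cs], pixel_size_nm, threshold)
        except DegenerateInputError:
            continue
        # "insufficient correlation": noise-only tiles can fluctuate above
        # the threshold at a single ring; demand that the low-frequency
        # quarter of the curve holds the threshold on average
        low = res.correlations[:max(1, len(res.correlations) // 4)]
        if res.resolution_nm is not None and low.mean() >= threshold:
            grid[i, j] = res.resolution_nm
    invalid = np.isnan(grid)
    if invalid.all():
        raise ValidationError("no block produced an FRC resolution")
    if invalid.any():
        pts = centres[~invalid]
        vals = grid[~invalid]
        grid[invalid] = idw_interpolate(pts, vals, centres[invalid], power=2.0)
    return ResolutionMap(block_grid=grid, interpolated_mask=invalid)


def split_halves(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Mean images of the odd and even frames of a movie — two independent
    realisations of the same field for FRC analysis."""
    if stack.n_frames < 2:
        raise ValidationError("need at least 2 frames to split")
    return stack.frames[0::2].mean(axis=0), stack.frames[1::2].mean(axis=0)
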