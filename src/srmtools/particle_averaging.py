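"""Template-based single-particle averaging for fluorescence images.

Many copies of the same structure (e.g. virus particles) scattered over a
field of view can be detected, cropped, aligned to a template over rotations
and translations, filtered by alignment quality, and averaged into a model
whose SNR grows like the square root of the number of contributing
particles. Alignment poses are found on one designated channel and applied
to all channels of a particle, so multi-channel data yield jointly
registered per-channel models.

The pose space is rotation + translation (no mirror flips); classification
is a single correlation-score threshold against the template. Distinct
particle orientations/classes are handled by building one model per seed
template rather than by unsupervised clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from ._interpolation import bicubic_sample, translate
from .drift_correction import cross_correlation_matrix, subpixel_peak
from .exceptions import (ClassificationError, DegenerateInputError,
                         ValidationError)

__all__ = [
    "SPAParams",
    "ParticleSet",
    "TemplateModel",
    "detect_particles",
    "extract_particles",
    "align_to_template",
    "classify_particles",
    "build_model",
]


@dataclass
class SPAParams:
    box_px: int = 33
    angle_step_deg: float = 5.0
    max_shift_px: int = 5
    score_threshold: float = 0.5
    n_iterations: int = 3
    alignment_channel: int = 0
    min_separation_px: int = 10
    threshold_k: float = 4.0  # detection threshold: mean + k*std


@dataclass
class ParticleSet:
    """Cropped candidate particles and (after alignment) their poses.

    ``crops`` has shape (n_particles, n_channels, box, box); ``poses`` holds
    per-particle (rotation_deg, dx_px, dy_px, score) on the alignment
    channel; ``accepted`` flags survive classification.
    """

    crops: np.ndarray
    source_positions: np.ndarray  # (n, 2) detection centres, (x, y)
    poses: np.ndarray | None = None  # (n, 4): rot_deg, dx, dy, score
    accepted: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return self.crops.shape[0]

    @property
    def n_channels(self) -> int:
        return self.crops.shape[1]

    @property
    def box_px(self) -> int:
        return self.crops.shape[-1]


@dataclass
class TemplateModel:
    channels: list[np.ndarray]
    n_contributing: int
    iteration: int


def detect_particles(image: np.ndarray, min_separation_px: int = 10,
                     threshold_k: float = 4.0) -> np.ndarray:
    """Detect bright particles as local maxima of the smoothed image.

    The image is Gaussian-smoothed (sigma 1 px); maxima above
    ``mean + threshold_k·std`` are kept, no two closer than
    ``min_separation_px`` (brightest wins), and each centre is refined to
    subpixel precision by the intensity centroid of its 5×5 neighbourhood.
    Returns an (n, 2) array of (x, y); may be empty.
    """
    if min_separation_px < 1:
        raise ValidationError("min_separation_px must be >= 1")
    img = np.asarray(image, dtype=float)
    smooth = ndimage.gaussian_filter(img, 1.0)
    thr = smooth.mean() + threshold_k * smooth.std()
    peaks = peak_local_max(smooth, min_distance=min_separation_px,
                           threshold_abs=thr, exclude_border=False)
    out = []
    h, w = img.shape
    for r, c in peaks:
        r0, r1 = max(0, r - 2), min(h, r + 3)
        c0, c1 = max(0, c - 2), min(w, c + 3)
        win = img[r0:r1, c0:c1]
        tot = win.sum()
        if tot <= 0:
            out.append((float(c), float(r)))
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        out.append((float((win * cc).sum() / tot), float((win * rr).sum() / tot)))
    return np.array(out).reshape(-1, 2)


def _as_channel_list(images_per_channel) -> list[np.ndarray]:
    """Accept a single 2D image, a (C, H, W) array, or a sequence of frames."""
    arr = np.asarray(images_per_channel, dtype=float)
    if arr.ndim == 2:
        return [arr]
    if arr.ndim == 3:
        return list(arr)
    raise ValidationError("expected a 2D image or a (channels, rows, cols) set")


def extract_particles(images_per_channel, positions: np.ndarray,
                      box_px: int = 33) -> ParticleSet:
    """Crop a ``box_px`` square around each subpixel position, per channel.

    Positions closer than box_px/2 to any border are dropped. Crops are
    bicubic-resampled so the particle centre lands exactly on the box
    centre.
    """
    images = _as_channel_list(images_per_channel)
    if box_px % 2 == 0 or box_px < 3:
        raise ValidationError("box_px must be odd and >= 3")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) < 1:
        raise ValidationError("need at least one position")
    h, w = images[0].shape
    half = box_px // 2
    keep = ((positions[:, 0] >= half) & (positions[:, 0] <= w - 1 - half)
            & (positions[:, 1] >= half) & (positions[:, 1] <= h - 1 - half))
    positions = positions[keep]
    if len(positions) == 0:
        raise ValidationError("all positions fell within box_px/2 of the border")
    offs = np.arange(box_px, dtype=float) - half
    crops = np.empty((len(positions), len(images), box_px, box_px))
    for c, img in enumerate(images):
        for i, (x, y) in enumerate(positions):
            rr, cc = np.meshgrid(y + offs, x + offs, indexing="ij")
            crops[i, c] = bicubic_sample(img, rr, cc)
    return ParticleSet(crops=crops, source_positions=positions)


def _rotate(patch: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg % 360.0 == 0.0:
        return patch.copy()
    return ndimage.rotate(patch, angle_deg, reshape=False, order=3,
                          mode="constant", cval=0.0)


def align_to_template(particles: ParticleSet, template: np.ndarray,
                      alignment_channel: int = 0, angle_step_deg: float = 5.0,
                      max_shift_px: int = 5) -> ParticleSet:
    """Exhaustive rotation search + correlation-based translation per particle.

    For each candidate angle the crop is rotated about its centre (bicubic)
    and the best translation is found from the cross-correlation peak with
    the template; the pose with the highest peak correlation wins. The pose
    is measured on ``alignment_channel`` and recorded for the particle as a
    whole, so it can be applied to every channel.
    """
    template = np.asarray(template, dtype=float)
    if template.shape != (particles.box_px, particles.box_px):
        raise ValidationError("template must match the particle box size")
    if angle_step_deg <= 0 or 360.0 % angle_step_deg != 0:
        raise ValidationError("angle_step_deg must divide 360")
    angles = np.arange(0.0, 360.0, angle_step_deg)
    poses = np.zeros((particles.n_particles, 4))
    for i in range(particles.n_particles):
        crop = particles.crops[i, alignment_channel]
        best = (-np.inf, 0.0, 0.0, 0.0)
        for a in angles:
            rot = _rotate(crop, -a)
            try:
                ccm = cross_correlation_matrix(template, rot, max_shift_px)
            except DegenerateInputError:
                continue
            with warnings.catch_warnings():
                # wrong-angle candidates routinely peak at the window border;
                # they lose the argmax anyway
                warnings.simplefilter("ignore", UserWarning)
                s = subpixel_peak(ccm)
            if s.peak_correlation > best[0]:
                best = (s.peak_correlation, a, s.dx_px, s.dy_px)
        poses[i] = (best[1], best[2], best[3],
                    best[0] if np.isfinite(best[0]) else -1.0)
    return replace(particles, poses=poses)


def classify_particles(particles: ParticleSet,
                       score_threshold: float = 0.5) -> ParticleSet:
    """Accept particles whose alignment score reaches the threshold."""
    if particles.poses is None:
        raise ValidationError("align_to_template must run before classification")
    scores = particles.poses[:, 3]
    accepted = scores >= score_threshold
    if not accepted.any():
        hist, edges = np.histogram(scores, bins=10, range=(-1, 1))
        raise ClassificationError(
            "no particle reached the score threshold "
            f"{score_threshold}; score histogram (bins {np.round(edges, 2).tolist()}): "
            f"{hist.tolist()}")
    return replace(particles, accepted=accepted)


def _aligned_crop(crop: np.ndarray, pose: np.ndarray) -> np.ndarray:
    rot, dx, dy = pose[0], pose[1], pose[2]
    aligned = _rotate(crop, -rot)
    return translate(aligned, -dx, -dy)


def average_accepted(particles: ParticleSet) -> TemplateModel:
    """Per-channel mean of the accepted, pose-corrected crops."""
    if particles.accepted is None or particles.poses is None:
        raise ValidationError("particles must be aligned and classified")
    idx = np.nonzero(particles.accepted)[0]
    channels = []
    for c in range(particles.n_channels):
        acc = [_aligned_crop(particles.crops[i, c], particles.poses[i])
               for i in idx]
        channels.append(np.mean(acc, axis=0))
    return TemplateModel(channels=channels, n_contributing=len(idx), iteration=0)


def build_model(images_per_channel, seed_template: np.ndarray,
                params: SPAParams | None = None,
                positions: np.ndarray | None = None) -> TemplateModel:
    """Detect, extract, and iteratively align/classify/average particles.

    ``seed_template`` is an exemplar crop (box_px square) on the alignment
    channel. Each iteration aligns every particle to the current template,
    rejects poor matches, and replaces the template with the per-channel
    mean of the accepted pose-corrected crops. Deterministic given inputs.
    """
    params = params or SPAParams()
    images = ([np.asarray(im, dtype=float) for im in images_per_channel]
              if not isinstance(images_per_channel, np.ndarray)
              or images_per_channel.ndim == 3
              else [np.asarray(images_per_channel, dtype=float)])
    seed_template = np.asarray(seed_template, dtype=float)
    if positions is None:
        positions = detect_particles(images[params.alignment_channel],
                                     params.min_separation_px, params.threshold_k)
    particles = extract_particles(images, positions, params.box_px)
    template = seed_template
    model = None
    for it in range(1, params.n_iterations + 1):
        particles = align_to_template(particles, template,
                                      params.alignment_channel,
                                      params.angle_step_deg, params.max_shift_px)
        particles = classify_particles(particles, params.score_threshold)
        model = average_accepted(particles)
        model.iteration = it
        template = model.channels[params.alignment_channel]
    return model
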