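"""On-disk artefacts: TIFF stacks, drift-table CSVs, displacement-field TIFFs.

Conventions (fixed once, relied on everywhere):

* 0-based (row, col) indexing; x = col, y = row; pixel centres at integers.
* A stored shift (dx, dy) means "this frame/channel is displaced by
  (+dx, +dy) relative to its reference"; correction translates by (−dx, −dy).
* Images are written as multi-page 32-bit little-endian float TIFF, one page
  per frame, with the pixel pitch encoded in the resolution tags
  (pixels per centimetre).
* Drift tables are CSV with header ``frame,dx_px,dy_px``, always relative to
  frame 0 (previous-frame estimates are accumulated before storage).
* Displacement fields are 2-page float32 TIFFs: page 0 = horizontal shift
  (x), page 1 = vertical shift (y).

Reading never rescales or clips intensities: a 16-bit value of 65535 is the
intensity 65535.0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, ValidationError

__all__ = [
    "ImageStack",
    "DriftTable",
    "DisplacementField",
    "read_stack",
    "write_stack",
    "read_drift_table",
    "write_drift_table",
    "read_displacement_field",
    "write_displacement_field",
]

_CM_PER_NM = 1e-7


@dataclass
class ImageStack:
    """An ordered set of 2D intensity frames plus the physical pixel pitch."""

    frames: np.ndarray  # (t, row, col), non-negative real intensities
    pixel_size_nm: float = 100.0
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError("frames must be a (t, row, col) array with t >= 1")
        if not self.pixel_size_nm > 0:
            raise ValidationError("pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class DriftTable:
    """Per-frame lateral shift (dx, dy) in pixels relative to frame 0."""

    frame_index: np.ndarray
    dx_px: np.ndarray
    dy_px: np.ndarray
    reference_mode: str = "first"

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.dx_px = np.asarray(self.dx_px, dtype=float)
        self.dy_px = np.asarray(self.dy_px, dtype=float)
        if not (len(self.frame_index) == len(self.dx_px) == len(self.dy_px)):
            raise ValidationError("drift table columns must have equal length")
        if len(self.frame_index) == 0:
            raise ValidationError("drift table must have at least one entry")
        if len(np.unique(self.frame_index)) != len(self.frame_index):
            raise ValidationError("duplicate frame index in drift table")
        order = np.argsort(self.frame_index)
        self.frame_index = self.frame_index[order]
        self.dx_px = self.dx_px[order]
        self.dy_px = self.dy_px[order]
        if self.frame_index[0] != 0 or np.any(np.diff(self.frame_index) <= 0):
            raise ValidationError("frame indices must be strictly increasing from 0")
        if self.reference_mode not in ("first", "previous-accumulated"):
            raise ValidationError(f"unknown reference_mode {self.reference_mode!r}")

    def __len__(self) -> int:
        return len(self.frame_index)

    def shift(self, frame: int) -> tuple[float, float]:
        """(dx, dy) of ``frame`` relative to frame 0."""
        pos = np.searchsorted(self.frame_index, frame)
        if pos >= len(self.frame_index) or self.frame_index[pos] != frame:
            raise ValidationError(f"no drift entry for frame {frame}")
        return float(self.dx_px[pos]), float(self.dy_px[pos])


@dataclass
class DisplacementField:
    """Dense per-pixel (x, y) shifts mapping a target channel onto a reference."""

    shift_x: np.ndarray
    shift_y: np.ndarray
    reference_channel: str = ""
    target_channel: str = ""

    def __post_init__(self) -> None:
        # float64 in memory; quantised to float32 on disk by image_io
        self.shift_x = np.asarray(self.shift_x, dtype=np.float64)
        self.shift_y = np.asarray(self.shift_y, dtype=np.float64)
        if self.shift_x.shape != self.shift_y.shape or self.shift_x.ndim != 2:
            raise ValidationError("shift_x and shift_y must be same-shape 2D rasters")
        if not (np.isfinite(self.shift_x).all() and np.isfinite(self.shift_y).all()):
            raise ValidationError("displacement field must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.shift_x.shape


def _pixel_size_from_tif(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 3
    unit = getattr(unit, "value", unit)
    px_per_unit = num / den
    if unit == 2:  # inch
        cm_per_px = 2.54 / px_per_unit
    else:  # centimetre (or unitless: assume cm, the convention write_stack uses)
        cm_per_px = 1.0 / px_per_unit
    return cm_per_px / _CM_PER_NM


def read_stack(path: str | os.PathLike, default_pixel_size_nm: float = 100.0,
               name: str | None = None) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Pixel values are taken verbatim (no rescaling); pixel size is decoded
    from the resolution tags when present, else ``default_pixel_size_nm``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            if page.samplesperpixel != 1:
                raise FormatError(
                    f"page {i} of {path} has {page.samplesperpixel} samples per "
                    "pixel; only grayscale stacks are supported"
                )
        frames = tif.asarray().astype(float)
        pixel_size = _pixel_size_from_tif(tif) or default_pixel_size_nm
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames, pixel_size_nm=pixel_size,
                      name=name if name is not None else os.path.basename(str(path)))


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as multi-page 32-bit float TIFF with pixel-size metadata."""
    if stack.n_frames < 1:
        raise ValidationError("cannot write an empty stack")
    px_per_cm = 1.0 / (stack.pixel_size_nm * _CM_PER_NM)
    tifffile.imwrite(
        str(path),
        stack.frames.astype(np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )


def read_drift_table(path: str | os.PathLike) -> DriftTable:
    """Read a ``frame,dx_px,dy_px`` CSV; rows are sorted by frame index."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = {"frame", "dx_px", "dy_px"} - set(df.columns)
    if missing:
        raise FormatError(f"drift table {path} missing column(s): {sorted(missing)}")
    return DriftTable(df["frame"].to_numpy(), df["dx_px"].to_numpy(),
                      df["dy_px"].to_numpy())


def write_drift_table(table: DriftTable, path: str | os.PathLike) -> None:
    df = pd.DataFrame({"frame": table.frame_index,
                       "dx_px": table.dx_px, "dy_px": table.dy_px})
    df.to_csv(path, index=False, float_format="%.9g")


def read_displacement_field(path: str | os.PathLike) -> DisplacementField:
    """Read a 2-page float TIFF (page 0 = shift_x, page 1 = shift_y)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
    if arr.ndim != 3 or arr.shape[0] != 2:
        n = arr.shape[0] if arr.ndim == 3 else 1
        raise FormatError(f"displacement field {path} has {n} page(s); expected 2")
    return DisplacementField(arr[0], arr[1])


def write_displacement_field(fld: DisplacementField, path: str | os.PathLike) -> None:
    tifffile.imwrite(str(path),
                     np.stack([fld.shift_x, fld.shift_y]).astype(np.float32),
                     photometric="minisblack")
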