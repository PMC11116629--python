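"""Multi-page TIFF video stacks: the uniform in-memory video representation.

Native interchange format is plain multi-page TIFF (one file per channel per
larva per timepoint).  Pixel size and frame interval travel in ImageJ-style
metadata when present, but caller-supplied values always win: acquisition
metadata in exported files is frequently wrong, and the plate table is the
single source of truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["VideoStack", "read_video", "write_video"]


@dataclass
class VideoStack:
    """T x Y x X intensity frames with physical calibration.

    pixel_size_um is the effective (post-binning) pixel size in micrometres;
    frame_rate_fps the acquisition rate in frames per second.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_rate_fps: float
    channel: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(f"frames must be T x Y x X with T >= 1, got shape {self.frames.shape}")
        if np.issubdtype(self.frames.dtype, np.floating) and np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_rate_fps <= 0:
            raise ValueError("frame_rate_fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_fps

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_fps


def write_video(path: str | Path, stack: VideoStack) -> Path:
    """Write a stack as a multi-page grayscale TIFF with ImageJ metadata.

    The output is deterministic for identical pixel data and calibration
    (no timestamps are embedded), so files can be compared by hash.
    """
    path = Path(path)
    res = 1.0 / stack.pixel_size_um
    tifffile.imwrite(
        path,
        stack.frames,
        photometric="minisblack",
        imagej=True,
        resolution=(res, res),
        metadata={
            "unit": "um",
            "finterval": 1.0 / stack.frame_rate_fps,
            "axes": "TYX",
        },
    )
    return path


def _metadata_from_tiff(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """(pixel_size_um, frame_rate_fps) from tags, where recoverable."""
    pixel_size = None
    fps = None
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is not None:
        num, den = tag.value
        if num:
            pixel_size = den / num
    meta = tif.imagej_metadata or {}
    finterval = meta.get("finterval")
    if finterval:
        fps = 1.0 / finterval
    return pixel_size, fps


def read_video(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_rate_fps: float | None = None,
    channel: str | None = None,
) -> VideoStack:
    """Read a multi-page TIFF into a VideoStack.

    Explicit ``pixel_size_um`` / ``frame_rate_fps`` arguments override any
    conflicting file metadata (with a logged warning); when omitted, the file
    metadata is used and its absence is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise ValueError(f"{path}: TIFF contains no pages")
        frames = tif.asarray()
        file_px, file_fps = _metadata_from_tiff(tif)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise ValueError(f"{path}: pages are not 2-D images (array shape {frames.shape})")

    def _resolve(name: str, arg: float | None, from_file: float | None) -> float:
        if arg is not None:
            if from_file is not None and not np.isclose(arg, from_file, rtol=1e-3):
                logger.warning("%s: %s %.6g from file conflicts with argument %.6g; using argument", path, name, from_file, arg)
            return float(arg)
        if from_file is None:
            raise ValueError(f"{path}: {name} not present in file metadata and not supplied")
        return float(from_file)

    return VideoStack(
        frames=frames,
        pixel_size_um=_resolve("pixel_size_um", pixel_size_um, file_px),
        frame_rate_fps=_resolve("frame_rate_fps", frame_rate_fps, file_fps),
        channel=channel,
    )
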