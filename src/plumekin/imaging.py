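"""Frame containers, PNG/TIFF stack I/O and binary image enhancement.

A recording is an ordered stack of 8-bit grayscale frames at a fixed
inter-frame interval (default 1/300 s) with a spatial calibration: the
physical pixel size in cm/px and the mouth position in pixel coordinates.
Pixel coordinates are 0-based, x rightward, y downward; physical
coordinates are in cm with the origin at the mouth, x positive along the
expectoration direction and y positive downward.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu

from .errors import InputError

DEFAULT_DT = 1.0 / 300.0  # s, 300 frames/s recording
DEFAULT_PIXEL_SIZE = 4.4 / 21.0  # cm/px: a 21 px window spans 4.4 cm


@dataclass(frozen=True)
class Frame:
    """One grayscale frame with its timestamp and calibration."""

    data: np.ndarray  # (H, W) uint8
    timestamp: float  # s
    pixel_size: float  # cm/px

    def __post_init__(self):
        if self.data.ndim != 2:
            raise InputError(f"frame data must be 2-D, got shape {self.data.shape}")
        if self.timestamp < 0:
            raise InputError("frame timestamp must be non-negative")
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class FrameSequence:
    """Ordered frames sharing shape, inter-frame interval and calibration."""

    data: np.ndarray  # (N, H, W) uint8
    dt: float = DEFAULT_DT
    pixel_size: float = DEFAULT_PIXEL_SIZE
    mouth_position: tuple[float, float] = (0.0, 0.0)  # (x, y) px

    def __post_init__(self):
        if self.data.ndim != 3:
            raise InputError(f"sequence data must be 3-D, got shape {self.data.shape}")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise InputError("dt and pixel_size must be positive")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def frame(self, i: int) -> Frame:
        return Frame(self.data[i], i * self.dt, self.pixel_size)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


def load_frames(
    path_pattern: str,
    dt: float = DEFAULT_DT,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    mouth_position: tuple[float, float] = (0.0, 0.0),
) -> FrameSequence:
    """Load a numbered grayscale image stack matching a glob pattern.

    Frames are ordered by filename; timestamps are ``i * dt``. Raises
    :class:`IOError` naming the offending file when a frame is missing,
    undecodable, not grayscale, or differently sized.
    """
    paths = sorted(glob.glob(path_pattern))
    if not paths:
        raise IOError(f"no files match pattern {path_pattern!r}")
    grids = []
    shape = None
    for p in paths:
        try:
            arr = np.asarray(iio.imread(p))
        except Exception as exc:  # noqa: BLE001 - re-raise with filename
            raise IOError(f"cannot decode frame file {p!r}: {exc}") from exc
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise IOError(f"frame file {p!r} is not grayscale (shape {arr.shape})")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise IOError(
                f"frame file {p!r} has shape {arr.shape}, expected {shape}"
            )
        grids.append(arr.astype(np.uint8))
    return FrameSequence(
        data=np.stack(grids),
        dt=dt,
        pixel_size=pixel_size,
        mouth_position=mouth_position,
    )


def write_frames(
    seq: FrameSequence, directory: str, prefix: str = "frame", ext: str = "png"
) -> list[str]:
    """Write each frame as a zero-padded numbered 8-bit grayscale image."""
    os.makedirs(directory, exist_ok=True)
    width = max(4, len(str(seq.n_frames - 1)))
    paths = []
    for i in range(seq.n_frames):
        path = os.path.join(directory, f"{prefix}_{i:0{width}d}.{ext}")
        iio.imwrite(path, seq.data[i])
        paths.append(path)
    return paths


def binarize(frame: Frame, threshold: int | str = "auto") -> Frame:
    """Binary image enhancement: pixels >= threshold map to 255, rest to 0.

    ``threshold='auto'`` picks a global threshold by Otsu's
    histogram-bimodality criterion. A constant frame has no bimodal
    histogram; it binarizes to all zero (nothing to enhance).
    """
    data = frame.data
    if threshold == "auto":
        if np.all(data == data.flat[0]):
            thr = int(data.flat[0]) + 1
        else:
            thr = threshold_otsu(data)
    else:
        thr = float(threshold)
        if not 0 <= thr <= 255:
            raise InputError(f"threshold must be in [0, 255] or 'auto', got {thr}")
    out = np.where(data >= thr, 255, 0).astype(np.uint8)
    return Frame(out, frame.timestamp, frame.pixel_size)


def binarize_sequence(seq: FrameSequence, threshold: int | str = "auto") -> FrameSequence:
    """Apply :func:`binarize` frame-wise (visualization / QC aid)."""
    stacked = np.stack(
        [binarize(seq.frame(i), threshold).data for i in range(seq.n_frames)]
    )
    return FrameSequence(stacked, seq.dt, seq.pixel_size, seq.mouth_position)
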