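"""Video container and grayscale video I/O.

A :class:`VideoStack` is the in-memory form of a microcirculation recording:
an ordered stack of grayscale frames plus the two calibration constants every
downstream stage needs — microns per pixel and frames per second.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np

from .errors import ConfigError, InputError

__all__ = ["VideoStack", "read_video", "write_video"]


@dataclasses.dataclass
class VideoStack:
    """Ordered grayscale frames with spatial and temporal calibration.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Intensity frames, float32.
    um_per_px : float
        Microns per pixel (isotropic).
    fps : float
        Frames per second.
    """

    frames: np.ndarray
    um_per_px: float
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ConfigError("frames must be a (n_frames, rows, cols) array")
        if self.frames.shape[0] < 2:
            raise ConfigError("a video needs at least 2 frames")
        if not (self.um_per_px > 0 and self.fps > 0):
            raise ConfigError("um_per_px and fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def dt(self) -> float:
        """Inter-frame interval in seconds."""
        return 1.0 / self.fps

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]


def read_video(path, um_per_px: float, fps: float) -> VideoStack:
    """Read a grayscale video (multi-page TIFF, or AVI/MP4 via imageio)."""
    path = pathlib.Path(path)
    if not path.exists():
        raise InputError(f"video file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = np.asarray(tifffile.imread(path))
    else:
        import imageio.v3 as iio

        frames = np.asarray(iio.imread(path))
        if frames.ndim == 4:  # color container: luminance
            frames = frames.mean(axis=-1)
    if frames.ndim == 2:
        raise InputError(f"{path} holds a single frame, not a video")
    return VideoStack(frames.astype(np.float32), um_per_px, fps)


def write_video(video: VideoStack, path) -> None:
    """Write a video as multi-page grayscale TIFF (8- or 16-bit)."""
    path = pathlib.Path(path)
    frames = np.clip(video.frames, 0, None)
    if frames.max() <= 255:
        data = np.round(frames).astype(np.uint8)
    else:
        data = np.round(np.clip(frames, 0, 65535)).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff", ""):
        import tifffile

        tifffile.imwrite(path.with_suffix(path.suffix or ".tiff"), data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)
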