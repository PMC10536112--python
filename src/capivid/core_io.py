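"""Frame, sequence and mask I/O for capillaroscopy video processing.

The working representation throughout the package is 8-bit grayscale: a
:class:`FrameSequence` holds an ``(N, H, W)`` uint8 stack plus the acquisition
frame rate, and an optional per-pixel validity stack produced by geometric
operations (stabilization warps pixels out of canvas; those are *invalid*, not
black). Binary capillary masks are held in memory as {0, 1} uint8 and stored on
disk as 0/255 8-bit PNG so they open correctly in ordinary viewers.

The canonical on-disk exchange format is a directory of lexicographically
ordered PNG/TIFF images (deterministic and codec-free); reading a video
container is a convenience that depends on the available imageio plugins.

Conventions: pixel (i, j) = (row, column), origin top-left, 0-based; frame
index k runs 0..N-1.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

__all__ = [
    "DEFAULT_FRAME_RATE",
    "FrameSequence",
    "as_gray_u8",
    "read_sequence",
    "write_sequence",
    "read_mask",
    "write_mask",
]

#: Acquisition rate of the capillaroscope recordings this package targets
#: (frames per second).
DEFAULT_FRAME_RATE = 120.0

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}

# ITU-R BT.601 luminance weights, the common default for RGB -> gray.
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray_u8(image: np.ndarray) -> np.ndarray:
    """Convert an image to 2-D uint8 grayscale.

    Color inputs are collapsed with BT.601 luminance weighting; an alpha
    channel, if present, is ignored.  Already-gray 3-channel images come back
    equal to their single channel exactly (the weights sum to 1 and all
    channels are identical, so rounding reproduces the channel value).
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            flat = arr.astype(np.float64) @ _LUMA
            arr = np.rint(flat)
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"unsupported channel count: {arr.shape[2]}")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        arr = arr // 257  # 16-bit to 8-bit full-scale
    return np.clip(np.rint(np.asarray(arr, dtype=np.float64)), 0, 255).astype(np.uint8)


@dataclasses.dataclass
class FrameSequence:
    """Ordered grayscale frames with a frame rate.

    Parameters
    ----------
    pixels:
        ``(N, H, W)`` uint8 stack; frame k is ``pixels[k]``.
    frame_rate:
        Acquisition rate in frames per second.
    valid:
        Optional ``(N, H, W)`` boolean stack marking pixels that carry real
        image content (False where a warp filled in the 0 sentinel).
    """

    pixels: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (N, H, W)")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        n, h, w = self.pixels.shape
        if n < 1 or h < 1 or w < 1:
            raise ValueError("empty sequence or degenerate frame size")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.pixels.shape:
                raise ValueError("valid mask shape must match pixels")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def height(self) -> int:
        return self.pixels.shape[1]

    @property
    def width(self) -> int:
        return self.pixels.shape[2]

    def frame(self, k: int) -> np.ndarray:
        return self.pixels[k]

    def validity(self) -> np.ndarray:
        """Validity stack; all-True when no warp has been applied."""
        if self.valid is None:
            return np.ones_like(self.pixels, dtype=bool)
        return self.valid

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.pixels)


def _frame_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    return files


def read_sequence(
    path: str | Path,
    kind: str = "directory",
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> FrameSequence:
    """Read a frame sequence from a directory of images or a video container.

    ``kind="directory"`` reads PNG/TIFF files in lexicographic order;
    ``kind="video"`` decodes a container file through imageio.  All frames are
    converted to 8-bit grayscale and must share dimensions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames: list[np.ndarray] = []
    if kind == "directory":
        if not path.is_dir():
            raise NotADirectoryError(path)
        for f in _frame_files(path):
            frames.append(as_gray_u8(iio.imread(f)))
    elif kind == "video":
        for raw in iio.imiter(path):
            frames.append(as_gray_u8(raw))
    else:
        raise ValueError(f"unknown kind: {kind!r}")
    if not frames:
        raise ValueError(f"no decodable frames found at {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame dimensions: {sorted(shapes)}")
    return FrameSequence(np.stack(frames), frame_rate=frame_rate)


def write_sequence(seq: FrameSequence, path: str | Path) -> None:
    """Write a sequence as zero-padded PNGs (``frame_0000.png`` ...).

    Round-trips exactly: reading the directory back reproduces the pixel
    values bit for bit.
    """
    if seq.n_frames < 1:
        raise ValueError("cannot write an empty sequence")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k in range(seq.n_frames):
        iio.imwrite(path / f"frame_{k:04d}.png", seq.pixels[k])
    if seq.valid is not None:
        vdir = path / "validity"
        vdir.mkdir(exist_ok=True)
        for k in range(seq.n_frames):
            iio.imwrite(
                vdir / f"valid_{k:04d}.png",
                (seq.valid[k].astype(np.uint8) * 255),
            )


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary capillary mask; any nonzero pixel counts as foreground."""
    arr = as_gray_u8(iio.imread(Path(path)))
    return (arr > 127).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as 0/255 8-bit PNG."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.astype(np.uint8) * 255))
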