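"""Core grayscale image container.

All image math in this package operates on :class:`EchoImage`: a 2-D grid of
floating-point intensities in ``[0, 1]`` plus a bit depth ``n``.  The integer
representation with ``2**n - 1`` levels appears only at file I/O and inside
the quality metrics, which are defined on the integer scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EchoImage"]


@dataclass(frozen=True)
class EchoImage:
    """A 2-D grayscale intensity grid.

    Parameters
    ----------
    pixels:
        2-D float array with every value in ``[0, 1]``.
    bit_depth:
        Bits per pixel of the integer file representation (default 8).
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"image must be at least 1x1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pixels must be finite")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(
                f"intensities must lie in [0, 1], got range "
                f"[{arr.min():.6g}, {arr.max():.6g}]"
            )
        if not (isinstance(self.bit_depth, (int, np.integer)) and self.bit_depth >= 1):
            raise ValueError(f"bit_depth must be a positive integer, got {self.bit_depth}")
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "bit_depth", int(self.bit_depth))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def levels(self) -> int:
        """Number of representable integer levels minus one: ``2**n - 1``."""
        return 2**self.bit_depth - 1

    def to_integer_scale(self) -> np.ndarray:
        """Intensities rescaled to the ``0 .. 2**n - 1`` float scale (not rounded)."""
        return self.pixels * self.levels

    def quantize(self) -> np.ndarray:
        """Round-to-nearest integer representation as an unsigned array."""
        dtype = np.uint8 if self.bit_depth <= 8 else np.uint16
        return np.rint(self.pixels * self.levels).astype(dtype)

    @classmethod
    def from_integer_array(cls, arr: np.ndarray, bit_depth: int) -> "EchoImage":
        """Build an image from integer pixel values on the ``0 .. 2**n - 1`` scale."""
        levels = 2**bit_depth - 1
        return cls(np.asarray(arr, dtype=np.float64) / levels, bit_depth=bit_depth)

    @classmethod
    def from_array(cls, arr: np.ndarray, bit_depth: int = 8, clip: bool = False) -> "EchoImage":
        """Build an image from a float array, optionally clipping into ``[0, 1]``."""
        arr = np.asarray(arr, dtype=np.float64)
        if clip:
            arr = np.clip(arr, 0.0, 1.0)
        return cls(arr, bit_depth=bit_depth)
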