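"""Image stack container and TIFF I/O.

All geometry is carried in physical units: pixel size in micrometres,
frame interval in seconds (time-lapse) or slice spacing in micrometres
(z-stacks).  Acquisition metadata is supplied explicitly by the caller
(CLI flag or config) and takes precedence over anything stored in file
tags, because acquisition settings are typically recorded in protocols
rather than embedded reliably in exported TIFFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]

_AXIS_KINDS = ("time", "z")


@dataclass
class ImageStack:
    """A grayscale stack with axis semantics.

    Parameters
    ----------
    data
        Array of shape ``(n_frames_or_slices, rows, cols)`` with
        non-negative intensities.
    axis_kind
        ``"time"`` for a time-lapse, ``"z"`` for a z-stack.
    pixel_size_um
        In-plane pixel size in micrometres (square pixels).
    step
        Frame interval in seconds (``axis_kind="time"``) or slice
        spacing in micrometres (``axis_kind="z"``).
    """

    data: np.ndarray
    axis_kind: str
    pixel_size_um: float
    step: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 2-D or 3-D, got ndim={self.data.ndim}"
            )
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if self.axis_kind not in _AXIS_KINDS:
            raise ValueError(
                f"axis_kind must be one of {_AXIS_KINDS}, got {self.axis_kind!r}"
            )
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if not (self.step > 0):
            raise ValueError("step must be > 0")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    # -- convenience -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def times(self) -> np.ndarray:
        """Frame times in seconds (time axis only)."""
        if self.axis_kind != "time":
            raise ValueError("times() requires axis_kind='time'")
        return np.arange(self.n_frames, dtype=float) * self.step


def read_stack(
    path: str | Path,
    axis_kind: str,
    pixel_size_um: float,
    step: float,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Page order is preserved as frame/slice order.  Metadata is taken from
    the arguments, never from TIFF tags (explicit values win by design).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected 2-D pages, got array of ndim={data.ndim}")
    return ImageStack(
        data=data,
        axis_kind=axis_kind,
        pixel_size_um=pixel_size_um,
        step=step,
        meta={"source": str(path)},
    )


def write_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a stack as a multi-page float32 TIFF; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), stack.data.astype(np.float32), photometric="minisblack")
    return path
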