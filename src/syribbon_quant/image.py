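"""Image containers and OME-TIFF input/output.

Conventions
-----------
Arrays are indexed ``(C, Z, Y, X)`` for multi-channel stacks and ``(T, Y, X)``
for single-plane time series.  Physical voxel sizes are carried as
``(dz, dy, dx)`` in micrometres, matching the array axis order; helper
constructors accept the microscope-style ``(dx, dy, dz)`` ordering where noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Multi-channel 3D voxel grid with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (C, Z, Y, X)
        Raw intensities, arbitrary units.
    voxel_size_zyx : tuple of float
        Voxel edge lengths ``(dz, dy, dx)`` in µm.
    channels : list of str
        One label per channel, e.g. ``["membrane", "RIBEYE", "Bassoon"]``.
    """

    data: np.ndarray
    voxel_size_zyx: tuple[float, float, float]
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"ImageStack data must be (C, Z, Y, X), got shape {self.data.shape}")
        if any(s <= 0 for s in self.voxel_size_zyx):
            raise ValueError("voxel sizes must be positive")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel labels do not match number of channels")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size_zyx
        return dz * dy * dx

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a (Z, Y, X) array."""
        return self.data[self.channel_index(name_or_index)]

    def channel_index(self, name_or_index: str | int) -> int:
        if isinstance(name_or_index, (int, np.integer)):
            return int(name_or_index)
        try:
            return self.channels.index(name_or_index)
        except ValueError:
            raise KeyError(
                f"channel {name_or_index!r} not in {self.channels}"
            ) from None


@dataclass
class TimeSeries:
    """Single-plane fluorescence time series (T, Y, X).

    ``frame_rate`` is in Hz; ``pixel_size_yx`` in µm.  Written to OME-TIFF as
    TZYX with a singleton z-axis.
    """

    data: np.ndarray
    pixel_size_yx: tuple[float, float]
    frame_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"TimeSeries data must be (T, Y, X), got shape {self.data.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate


def write_ome_tiff(path, stack: ImageStack | TimeSeries) -> None:
    """Write a stack or time series as OME-TIFF with physical pixel sizes."""
    if isinstance(stack, ImageStack):
        dz, dy, dx = stack.voxel_size_zyx
        tifffile.imwrite(
            path,
            stack.data.astype(np.float32),
            ome=True,
            metadata={
                "axes": "CZYX",
                "PhysicalSizeX": dx,
                "PhysicalSizeY": dy,
                "PhysicalSizeZ": dz,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZUnit": "µm",
                "Channel": {"Name": stack.channels},
            },
        )
    else:
        dy, dx = stack.pixel_size_yx
        tifffile.imwrite(
            path,
            stack.data[:, None].astype(np.float32),
            ome=True,
            metadata={
                "axes": "TZYX",
                "PhysicalSizeX": dx,
                "PhysicalSizeY": dy,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "TimeIncrement": 1.0 / stack.frame_rate,
                "TimeIncrementUnit": "s",
            },
        )


def read_ome_tiff(path) -> ImageStack | TimeSeries:
    """Read an OME-TIFF written by :func:`write_ome_tiff`."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        ome = tf.ome_metadata
        axes = tf.series[0].axes
    import re

    def _attr(name, default):
        m = re.search(rf'{name}="([0-9.eE+-]+)"', ome or "")
        return float(m.group(1)) if m else default

    dx = _attr("PhysicalSizeX", 1.0)
    dy = _attr("PhysicalSizeY", 1.0)
    if axes.startswith("T") or "T" in axes:
        dt = _attr("TimeIncrement", 0.05)
        arr = np.squeeze(arr)
        if arr.ndim != 3:
            raise ValueError(f"expected single-plane time series, got axes {axes}")
        return TimeSeries(arr, (dy, dx), frame_rate=1.0 / dt)
    dz = _attr("PhysicalSizeZ", 1.0)
    if arr.ndim == 3:
        arr = arr[None]
    names = re.findall(r'Channel[^>]*Name="([^"]*)"', ome or "")
    return ImageStack(arr, (dz, dy, dx), channels=names or None or [])
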