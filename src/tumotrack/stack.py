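"""Calibrated multi-dimensional image container and OME-TIFF I/O.

Axes are fixed as T, Z, C, Y, X. Physical coordinates follow the
pixel-center convention: the center of voxel ``(z, y, x)`` sits at
``((x + 0.5) * lateral_pixel_size, (y + 0.5) * lateral_pixel_size,
(z + 0.5) * z_step)`` µm. All public APIs exchange positions in µm.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import tifffile

from tumotrack.scenario import ValidationError

DEFAULT_CHANNELS: Dict[str, int] = {"nuclei": 0, "pi": 1, "tcell": 2}


@dataclass
class ImageStack:
    """A calibrated T,Z,C,Y,X intensity grid with channel-role map."""

    data: np.ndarray  # float32/uint16, shape (T, Z, C, Y, X)
    channel_roles: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHANNELS))
    lateral_pixel_size: float = 2.0   # µm / px
    z_step: float = 10.0              # µm
    frame_interval: float = 1.0       # h

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValidationError(
                f"stack must have axes (T, Z, C, Y, X); got {self.data.ndim} axes")
        if self.lateral_pixel_size <= 0 or self.z_step <= 0 or self.frame_interval <= 0:
            raise ValidationError("calibration values must be > 0")
        n_c = self.data.shape[2]
        if any(not 0 <= idx < n_c for idx in self.channel_roles.values()):
            raise ValidationError("channel_roles index outside channel axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    def channel(self, role: str) -> np.ndarray:
        """All data of one channel role, shape (T, Z, Y, X)."""
        return self.data[:, :, self.channel_roles[role]]

    def volume(self, role: str, t: int) -> np.ndarray:
        """One channel at one timepoint, shape (Z, Y, X)."""
        return self.data[t, :, self.channel_roles[role]]

    def plane(self, role: str, t: int, z: int) -> np.ndarray:
        return self.data[t, z, self.channel_roles[role]]

    def write(self, path: str | Path) -> None:
        """Write as OME-TIFF with physical calibration and channel names."""
        names = [None] * self.data.shape[2]
        for role, idx in self.channel_roles.items():
            names[idx] = role
        metadata = {
            "axes": "TZCYX",
            "PhysicalSizeX": self.lateral_pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": self.lateral_pixel_size,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": self.z_step,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": self.frame_interval,
            "TimeIncrementUnit": "h",
            "Channel": {"Name": [n if n is not None else f"ch{i}"
                                 for i, n in enumerate(names)]},
        }
        tifffile.imwrite(str(path), self.data, ome=True, metadata=metadata)

    @classmethod
    def read(cls, path: str | Path) -> "ImageStack":
        """Read an OME-TIFF written by :meth:`write` (calibration included)."""
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            ome_xml = tf.ome_metadata
        # normalize to TZCYX, inserting missing axes as singletons
        order = []
        for ax in "TZCYX":
            if ax in axes:
                order.append(axes.index(ax))
        data = np.transpose(data, order) if order != sorted(order) else data
        for pos, ax in enumerate("TZCYX"):
            if ax not in axes:
                data = np.expand_dims(data, pos)
        pixels = _first_pixels_element(ome_xml)
        lateral = float(pixels.get("PhysicalSizeX", 1.0))
        z_step = float(pixels.get("PhysicalSizeZ", 1.0))
        frame_interval = float(pixels.get("TimeIncrement", 1.0))
        roles: Dict[str, int] = {}
        for i, ch in enumerate(e for e in pixels if e.tag.endswith("Channel")):
            name = ch.get("Name")
            if name:
                roles[name] = i
        if not roles:
            roles = dict(DEFAULT_CHANNELS)
        return cls(data=data, channel_roles=roles,
                   lateral_pixel_size=lateral, z_step=z_step,
                   frame_interval=frame_interval)


def _first_pixels_element(ome_xml: str) -> ET.Element:
    root = ET.fromstring(ome_xml)
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            return el
    raise ValueError("no Pixels element in OME metadata")
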