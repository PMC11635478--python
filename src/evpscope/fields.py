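"""Field-of-view container and TIFF I/O.

A :class:`FieldImage` is one imaged region of interest: a dictionary of
per-channel single-plane intensity grids (ADU, float) sharing identical
dimensions, plus the pixel scale in micrometres.  Images are written as
plain single-plane 16-bit unsigned TIFFs, one file per channel, named
``<field_id>_<channel>.tif``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
import tifffile


@dataclass
class FieldImage:
    channels: Dict[str, np.ndarray]
    pixel_size_um: float
    field_id: str = "field"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage needs at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {np.asarray(img).shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel dimension mismatch: {shapes}")
        self.channels = {c: np.asarray(img, dtype=float) for c, img in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def area_um2(self) -> float:
        ny, nx = self.shape
        return ny * nx * self.pixel_size_um**2

    def save(self, directory: str | os.PathLike) -> dict[str, str]:
        """Write one 16-bit TIFF per channel; returns channel -> path."""
        os.makedirs(directory, exist_ok=True)
        paths: dict[str, str] = {}
        for c, img in self.channels.items():
            path = os.path.join(str(directory), f"{self.field_id}_{c}.tif")
            data = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
            tifffile.imwrite(path, data)
            paths[c] = path
        return paths

    @classmethod
    def load(
        cls,
        channel_paths: Mapping[str, str | os.PathLike],
        pixel_size_um: float,
        field_id: str = "field",
    ) -> "FieldImage":
        """Read single-plane TIFFs; channel order follows the mapping order."""
        channels = {}
        for c, path in channel_paths.items():
            img = tifffile.imread(os.fspath(path))
            if img.ndim != 2:
                raise ValueError(f"{path}: expected a single-plane image, got shape {img.shape}")
            channels[c] = np.asarray(img, dtype=float)
        return cls(channels=channels, pixel_size_um=pixel_size_um, field_id=field_id)
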