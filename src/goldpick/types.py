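"""Core in-memory containers shared across the pipeline.

Coordinate convention (used everywhere in this package): rasters are indexed
``[row, col]``; particle positions are 0-based ``(x_px, y_px)`` with ``x``
the column and ``y`` the row, and pixel centers at integer coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImagePlane",
    "MaskImage",
    "GroundTruthParticle",
    "ParticleRecord",
]


@dataclass
class ImagePlane:
    """A 2-D single-channel intensity raster with a physical pixel size.

    ``data`` is float32 in [0, 1] internally; 8/16-bit integer rasters are
    rescaled on load by :func:`goldpick.io_export.read_image`.
    """

    data: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError(f"ImagePlane must be 2-D, got shape {self.data.shape}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class MaskImage:
    """Per-pixel annotation raster aligned 1:1 with an :class:`ImagePlane`.

    Values are float32 in [0, 1]: exactly {0, 1} for rendered target masks,
    continuous for generator output (binarized later by the extraction stage).
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValueError(f"MaskImage must be 2-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class GroundTruthParticle:
    """One simulated gold particle: true sub-pixel center and nominal size."""

    x_px: float
    y_px: float
    diameter_nm: float


@dataclass(frozen=True)
class ParticleRecord:
    """One detected particle.

    ``group`` is a 0-based size-group label ordered by ascending mean group
    area; ``diameter_nm_est`` is the equivalent-circle diameter
    ``2*sqrt(area/pi)*pixel_size_nm``.
    """

    x_px: float
    y_px: float
    area_px: int
    group: int
    diameter_nm_est: float
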