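"""Core voxel-volume container shared by every pipeline stage.

A :class:`VoxelVolume` is a 3-D scalar density grid (arbitrary density
units, proportional to local electron density in phase-contrast CT) with
an isotropic physical voxel size in micrometres.  Axis order is (z, y, x),
voxel indices are 0-based, and the physical position of a voxel is
``(index + 0.5) * voxel_size`` — voxel values live at voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class IchdQuantError(Exception):
    """Base class for all package errors."""


class PlacementError(IchdQuantError):
    """Synthetic objects could not be placed without violating packing bounds."""


class DegenerateHistogramError(IchdQuantError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


class InsufficientDataError(IchdQuantError):
    """Too few observations for the requested model."""


@dataclass
class VoxelVolume:
    """3-D scalar grid with physical voxel size.

    Parameters
    ----------
    values
        3-D array of densities, axis order (z, y, x).
    voxel_size
        Isotropic voxel edge length in µm; must be > 0.
    meta
        Free-form provenance metadata (seed, source path, config hash ...).
    """

    values: np.ndarray
    voxel_size: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in µm³."""
        return float(self.voxel_size) ** 3

    @property
    def total_volume_um3(self) -> float:
        """Physical volume of the whole grid in µm³."""
        return self.values.size * self.voxel_volume_um3

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (µm) of voxel centres along one axis."""
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.voxel_size
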