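"""Shared in-memory containers for images, nuclei and FISH signals.

Conventions used throughout the package:

* voxel arrays are indexed ``(Z, Y, X)`` (2D images ``(Y, X)``);
* ``voxel_size`` is given in the same order, ``(dz, dy, dx)`` micrometres;
* physical coordinates are voxel-centre positions in micrometres, ordered
  ``(x, y, z)``, with the centre of voxel ``(iz, iy, ix)`` at
  ``((ix + 0.5) dx, (iy + 0.5) dy, (iz + 0.5) dz)``;
* all distances are computed in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


def phys_to_index(points: np.ndarray, voxel_size: Sequence[float]) -> np.ndarray:
    """Convert physical (x, y, z) coordinates to fractional (z, y, x) indices."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vs = np.asarray(voxel_size, dtype=float)  # (dz, dy, dx)
    idx = pts[:, ::-1] / vs - 0.5
    return idx if np.asarray(points).ndim > 1 else idx[0]


def index_to_phys(indices: np.ndarray, voxel_size: Sequence[float]) -> np.ndarray:
    """Convert (z, y, x) voxel indices to physical (x, y, z) coordinates."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    vs = np.asarray(voxel_size, dtype=float)
    pts = (idx + 0.5) * vs
    pts = pts[:, ::-1]
    return pts if np.asarray(indices).ndim > 1 else pts[0]


@dataclass
class VoxelImage:
    """A single-channel intensity grid with physical voxel sizes.

    ``data`` is (Z, Y, X) for 3D stacks or (Y, X) for 2D images; ``voxel_size``
    matches the array order ((dz, dy, dx) or (dy, dx)).
    """

    data: np.ndarray
    voxel_size: tuple
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.data.ndim != len(self.voxel_size):
            raise ValueError(
                f"voxel_size has {len(self.voxel_size)} entries for a "
                f"{self.data.ndim}-dimensional image"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class NucleusModel:
    """Binary nuclear mask plus tail/head landmarks and axis measurements.

    ``tail_point``/``head_point`` are physical (x, y, z) positions; ``length_L``
    is the tail-to-head distance and ``widest_diameter_D`` the maximum caliper
    extent of the mask measured orthogonally to the tail->head axis.  For
    synthetic nuclei ``geometry`` retains the analytic ellipsoid so that exact
    ground-truth distances remain available.
    """

    mask: np.ndarray
    voxel_size: tuple
    tail_point: Optional[np.ndarray] = None
    head_point: Optional[np.ndarray] = None
    length_L: Optional[float] = None
    widest_diameter_D: Optional[float] = None
    volume: Optional[float] = None
    geometry: object = None  # EllipsoidGeometry for synthetic nuclei

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        for name in ("tail_point", "head_point"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def mask_volume(self) -> float:
        """Volume of the binary mask (voxel count x voxel volume), um^3."""
        return float(self.mask.sum()) * self.voxel_volume

    def axis_unit(self) -> np.ndarray:
        if self.tail_point is None or self.head_point is None:
            raise ValueError("nucleus has no tail/head landmarks")
        v = self.head_point - self.tail_point
        n = float(np.linalg.norm(v))
        if n == 0:
            raise ValueError("degenerate tail->head axis")
        return v / n


@dataclass
class FishSignal:
    """One detected (or planted) FISH signal.

    Non-rendered signals are local maxima that passed the presence gate but not
    the rendering gate; they carry a centroid but no voxel support.
    """

    channel: str
    centroid: np.ndarray  # physical (x, y, z); (x, y) in 2D mode
    voxel_count: int = 0
    peak_intensity: float = 0.0
    rendered: bool = True

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.rendered and self.voxel_count < 1:
            raise ValueError("rendered signals must occupy at least one voxel")
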