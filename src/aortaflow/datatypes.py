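"""Core containers shared across the pipeline.

Unit conventions used throughout the package:

* lengths and coordinates in **mm** (world axes aligned with voxel axes,
  voxel ``(i, j, k)`` centered at ``(i, j, k) * voxel_size``),
* velocities in **m/s**,
* times in **ms** (frame duration) — converted to seconds only where a
  physical rate is needed,
* wall shear stress in **N/m²** (Pa),
* dynamic viscosity in **Pa·s**.

Velocity data are stored as ``(n_frames, nx, ny, nz, 3)`` arrays; magnitude
images as ``(n_frames, nx, ny, nz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VelocityField4D",
    "LumenMask",
    "SurfaceMesh",
    "Centerline",
    "SegmentPartition",
    "WSSMap",
    "SEGMENT_NAMES",
    "ZONE_NAMES",
]

#: Anatomic names of the ten wall segments, indexed by label 1..10.
SEGMENT_NAMES = {
    1: "proximal inner AAo",
    2: "proximal outer AAo",
    3: "distal inner AAo",
    4: "distal outer AAo",
    5: "inner arch",
    6: "outer arch",
    7: "proximal inner DAo",
    8: "proximal outer DAo",
    9: "distal inner DAo",
    10: "distal outer DAo",
}

#: Longitudinal zones (1..5); each zone splits into inner/outer segments.
ZONE_NAMES = {
    1: "proximal AAo",
    2: "distal AAo",
    3: "arch",
    4: "proximal DAo",
    5: "distal DAo",
}

#: Region -> longitudinal zones, used for regional peak-velocity analysis.
REGION_ZONES = {"AAo": (1, 2), "arch": (3,), "DAo": (4, 5)}


@dataclass
class VelocityField4D:
    """Time-resolved three-component voxel velocity field.

    Attributes
    ----------
    values : ndarray, shape (n_frames, nx, ny, nz, 3)
        Velocity components along the world x/y/z axes, m/s.
    voxel_size : ndarray, shape (3,)
        Voxel edge lengths, mm.
    frame_duration : float
        Temporal resolution, ms.
    venc : ndarray, shape (3,)
        Velocity-encoding limit per component, m/s.  Stored phase-contrast
        values alias (wrap) outside ``[-venc, +venc)``.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    frame_duration: float
    venc: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise ValueError("values must have shape (n_frames, nx, ny, nz, 3)")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.venc = np.broadcast_to(np.asarray(self.venc, dtype=float), (3,)).copy()
        if np.any(self.venc <= 0):
            raise ValueError("venc must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:4]

    def speed(self, frame: Optional[int] = None) -> np.ndarray:
        """Speed |v| per voxel, for one frame or all frames."""
        v = self.values if frame is None else self.values[frame]
        return np.linalg.norm(v, axis=-1)

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) of voxel centers."""
        nx, ny, nz = self.grid_shape
        return (
            np.arange(nx) * self.voxel_size[0],
            np.arange(ny) * self.voxel_size[1],
            np.arange(nz) * self.voxel_size[2],
        )

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            self.values.copy(), self.voxel_size.copy(),
            self.frame_duration, self.venc.copy(),
        )


@dataclass
class LumenMask:
    """Binary vessel segmentation with its provenance."""

    mask: np.ndarray
    voxel_size: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SurfaceMesh:
    """Closed triangulated lumen boundary with outward normals.

    vertices in mm; ``vertex_areas`` is one third of the incident triangle
    area per vertex so that ``vertex_areas.sum()`` equals the surface area.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    vertex_areas: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def area(self) -> float:
        return float(self.vertex_areas.sum())


@dataclass
class Centerline:
    """Ordered vessel centerline with differential geometry.

    points (mm), cumulative ``arc_length`` (mm, strictly increasing), unit
    ``tangents`` and ``curvature`` vectors (mm⁻¹, pointing toward the local
    center of curvature).
    """

    points: np.ndarray
    arc_length: np.ndarray
    tangents: np.ndarray
    curvature: np.ndarray

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def arc_fraction(self) -> np.ndarray:
        return self.arc_length / self.arc_length[-1]


@dataclass
class SegmentPartition:
    """Per-vertex assignment to the 10 anatomic wall segments.

    ``labels`` holds 1..10, or 0 for unassigned vertices. ``landmarks`` are
    the arc-length fractions separating the five longitudinal zones.
    """

    labels: np.ndarray
    landmarks: tuple

    def vertices_of(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class WSSMap:
    """Vertex-wise wall shear stress over time plus its systolic average.

    ``vectors``: (n_frames, n_vertices, 3) N/m²; ``wss_sys``: per-vertex mean
    |WSS| over the five frames centered on ``peak_frame``; ``valid``: vertices
    whose wall-normal samples stayed inside the field domain.
    """

    vectors: np.ndarray
    wss_sys: np.ndarray
    peak_frame: int
    frames_averaged: tuple
    valid: np.ndarray

    def magnitude(self, frame: int) -> np.ndarray:
        return np.linalg.norm(self.vectors[frame], axis=-1)
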