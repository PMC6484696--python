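"""In-memory imaging containers: volumes, masks, 2D slices and multi-slice stacks.

Conventions (used throughout the package):

* world frame is RAS in millimetres; voxel indices are 0-based;
* a :class:`Volume` couples a 3D scalar grid with a 4x4 voxel-index -> world
  affine (as in NIfTI-1);
* a :class:`Stack` is an ordered list of parallel 2D :class:`Slice` objects;
  the slice axis is always the third grid axis when a stack is materialised
  as a 3D array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform


@dataclass
class Volume:
    """3D scalar grid plus voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume payload must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def inv_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = self.inv_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def sample(self, world_pts: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate the grid at world points (.., 3); outside -> ``cval``."""
        pts = np.asarray(world_pts, dtype=float)
        idx = self.world_to_index(pts.reshape(-1, 3))
        vals = ndimage.map_coordinates(
            self.data.astype(float, copy=False), idx.T, order=order, cval=cval, mode="constant"
        )
        return vals.reshape(pts.shape[:-1])

    def contains(self, world_pts: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(np.asarray(world_pts, dtype=float).reshape(-1, 3))
        shape = np.asarray(self.shape)
        ok = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
        return ok.reshape(np.asarray(world_pts).shape[:-1])

    def grid_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.index_to_world(idx).reshape(*self.shape, 3)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


@dataclass
class Mask:
    """Binary region of interest sharing a parent :class:`Volume` grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask payload must be 3D")
        if not self.data.any():
            raise ValueError("mask is empty")
        self.affine = np.asarray(self.affine, dtype=float)

    def as_volume(self) -> Volume:
        return Volume(self.data.astype(float), self.affine)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def centroid_world(self) -> np.ndarray:
        idx = np.argwhere(self.data).mean(axis=0)
        return Volume(self.data.astype(float), self.affine).index_to_world(idx)

    def sample(self, world_pts: np.ndarray) -> np.ndarray:
        return self.as_volume().sample(world_pts, order=1)

    def bounding_box_world(self) -> tuple:
        """(min_corner, max_corner) in world mm over all 8 corners of the index bbox."""
        idx = np.argwhere(self.data)
        lo, hi = idx.min(axis=0).astype(float), idx.max(axis=0).astype(float)
        corners = np.array(
            [[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1]) for c in (lo[2], hi[2])]
        )
        w = Volume(self.data.astype(float), self.affine).index_to_world(corners)
        return w.min(axis=0), w.max(axis=0)


@dataclass
class SliceGeometry:
    """Geometry of one 2D slice (or of a whole stack of parallel slices).

    ``orientation`` columns are the unit direction cosines of the two in-plane
    pixel axes and the through-plane normal; ``origin`` is the world position
    of pixel (0, 0). ``slice_step`` is the centre-to-centre distance between
    neighbouring slices: with the default 2.5 mm thickness and 1.25 mm overlap,
    step = thickness - overlap = 1.25 mm (2x through-plane oversampling).
    """

    in_plane_spacing: np.ndarray = field(default_factory=lambda: np.array([1.25, 1.25]))
    thickness: float = 2.5
    slice_step: float = 1.25
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.in_plane_spacing = np.asarray(self.in_plane_spacing, dtype=float).reshape(2)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.thickness <= 0 or self.slice_step <= 0 or np.any(self.in_plane_spacing <= 0):
            raise ValueError("slice geometry lengths must be positive")

    @property
    def overlap(self) -> float:
        return self.thickness - self.slice_step

    @property
    def normal(self) -> np.ndarray:
        return self.orientation[:, 2]

    def shifted(self, n_steps: float) -> "SliceGeometry":
        """Geometry of the slice ``n_steps`` slice-steps along the normal."""
        return replace(self, origin=self.origin + n_steps * self.slice_step * self.normal)

    def pixel_world(self, shape: tuple) -> np.ndarray:
        """World coordinates of pixel centres for a ``shape=(nu, nv)`` grid."""
        nu, nv = shape
        uu, vv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
        du = self.in_plane_spacing[0] * self.orientation[:, 0]
        dv = self.in_plane_spacing[1] * self.orientation[:, 1]
        return (
            self.origin[None, None, :]
            + uu[..., None] * du[None, None, :]
            + vv[..., None] * dv[None, None, :]
        )

    def corners_world(self, shape: tuple) -> np.ndarray:
        nu, nv = shape
        du = self.in_plane_spacing[0] * self.orientation[:, 0]
        dv = self.in_plane_spacing[1] * self.orientation[:, 1]
        return np.array(
            [
                self.origin,
                self.origin + (nu - 1) * du,
                self.origin + (nv - 1) * dv,
                self.origin + (nu - 1) * du + (nv - 1) * dv,
            ]
        )


@dataclass
class Slice:
    """One acquired 2D image with its current motion estimate and robust weight."""

    pixels: np.ndarray
    geometry: SliceGeometry
    index_in_stack: int
    transform: RigidTransform = field(default_factory=RigidTransform)
    scale: float = 1.0
    weight: float = 1.0
    excluded: bool = False
    stack_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("slice weight must lie in [0, 1]")
        if self.scale <= 0:
            raise ValueError("slice scale must be positive")

    def pixel_world(self) -> np.ndarray:
        return self.geometry.pixel_world(self.pixels.shape)

    def corners_world(self) -> np.ndarray:
        return self.geometry.corners_world(self.pixels.shape)

    def shallow_copy(self) -> "Slice":
        return replace(self)


def interleaved_order(n_slices: int) -> np.ndarray:
    """Odd/even interleaved acquisition order (0-based even positions first)."""
    return np.concatenate([np.arange(0, n_slices, 2), np.arange(1, n_slices, 2)])


@dataclass
class Stack:
    """Ordered multi-slice 2D acquisition sharing one orientation."""

    slices: List[Slice]
    acquisition_order: np.ndarray = None
    id: str = ""

    def __post_init__(self):
        if not self.slices:
            raise ValueError("stack must contain at least one slice")
        if self.acquisition_order is None:
            self.acquisition_order = interleaved_order(len(self.slices))
        self.acquisition_order = np.asarray(self.acquisition_order, dtype=int)
        if sorted(self.acquisition_order.tolist()) != list(range(len(self.slices))):
            raise ValueError("acquisition_order must be a permutation of slice indices")
        ref = self.slices[0].geometry
        for s in self.slices:
            if not np.allclose(s.geometry.orientation, ref.orientation):
                raise ValueError("all slices in a stack must share orientation")
            if not np.allclose(s.geometry.in_plane_spacing, ref.in_plane_spacing):
                raise ValueError("all slices in a stack must share in-plane spacing")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def geometry(self) -> SliceGeometry:
        return self.slices[0].geometry

    def as_volume(self) -> Volume:
        """Materialise the stack as a 3D volume (slice axis third).

        Through-plane voxel size equals ``slice_step`` (centre-to-centre);
        slice thickness is acquisition metadata, not grid spacing.
        """
        shapes = {s.pixels.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError("stack slices have inconsistent pixel grids")
        data = np.stack([s.pixels for s in self.slices], axis=2)
        g0 = self.slices[0].geometry
        aff = np.eye(4)
        aff[:3, 0] = g0.in_plane_spacing[0] * g0.orientation[:, 0]
        aff[:3, 1] = g0.in_plane_spacing[1] * g0.orientation[:, 1]
        aff[:3, 2] = g0.slice_step * g0.orientation[:, 2]
        aff[:3, 3] = g0.origin
        return Volume(data, aff)

    def shallow_copy(self) -> "Stack":
        return Stack(
            [s.shallow_copy() for s in self.slices],
            acquisition_order=self.acquisition_order.copy(),
            id=self.id,
        )


def axis_aligned_affine(shape, spacing, origin=None) -> np.ndarray:
    """Convenience affine for an axis-aligned grid centred at the world origin."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    shape = np.asarray(shape)
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    if origin is None:
        origin = -spacing * (shape - 1) / 2.0
    aff[:3, 3] = origin
    return aff
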