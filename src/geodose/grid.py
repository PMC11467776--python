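"""Axis-aligned 3D sampling lattices shared by CT, dose and integrated volumes.

Conventions (used package-wide, asserted in the test suite):

* Patient coordinates are the DICOM patient coordinate system (LPS), in
  millimetres.
* Grid metadata (``origin``, ``spacing``, ``dims``) is ordered ``(x, y, z)``;
  ``origin`` is the centre of voxel ``(0, 0, 0)``.
* Arrays are indexed ``[z, y, x]`` (axial slice first), voxel indices are
  0-based, grid intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class VolumeGrid:
    """Regular sampling lattice in patient coordinates.

    Parameters
    ----------
    origin : tuple of float
        (x, y, z) mm position of the centre of voxel (0, 0, 0).
    spacing : tuple of float
        (x, y, z) mm voxel pitch; all entries strictly positive.
    dims : tuple of int
        (nx, ny, nz) voxel counts; all entries >= 1.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must each have 3 entries")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape, (nz, ny, nx)."""
        nx, ny, nz = self.dims
        return (nz, ny, nx)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along ``axis`` (0=x, 1=y, 2=z), mm."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) voxel-centre coordinate arrays, shape-compatible
        with ``[z, y, x]``-indexed volumes."""
        x = self.axis_coords(0)[np.newaxis, np.newaxis, :]
        y = self.axis_coords(1)[np.newaxis, :, np.newaxis]
        z = self.axis_coords(2)[:, np.newaxis, np.newaxis]
        return x, y, z

    def world_to_continuous_index(self, points_xyz: np.ndarray) -> np.ndarray:
        """Map (N, 3) world mm points to continuous (x, y, z) voxel indices."""
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_index(self, idx_xyz: np.ndarray) -> np.ndarray:
        """True where rounded (x, y, z) indices fall inside the grid."""
        idx = np.atleast_2d(idx_xyz)
        dims = np.asarray(self.dims)
        return np.all((idx >= -0.5) & (idx <= dims - 0.5), axis=-1)

    def validate_volume(self, values: np.ndarray) -> None:
        if tuple(values.shape) != self.shape:
            raise ValueError(
                f"volume shape {values.shape} does not match grid shape {self.shape}"
            )


def resample_volume(
    values: np.ndarray, grid: VolumeGrid, target_spacing: tuple[float, float, float]
) -> tuple[np.ndarray, VolumeGrid]:
    """Trilinearly resample a volume to a new spacing covering the same extent.

    Idempotent when the spacing already matches. Output voxel centres start at
    the input origin and step by ``target_spacing`` while staying inside the
    input voxel-centre extent (no extrapolation).
    """
    ts = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in ts):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    grid.validate_volume(values)
    if ts == grid.spacing:
        return values.copy(), grid

    new_dims = tuple(
        max(1, int(np.floor((grid.dims[a] - 1) * grid.spacing[a] / ts[a] + 1e-9)) + 1)
        for a in range(3)
    )
    out_grid = VolumeGrid(origin=grid.origin, spacing=ts, dims=new_dims)
    # map output voxel centres to input continuous indices, per axis
    idx = [
        (out_grid.axis_coords(a) - grid.origin[a]) / grid.spacing[a] for a in range(3)
    ]
    zz, yy, xx = np.meshgrid(idx[2], idx[1], idx[0], indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(values, dtype=float), [zz, yy, xx], order=1, mode="nearest"
    )
    return out, out_grid


def extract_subvolume(
    values: np.ndarray,
    grid: VolumeGrid,
    center: tuple[float, float, float],
    dims: tuple[int, int, int],
    max_pad: int | None = None,
) -> tuple[np.ndarray, VolumeGrid]:
    """Extract a zero-padded block of ``dims`` voxels centred on the voxel
    nearest ``center`` (world mm).

    Out-of-grid regions are zero-filled. ``max_pad`` bounds the allowed padding
    per face (voxels); a request needing more raises ``ValueError``.
    """
    grid.validate_volume(values)
    dims = tuple(int(d) for d in dims)
    if any(d < 1 for d in dims):
        raise ValueError(f"subvolume dims must be >= 1, got {dims}")
    cidx = np.rint(grid.world_to_continuous_index(center)[0]).astype(int)
    start = [cidx[a] - dims[a] // 2 for a in range(3)]  # (x, y, z) start indices
    if max_pad is not None:
        for a in range(3):
            lo_pad = max(0, -start[a])
            hi_pad = max(0, start[a] + dims[a] - grid.dims[a])
            if lo_pad > max_pad or hi_pad > max_pad:
                raise ValueError(
                    f"subvolume axis {a} needs padding beyond max_pad={max_pad}"
                )
    out = np.zeros((dims[2], dims[1], dims[0]), dtype=np.asarray(values).dtype)
    # source / destination slice per axis, clipped to the grid
    src, dst = [], []
    for a in range(3):
        s0 = max(start[a], 0)
        s1 = min(start[a] + dims[a], grid.dims[a])
        if s1 <= s0:
            raise ValueError("subvolume lies entirely outside the grid")
        src.append(slice(s0, s1))
        dst.append(slice(s0 - start[a], s1 - start[a]))
    out[dst[2], dst[1], dst[0]] = values[src[2], src[1], src[0]]
    sub_origin = tuple(grid.origin[a] + start[a] * grid.spacing[a] for a in range(3))
    return out, VolumeGrid(origin=sub_origin, spacing=grid.spacing, dims=dims)


def embed_subvolume(
    block: np.ndarray, block_grid: VolumeGrid, target: np.ndarray, grid: VolumeGrid
) -> np.ndarray:
    """Write ``block`` back into ``target`` at the position its grid records.

    Inverse of :func:`extract_subvolume` for in-grid voxels.
    """
    grid.validate_volume(target)
    block_grid.validate_volume(block)
    start = np.rint(
        (np.asarray(block_grid.origin) - np.asarray(grid.origin))
        / np.asarray(grid.spacing)
    ).astype(int)
    out = target.copy()
    for a in range(3):
        if block_grid.spacing[a] != grid.spacing[a]:
            raise ValueError("block and target spacing differ")
    src, dst = [], []
    for a in range(3):
        s0 = max(start[a], 0)
        s1 = min(start[a] + block_grid.dims[a], grid.dims[a])
        src.append(slice(s0 - start[a], s1 - start[a]))
        dst.append(slice(s0, s1))
    out[dst[2], dst[1], dst[0]] = block[src[2], src[1], src[0]]
    return out
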