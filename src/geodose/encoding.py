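"""Spatial encoding of fluence maps into the CT image domain.

Each fluence map is back-projected from the isocenter plane toward the point
source onto a plane a fixed distance (300 mm by default) from the isocenter,
so the beam-delivery geometry is represented inside the image volume itself:
painted intensities form a ring of radius ~300 mm around the patient, clear of
body and couch, and the result is a single-channel volume holding relative
electron density inside the patient and scaled fluence on the ring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .beam import BeamGeometry
from .fluence import FluenceMap
from .grid import VolumeGrid, extract_subvolume, resample_volume  # noqa: F401

#: Default painted-intensity ceiling: above soft-tissue RED so the fluence
#: signal is salient in the single shared channel.
DEFAULT_FLUENCE_CEILING = 2.0


def backproject_fm(
    fm: FluenceMap, geometry: BeamGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Back-project a fluence map onto the encoding plane.

    A pixel at isocenter-plane offset (u, v) maps to the 3D point on the
    plane perpendicular to the central axis at ``plane_distance`` toward the
    source, with lateral offset scaled by the point-source magnification
    ``(sad - plane_distance) / sad``; intensity is unchanged.

    Returns
    -------
    points : (N, 3) float array, mm, patient coordinates
    intensities : (N,) float array (same order, row-major over [v, u])
    """
    u, v = fm.grid.pixel_centers()
    uu, vv = np.meshgrid(u, v, indexing="xy")  # [v, u] layout
    m = geometry.magnification
    u_hat, v_hat = geometry.fm_axes(fm.gantry_angle)
    e_s = geometry.source_direction(fm.gantry_angle)
    iso = np.asarray(geometry.isocenter)
    pts = (
        iso[None, :]
        + m * uu.reshape(-1, 1) * u_hat[None, :]
        + m * vv.reshape(-1, 1) * v_hat[None, :]
        + geometry.plane_distance * e_s[None, :]
    )
    return pts, fm.intensity.reshape(-1).copy()


@dataclass
class IntegratedVolume:
    """Single-channel network input: RED inside the patient, encoded fluence
    on the 300 mm ring."""

    values: np.ndarray
    grid: VolumeGrid
    painted_mask: np.ndarray  # True where fluence was deposited
    fluence_scale: float
    geometry: BeamGeometry
    meta: dict = field(default_factory=dict)

    def fm_layer(self) -> np.ndarray:
        """The painted fluence component (zero off the ring)."""
        red = np.where(self.painted_mask, 0.0, self.values)
        return self.values - red


def encode_integrated_volume(
    red_volume: np.ndarray,
    grid: VolumeGrid,
    fms: list[FluenceMap],
    geometry: BeamGeometry,
    fluence_scale: float | None = None,
    body_mask: np.ndarray | None = None,
    overlap: str = "warn",
) -> IntegratedVolume:
    """Paint back-projected fluence maps additively into a RED volume.

    Each nonzero FM pixel deposits ``intensity x fluence_scale`` into the
    voxel nearest its back-projected 3D point (points outside the grid are
    dropped). Deposits from all maps accumulate; unpainted voxels keep their
    RED values. With ``fluence_scale=None`` the scale is chosen so the
    maximum accumulated painted value equals ``DEFAULT_FLUENCE_CEILING``; the
    scale actually used is recorded for downstream un-scaling.

    ``body_mask`` (body plus couch), when given, is checked against the
    painted voxels; an intersection warns by default (``overlap="error"``
    raises, ``"ignore"`` silences).
    """
    grid.validate_volume(red_volume)
    if overlap not in ("warn", "error", "ignore"):
        raise ValueError("overlap must be 'warn', 'error' or 'ignore'")
    raw = np.zeros(grid.shape)
    for fm in fms:
        pts, inten = backproject_fm(fm, geometry)
        nz = inten > 0
        if not np.any(nz):
            continue
        idx = np.rint(grid.world_to_continuous_index(pts[nz])).astype(int)
        inside = (
            (idx[:, 0] >= 0) & (idx[:, 0] < grid.dims[0])
            & (idx[:, 1] >= 0) & (idx[:, 1] < grid.dims[1])
            & (idx[:, 2] >= 0) & (idx[:, 2] < grid.dims[2])
        )
        idx = idx[inside]
        np.add.at(raw, (idx[:, 2], idx[:, 1], idx[:, 0]), inten[nz][inside])
    painted = raw > 0
    if fluence_scale is None:
        peak = raw.max()
        fluence_scale = DEFAULT_FLUENCE_CEILING / peak if peak > 0 else 1.0
    if body_mask is not None and np.any(painted & (body_mask > 0)):
        n_bad = int(np.sum(painted & (body_mask > 0)))
        msg = f"{n_bad} painted voxels intersect the body/couch mask"
        if overlap == "error":
            raise ValueError(msg)
        if overlap == "warn":
            warnings.warn(msg, stacklevel=2)
    values = np.where(painted, red_volume + fluence_scale * raw, red_volume)
    return IntegratedVolume(
        values=values,
        grid=grid,
        painted_mask=painted,
        fluence_scale=float(fluence_scale),
        geometry=geometry,
        meta={"n_maps": len(fms)},
    )
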