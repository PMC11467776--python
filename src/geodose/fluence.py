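"""Fluence-map reconstruction from VMAT control points.

A fluence map (FM) is the MU-weighted open-field intensity of the beam over
the treatment field, defined on the plane through the isocenter perpendicular
to the beam central axis. Each control point contributes its MLC-and-jaw
aperture (as fractional pixel open area) times its MU share; contributions
are binned to the nearest sampled gantry angle and summed across arcs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam import BeamGeometry
from .plan import Arc, ControlPoint, PlanModel


@dataclass(frozen=True)
class FluenceGrid:
    """Pixel lattice of a fluence map on the isocenter plane.

    ``origin`` is the (u, v) mm offset of the centre of pixel (0, 0) from the
    beam central axis; intensity matrices are indexed ``[v, u]``.
    """

    pixel_spacing: float = 2.5  # mm at the isocenter plane
    fov: float = 400.0  # mm, square field of view, centred on the axis

    def __post_init__(self) -> None:
        if self.pixel_spacing <= 0 or self.fov <= 0:
            raise ValueError("pixel_spacing and fov must be positive")

    @property
    def n_pixels(self) -> int:
        return int(round(self.fov / self.pixel_spacing))

    @property
    def origin(self) -> tuple[float, float]:
        o = -self.fov / 2 + self.pixel_spacing / 2
        return (o, o)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) centre coordinates, each of length ``n_pixels``."""
        c = self.origin[0] + self.pixel_spacing * np.arange(self.n_pixels)
        return c, c.copy()

    def pixel_edges(self) -> np.ndarray:
        """Shared u/v pixel edge coordinates, length ``n_pixels + 1``."""
        return -self.fov / 2 + self.pixel_spacing * np.arange(self.n_pixels + 1)


@dataclass
class FluenceMap:
    """MU-weighted beam intensity for one sampled gantry angle."""

    gantry_angle: float  # deg
    intensity: np.ndarray  # (n_v, n_u), arbitrary fluence units, >= 0
    grid: FluenceGrid

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = self.grid.n_pixels
        if self.intensity.shape != (n, n):
            raise ValueError("intensity shape does not match fluence grid")
        if np.any(self.intensity < 0):
            raise ValueError("fluence intensity must be non-negative")

    @property
    def total(self) -> float:
        """Integrated intensity x area (fluence units x mm^2)."""
        return float(self.intensity.sum() * self.grid.pixel_spacing**2)


def _interval_overlap(lo: np.ndarray, hi: np.ndarray, a: float, b: float) -> np.ndarray:
    return np.clip(np.minimum(hi, b) - np.maximum(lo, a), 0.0, None)


def rasterize_aperture(
    control_point: ControlPoint,
    fm_grid: FluenceGrid,
    *,
    leaf_boundaries: np.ndarray,
    jaws_x: tuple[float, float],
    jaws_y: tuple[float, float],
) -> np.ndarray:
    """Fractional open area of the MLC-and-jaw aperture over each FM pixel.

    Exact geometric area: the aperture is the union over leaf rows of the
    rectangle [A_r, B_r] x [row_lo, row_hi], intersected with the jaw
    rectangle; each pixel's value is the open fraction of its area, in [0, 1].
    """
    edges = fm_grid.pixel_edges()
    lb = np.asarray(leaf_boundaries, dtype=float)
    if lb[0] > edges[0] + 1e-9 or lb[-1] < edges[-1] - 1e-9:
        raise ValueError(
            f"leaf rows cover [{lb[0]}, {lb[-1]}] mm but the fluence grid "
            f"extends [{edges[0]}, {edges[-1]}] mm"
        )
    n = fm_grid.n_pixels
    s = fm_grid.pixel_spacing
    u_lo, u_hi = edges[:-1], edges[1:]
    out = np.zeros((n, n))
    for r in range(lb.size - 1):
        y0 = max(lb[r], jaws_y[0])
        y1 = min(lb[r + 1], jaws_y[1])
        if y1 <= y0:
            continue
        x0 = max(float(control_point.mlc_a[r]), jaws_x[0])
        x1 = min(float(control_point.mlc_b[r]), jaws_x[1])
        if x1 <= x0:
            continue
        frac_u = _interval_overlap(u_lo, u_hi, x0, x1) / s  # (n,)
        frac_v = _interval_overlap(u_lo, u_hi, y0, y1) / s  # rows share edges
        out += frac_v[:, None] * frac_u[None, :]
    return np.clip(out, 0.0, 1.0)


def _arc_mu_shares(arc: Arc) -> list[tuple[ControlPoint, float]]:
    """(control point, MU share) pairs; the aperture of each delivery segment
    is taken at the segment's later control point."""
    shares = []
    prev_w = 0.0
    for cp in arc.control_points:
        shares.append((cp, (cp.cumulative_weight - prev_w) * arc.beam_mu))
        prev_w = cp.cumulative_weight
    return shares


def control_points_to_fluence_maps(
    plan: PlanModel, geometry: BeamGeometry, fm_grid: FluenceGrid | None = None
) -> list[FluenceMap]:
    """Reconstruct one fluence map per sampled gantry angle, summed over arcs.

    Every control point deposits ``aperture x MU-share`` into the map of the
    sampled angle nearest its gantry angle (exact midpoints round to the
    lower bin). MU is conserved: the integrated intensity of the output
    equals the sum over control points of MU share times aperture open area.
    """
    fm_grid = fm_grid or FluenceGrid()
    n = fm_grid.n_pixels
    maps = np.zeros((geometry.n_angles, n, n))
    for arc in plan.arcs:
        for cp, share in _arc_mu_shares(arc):
            if share == 0.0:
                continue
            aperture = rasterize_aperture(
                cp,
                fm_grid,
                leaf_boundaries=arc.leaf_boundaries,
                jaws_x=arc.jaws_x,
                jaws_y=arc.jaws_y,
            )
            maps[geometry.nearest_angle_bin(cp.gantry_angle)] += share * aperture
    angles = geometry.sampled_angles()
    return [
        FluenceMap(gantry_angle=float(angles[i]), intensity=maps[i], grid=fm_grid)
        for i in range(geometry.n_angles)
    ]
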