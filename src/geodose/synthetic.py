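"""Synthetic pelvic phantoms, VMAT-like plans and an analytic dose oracle.

The clinical data this method targets (CT, optimized arc plans, TPS dose) is
not publicly shareable, so this module generates cases carrying the same
statistical and physical structure the learning task relies on:

* an axial body phantom with heterogeneous relative electron density (RED),
  a central target (PTV) and nearby avoidance structures on a couch slab;
* a full-arc VMAT plan whose apertures conform to the target's beam's-eye
  view plus random dilation/erosion noise, so dose correlates with target
  shape the way optimized plans do;
* a deliberately simple first-principles dose oracle — exponential
  attenuation along the radiological path, point-source inverse-square
  falloff and a Gaussian lateral scatter kernel — that is exactly linear in
  fluence. It is a ground-truth *generator* for the learning task, not a
  clinical dose engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .beam import BeamGeometry
from .fluence import FluenceGrid, FluenceMap, control_points_to_fluence_maps
from .grid import VolumeGrid
from .plan import Arc, ControlPoint, PlanModel

#: Synthetic prescription dose, Gy (SBRT-style prostate level; the scaling
#: augmentation covers other dose levels during training).
DEFAULT_PRESCRIPTION_GY = 45.0


def default_organ_shapes() -> list[tuple]:
    """Pelvic organ layout: (name, shape, center mm, size mm, RED range).

    Shapes are 'sphere' (size = radius) or 'zcylinder' (size = (radius,
    half-length)). Anterior is -y in the LPS frame used package-wide.
    """
    return [
        ("bladder", "sphere", (0.0, -60.0, 0.0), 30.0, (0.95, 1.05)),
        ("rectum", "zcylinder", (0.0, 45.0, 0.0), (15.0, 60.0), (0.45, 0.75)),
        ("femoral_head_l", "sphere", (95.0, 0.0, 0.0), 22.0, (1.25, 1.45)),
        ("femoral_head_r", "sphere", (-95.0, 0.0, 0.0), 22.0, (1.25, 1.45)),
    ]


@dataclass
class PhantomSpec:
    """Geometry and tissue description of one synthetic phantom.

    The target is always centred at the isocenter (grid-coordinate origin).
    ``tissue_red_ranges`` gives per-class (lo, hi) RED draws; the body's
    smooth texture field is added on top of the soft-tissue draw.
    """

    grid: VolumeGrid
    body_semi_axes: tuple[float, float] = (170.0, 110.0)  # mm, (x, y)
    couch_thickness: float = 40.0  # mm
    target_radius: float = 25.0  # mm
    organ_shapes: list[tuple] = field(default_factory=default_organ_shapes)
    tissue_red_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "soft_tissue": (0.96, 1.04),
            "couch": (0.2, 0.3),
            "ptv": (0.98, 1.05),
        }
    )
    texture_amplitude: float = 0.04  # RED units of the smooth body texture
    seed: int = 0

    def validate(self) -> None:
        ext_x = (self.grid.dims[0] - 1) * self.grid.spacing[0] / 2
        ext_y = (self.grid.dims[1] - 1) * self.grid.spacing[1] / 2
        if self.body_semi_axes[0] > ext_x - 30 or self.body_semi_axes[1] > ext_y - 30:
            raise ValueError("structure 'body' does not fit in the grid "
                             "with a 30 mm margin")
        if self.target_radius <= 0:
            raise ValueError("structure 'ptv' is empty (target_radius must be > 0)")
        for name, shape, center, size, _ in self.organ_shapes:
            r = size if np.isscalar(size) else size[0]
            if (abs(center[0]) + r > ext_x) or (abs(center[1]) + r > ext_y):
                raise ValueError(f"structure '{name}' exceeds grid bounds")
        for cls, (lo, hi) in self.tissue_red_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"RED range for '{cls}' invalid: ({lo}, {hi})")


def _shape_mask(grid: VolumeGrid, shape: str, center, size) -> np.ndarray:
    x, y, z = grid.voxel_centers()
    if shape == "sphere":
        r = float(size)
        return ((x - center[0]) ** 2 + (y - center[1]) ** 2
                + (z - center[2]) ** 2) <= r**2
    if shape == "zcylinder":
        r, hl = float(size[0]), float(size[1])
        return (((x - center[0]) ** 2 + (y - center[1]) ** 2) <= r**2) & (
            np.abs(z - center[2]) <= hl
        )
    raise ValueError(f"unknown shape '{shape}'")


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Build the RED volume and named binary masks for one phantom.

    Deterministic given ``spec.seed``. RED is zero outside body and couch,
    in [0, 2] inside.
    """
    spec.validate()
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    x, y, z = grid.voxel_centers()

    ax, ay = spec.body_semi_axes
    body = ((x / ax) ** 2 + (y / ay) ** 2) <= 1.0
    body = np.broadcast_to(body, grid.shape).copy()

    couch_top = ay + 10.0  # 10 mm air gap below the posterior skin
    couch = (y >= couch_top) & (y <= couch_top + spec.couch_thickness)
    couch = np.broadcast_to(couch & (np.abs(x) <= ax + 60), grid.shape).copy()

    masks: dict[str, np.ndarray] = {"body": body, "couch": couch}
    masks["ptv"] = _shape_mask(grid, "sphere", (0, 0, 0), spec.target_radius) & body
    if not masks["ptv"].any():
        raise ValueError("structure 'ptv' is empty on this grid")

    draw = {c: rng.uniform(lo, hi) for c, (lo, hi) in spec.tissue_red_ranges.items()}
    red = np.zeros(grid.shape)
    texture = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=2.0)
    tex_scale = texture.std() or 1.0
    red[body] = draw["soft_tissue"] + spec.texture_amplitude * (
        texture[body] / tex_scale
    )
    for name, shape, center, size, (lo, hi) in spec.organ_shapes:
        m = _shape_mask(grid, shape, center, size) & body
        masks[f"oar_{name}"] = m
        red[m] = rng.uniform(lo, hi)
    red[masks["ptv"]] = draw["ptv"]
    red[couch] = draw["couch"]
    np.clip(red, 0.0, 2.0, out=red)
    red[~(body | couch)] = 0.0
    return red, masks


# ---------------------------------------------------------------------------
# plan generation


def generate_plan(
    masks: dict[str, np.ndarray],
    geometry: BeamGeometry,
    n_arcs: int = 1,
    seed: int = 0,
    *,
    grid: VolumeGrid,
    fm_grid: FluenceGrid | None = None,
    leaf_width: float = 10.0,
    margin: float = 6.0,
    aperture_noise_mm: float = 3.0,
    mu_range: tuple[float, float] = (300.0, 500.0),
) -> PlanModel:
    """Generate a VMAT-like plan: one control point per sampled gantry angle
    per arc, apertures conformal to the target's beam's-eye-view projection
    with random per-leaf dilation/erosion noise, positive meterset shares
    summing to the plan MU.
    """
    if "ptv" not in masks or not masks["ptv"].any():
        raise ValueError("empty target mask: cannot generate a plan")
    fm_grid = fm_grid or FluenceGrid()
    rng = np.random.default_rng(seed)

    zi, yi, xi = np.nonzero(masks["ptv"])
    pts = np.stack(
        [
            grid.origin[0] + grid.spacing[0] * xi,
            grid.origin[1] + grid.spacing[1] * yi,
            grid.origin[2] + grid.spacing[2] * zi,
        ],
        axis=1,
    ) - np.asarray(geometry.isocenter)

    half_fov = fm_grid.fov / 2
    n_rows = int(np.ceil(fm_grid.fov / leaf_width))
    boundaries = -half_fov + leaf_width * np.arange(n_rows + 1)
    boundaries[-1] = max(boundaries[-1], half_fov)

    angles = geometry.sampled_angles()
    t = np.deg2rad(angles)
    # beam's-eye-view extent of the target per angle (parallel projection)
    u = pts[:, 0, None] * np.cos(t)[None, :] + pts[:, 1, None] * np.sin(t)[None, :]
    u_min, u_max = u.min(axis=0), u.max(axis=0)
    v_min, v_max = pts[:, 2].min(), pts[:, 2].max()

    jaw_x = (float(u_min.min() - margin - 10), float(u_max.max() + margin + 10))
    jaw_y = (float(v_min - margin - 10), float(v_max + margin + 10))

    arcs = []
    for _ in range(int(n_arcs)):
        cps = []
        open_rows = (boundaries[1:] > v_min - margin) & (
            boundaries[:-1] < v_max + margin
        )
        for k, ang in enumerate(angles):
            a_edge = np.zeros(n_rows)
            b_edge = np.zeros(n_rows)
            noise = rng.normal(0.0, aperture_noise_mm, size=(n_rows, 2))
            lo = u_min[k] - margin + noise[:, 0]
            hi = u_max[k] + margin + noise[:, 1]
            lo = np.clip(lo, jaw_x[0], jaw_x[1])
            hi = np.clip(hi, jaw_x[0], jaw_x[1])
            bad = hi < lo
            mid = (lo + hi) / 2
            lo[bad] = mid[bad]
            hi[bad] = mid[bad]
            a_edge[open_rows] = lo[open_rows]
            b_edge[open_rows] = hi[open_rows]
            cps.append(
                ControlPoint(
                    gantry_angle=float(ang),
                    mlc_a=a_edge,
                    mlc_b=b_edge,
                    cumulative_weight=0.0,  # filled below
                )
            )
        incr = rng.uniform(0.5, 1.5, size=len(cps))
        cumw = np.cumsum(incr) / incr.sum()
        for cp, w in zip(cps, cumw):
            cp.cumulative_weight = float(w)
        arcs.append(
            Arc(
                control_points=cps,
                leaf_boundaries=boundaries,
                jaws_x=jaw_x,
                jaws_y=jaw_y,
                beam_mu=float(rng.uniform(*mu_range)),
            )
        )
    return PlanModel(
        arcs=arcs,
        isocenter=geometry.isocenter,
        prescription_gy=DEFAULT_PRESCRIPTION_GY,
    )


# ---------------------------------------------------------------------------
# analytic dose oracle


@dataclass(frozen=True)
class OracleConfig:
    """Parameters of the analytic dose oracle.

    ``mu_eff`` is the effective linear attenuation coefficient of the
    water-equivalent medium (1/mm; 0.005 is the order of magnitude of a 6 MV
    beam). ``lateral_sigma`` is the Gaussian scatter-kernel width stated at
    the isocenter plane (mm). ``beamlet_spacing`` is the pitch of the beamlet
    lattice, i.e. the fluence-map pixel spacing the oracle integrates over.
    ``output_factor`` converts MU-weighted fluence to Gy.
    """

    mu_eff: float = 0.005  # 1/mm
    lateral_sigma: float = 5.0  # mm at the isocenter plane
    beamlet_spacing: float = 2.5  # mm
    output_factor: float = 0.2  # Gy per fluence unit
    depth_step_hint: float | None = None  # mm; None -> axial voxel pitch

    def __post_init__(self) -> None:
        if self.mu_eff <= 0:
            raise ValueError("mu_eff must be > 0")
        if self.lateral_sigma < 0:
            raise ValueError("lateral_sigma must be >= 0")
        if self.beamlet_spacing <= 0:
            raise ValueError("beamlet_spacing must be > 0")


def _parallel_depth(
    red: np.ndarray, grid: VolumeGrid, gantry_angle: float, geometry: BeamGeometry
) -> np.ndarray:
    """Radiological depth (mm water-equivalent) of every voxel along the
    beam direction, parallel-ray approximation.

    The RED volume is rotated so the beam travels along +y, depth is the
    half-voxel-centred cumulative sum of RED x pitch, and the result is
    rotated back. Exact for a gantry-0 beam on an axis-aligned slab.
    """
    dy = grid.spacing[1]
    if gantry_angle % 360.0 == 0.0:
        rot = red
    else:
        rot = ndimage.rotate(
            red, gantry_angle, axes=(2, 1), reshape=False, order=1,
            mode="constant", cval=0.0, prefilter=False,
        )
    depth = (np.cumsum(rot, axis=1) - 0.5 * rot) * dy
    if gantry_angle % 360.0 == 0.0:
        return depth
    return ndimage.rotate(
        depth, -gantry_angle, axes=(2, 1), reshape=False, order=1,
        mode="nearest", cval=0.0, prefilter=False,
    )


def oracle_dose_from_fms(
    red: np.ndarray,
    grid: VolumeGrid,
    fms: list[FluenceMap],
    geometry: BeamGeometry,
    cfg: OracleConfig | None = None,
) -> np.ndarray:
    """Analytic dose (Gy) on ``grid`` for a list of fluence maps.

    Per angle, dose(v) = fluence term x exp(-mu_eff x radiological depth)
    x (SAD / source-to-voxel distance)^2. The fluence term is the FM
    convolved with the Gaussian scatter kernel, sampled at each voxel's
    divergent projection onto the isocenter plane (so off-axis beamlets
    spread with the point-source magnification). Exactly linear in the FM
    intensities; beamlets whose rays miss the grid simply contribute nothing.
    """
    cfg = cfg or OracleConfig()
    grid.validate_volume(red)
    iso = np.asarray(geometry.isocenter)
    x, y, z = grid.voxel_centers()
    px = np.broadcast_to(x, grid.shape) - iso[0]
    py = np.broadcast_to(y, grid.shape) - iso[1]
    pz = np.broadcast_to(z, grid.shape) - iso[2]

    dose = np.zeros(grid.shape)
    for fm in fms:
        if not np.any(fm.intensity):
            continue
        s = fm.grid.pixel_spacing
        smooth = (
            ndimage.gaussian_filter(
                fm.intensity, sigma=cfg.lateral_sigma / s, mode="constant", cval=0.0
            )
            if cfg.lateral_sigma > 0
            else fm.intensity
        )
        t = np.deg2rad(fm.gantry_angle)
        # beam frame: zeta = distance from source along the central axis
        lat_u = px * np.cos(t) + py * np.sin(t)
        ax = px * np.sin(t) - py * np.cos(t)  # component toward the source
        zeta = geometry.sad - ax
        with np.errstate(divide="ignore", invalid="ignore"):
            mag = geometry.sad / zeta
        u_iso = lat_u * mag
        v_iso = pz * mag
        o_u, o_v = fm.grid.origin
        fl = ndimage.map_coordinates(
            smooth,
            [(v_iso - o_v) / s, (u_iso - o_u) / s],
            order=1,
            mode="constant",
            cval=0.0,
        )
        d_sv2 = zeta**2 + lat_u**2 + pz**2
        depth = _parallel_depth(red, grid, fm.gantry_angle, geometry)
        dose += fl * np.exp(-cfg.mu_eff * depth) * (geometry.sad**2 / d_sv2)
    return cfg.output_factor * dose


def oracle_dose(
    red: np.ndarray,
    grid: VolumeGrid,
    plan: PlanModel,
    geometry: BeamGeometry,
    cfg: OracleConfig | None = None,
    fm_grid: FluenceGrid | None = None,
) -> np.ndarray:
    """Analytic dose for a plan: reconstruct its fluence maps, then integrate."""
    cfg = cfg or OracleConfig()
    fm_grid = fm_grid or FluenceGrid(pixel_spacing=cfg.beamlet_spacing)
    fms = control_points_to_fluence_maps(plan, geometry, fm_grid)
    return oracle_dose_from_fms(red, grid, fms, geometry, cfg)
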