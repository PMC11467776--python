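"""Dosimetric comparison of estimated vs ground-truth dose.

Implements global-normalization γ-index analysis, cumulative DVH curves,
the D98/D95/Dmax/Dmin/Dmean family of structure metrics, and the
prescription-normalized relative error (estimate - ground truth) / Rx x 100%.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid


@dataclass(frozen=True)
class GammaCriteria:
    """γ-analysis configuration.

    ``dose_tolerance`` is the dose-difference criterion in % of the global
    maximum of the reference distribution; ``dta`` the distance-to-agreement
    in mm; ``threshold`` excludes voxels whose reference dose falls below
    this % of the reference maximum.
    """

    dose_tolerance: float = 3.0  # %
    dta: float = 2.0  # mm
    threshold: float = 10.0  # %
    normalization: str = "global"

    def __post_init__(self) -> None:
        if self.dose_tolerance <= 0 or self.dta <= 0 or self.threshold <= 0:
            raise ValueError("gamma criteria must be strictly positive")
        if self.normalization != "global":
            raise ValueError("only global normalization is supported")

    @property
    def label(self) -> str:
        return f"{self.dose_tolerance:g}%/{self.dta:g}mm"


def _search_offsets(
    spacing: tuple[float, ...], radius: float, step: float
) -> np.ndarray:
    """All displacement vectors (mm) within ``radius``, on a ``step`` lattice
    that contains the origin exactly."""
    k = int(np.floor(radius / step + 1e-9))
    axis = np.arange(-k, k + 1) * step
    offs = np.array(list(itertools.product(*[axis] * len(spacing))))
    return offs[np.linalg.norm(offs, axis=1) <= radius + 1e-12]


def gamma_index(
    reference: np.ndarray,
    evaluated: np.ndarray,
    spacing: tuple[float, ...],
    criteria: GammaCriteria = GammaCriteria(),
    *,
    step: float | None = None,
    search_radius_factor: float = 3.0,
) -> tuple[np.ndarray, float]:
    """Per-voxel γ and the pass rate (% of evaluable voxels with γ <= 1).

    γ(r) = min over candidate points e of
    sqrt((ΔD(r, e) / (tol% x Dmax_ref))^2 + (|r - e|/dta)^2), with the
    evaluated distribution interpolated linearly on a sub-voxel lattice
    (``step`` mm, default 0.2 in 2D and 1.0 in 3D) out to
    ``search_radius_factor x dta``. Works on 2D slices or 3D volumes;
    ``spacing`` is in array-axis order. Voxels below the low-dose threshold
    get γ = NaN and are excluded from the pass rate.
    """
    reference = np.asarray(reference, dtype=float)
    evaluated = np.asarray(evaluated, dtype=float)
    if reference.shape != evaluated.shape:
        raise ValueError("reference and evaluated must share a grid")
    if len(spacing) != reference.ndim:
        raise ValueError("one spacing entry per array axis required")
    d_max = reference.max()
    if d_max <= 0:
        raise ValueError("no evaluable voxels: reference dose is non-positive")
    include = reference >= criteria.threshold / 100.0 * d_max
    if not include.any():
        raise ValueError("no evaluable voxels above the dose threshold")
    tol = criteria.dose_tolerance / 100.0 * d_max
    if step is None:
        step = 0.2 if reference.ndim == 2 else 1.0
    radius = search_radius_factor * criteria.dta

    ref_vals = reference[include]
    base_idx = np.stack(
        [c.astype(float) for c in np.nonzero(include)]
    )  # (ndim, n)
    sp = np.asarray(spacing, dtype=float)
    best = np.full(ref_vals.shape, np.inf)
    for off in _search_offsets(tuple(sp), radius, step):
        dist2 = float(np.sum(off**2)) / criteria.dta**2
        if dist2 > best.max():
            continue
        coords = base_idx + (off / sp)[:, None]
        ev = ndimage.map_coordinates(
            evaluated, coords, order=1, mode="constant", cval=np.nan
        )
        cand = (ref_vals - ev) ** 2 / tol**2 + dist2
        np.fmin(best, cand, out=best)  # fmin ignores NaN candidates
    gamma_vals = np.sqrt(best)
    gamma_map = np.full(reference.shape, np.nan)
    gamma_map[include] = gamma_vals
    pass_rate = 100.0 * float(np.mean(gamma_vals <= 1.0))
    return gamma_map, pass_rate


def dvh(
    dose: np.ndarray, mask: np.ndarray, bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-volume histogram of ``dose`` within ``mask``.

    Returns (dose levels Gy, % volume receiving at least that dose); the
    curve starts at 100% at 0 Gy and is monotone non-increasing. Dx% is
    recoverable by inverse lookup within one bin width.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = np.asarray(dose, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty structure mask: cannot compute a DVH")
    levels = np.arange(0.0, vals.max() + 2 * bin_width, bin_width)
    counts = np.searchsorted(np.sort(vals), levels, side="left")
    volume = 100.0 * (vals.size - counts) / vals.size
    return levels, volume


def dvh_inverse(levels: np.ndarray, volume: np.ndarray, x_percent: float) -> float:
    """Largest dose level still covering at least ``x_percent`` of the volume."""
    ok = volume >= x_percent
    if not ok.any():
        return 0.0
    return float(levels[np.nonzero(ok)[0][-1]])


@dataclass(frozen=True)
class DoseMetrics:
    """Structure dose summary, Gy. Dx% is the minimum dose received by the
    hottest x% of the structure's voxels (voxel-count percentile)."""

    d98: float
    d95: float
    dmax: float
    dmin: float
    dmean: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def dose_percentile(dose_sorted_desc: np.ndarray, x: float) -> float:
    k = int(np.ceil(x / 100.0 * dose_sorted_desc.size))
    k = min(max(k, 1), dose_sorted_desc.size)
    return float(dose_sorted_desc[k - 1])


def dose_metrics(dose: np.ndarray, mask: np.ndarray) -> DoseMetrics:
    vals = np.asarray(dose, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty structure mask: cannot compute dose metrics")
    desc = np.sort(vals)[::-1]
    return DoseMetrics(
        d98=dose_percentile(desc, 98.0),
        d95=dose_percentile(desc, 95.0),
        dmax=float(desc[0]),
        dmin=float(desc[-1]),
        dmean=float(vals.mean()),
    )


def relative_error(estimated: float, ground_truth: float, prescription: float) -> float:
    """(Estimate - ground truth) / prescription x 100, signed %."""
    if prescription <= 0:
        raise ValueError("prescription dose must be positive")
    return (estimated - ground_truth) / prescription * 100.0


def evaluate_case(
    gt_dose: np.ndarray,
    est_dose: np.ndarray,
    grid: VolumeGrid,
    masks: dict[str, np.ndarray],
    prescription: float,
    criteria_list: list[GammaCriteria] | None = None,
    gamma_mode: str = "2d",
) -> dict:
    """Full dosimetric report for one case.

    γ analysis runs on the central axial slice by default (``gamma_mode=
    "3d"`` evaluates the whole volume). Structure metrics cover the PTV and
    every supplied OAR, absolute (Gy) and relative to prescription (%); in
    "2d" mode they are restricted to the central axial slice — the plane the
    dose model supervises and the only plane where its estimate is defined.
    The returned dict contains only plain Python scalars/lists and
    serializes as-is to JSON or YAML.
    """
    criteria_list = criteria_list or [
        GammaCriteria(3.0, 2.0, 10.0),
        GammaCriteria(2.0, 2.0, 10.0),
    ]
    grid.validate_volume(gt_dose)
    if gt_dose.shape != est_dose.shape:
        raise ValueError("ground-truth and estimated dose grids differ")
    if "ptv" not in masks:
        raise ValueError("masks must include 'ptv'")
    oars = [k for k in masks if k.startswith("oar_")]
    if not oars:
        raise ValueError("masks must include at least one OAR")
    if gamma_mode not in ("2d", "3d"):
        raise ValueError("gamma_mode must be '2d' or '3d'")

    zc = grid.dims[2] // 2
    report: dict = {"prescription_gy": float(prescription), "gamma": {}}
    for crit in criteria_list:
        if gamma_mode == "2d":
            _, rate = gamma_index(
                gt_dose[zc], est_dose[zc],
                (grid.spacing[1], grid.spacing[0]), crit,
            )
        else:
            _, rate = gamma_index(
                gt_dose, est_dose,
                (grid.spacing[2], grid.spacing[1], grid.spacing[0]), crit,
            )
        report["gamma"][crit.label] = float(rate)

    report["structures"] = {}
    for name in ["ptv", *sorted(oars)]:
        if gamma_mode == "2d":
            m = masks[name][zc]
            gt_s, est_s = gt_dose[zc], est_dose[zc]
        else:
            m = masks[name]
            gt_s, est_s = gt_dose, est_dose
        if not m.any():
            raise ValueError(f"empty structure mask: '{name}'")
        gt_m = dose_metrics(gt_s, m).as_dict()
        est_m = dose_metrics(est_s, m).as_dict()
        report["structures"][name] = {
            "ground_truth_gy": gt_m,
            "estimated_gy": est_m,
            "abs_error_gy": {k: est_m[k] - gt_m[k] for k in gt_m},
            "rel_error_pct": {
                k: relative_error(est_m[k], gt_m[k], prescription) for k in gt_m
            },
        }

    if gamma_mode == "2d":
        diff_pct = (est_dose[zc] - gt_dose[zc]) / prescription * 100.0
    else:
        diff_pct = (est_dose - gt_dose) / prescription * 100.0
    report["dose_difference_pct_rx"] = {
        "mean": float(diff_pct.mean()),
        "std": float(diff_pct.std()),
        "max_abs": float(np.abs(diff_pct).max()),
    }
    return report
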