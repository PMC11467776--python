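"""Synthetic case archives: generation, persistence and loading.

One directory per case holding a self-describing ``arrays.npz`` (named
arrays plus grid metadata) and a YAML manifest at the archive root recording
per-case seeds and the train/validation/test split. Splits are assigned by
hashing case identifiers so membership is stable when the archive grows.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .beam import BeamGeometry
from .encoding import encode_integrated_volume
from .fluence import FluenceGrid, FluenceMap, control_points_to_fluence_maps
from .grid import VolumeGrid
from .synthetic import (
    DEFAULT_PRESCRIPTION_GY,
    OracleConfig,
    PhantomSpec,
    generate_phantom,
    generate_plan,
    oracle_dose_from_fms,
)

SPLIT_NAMES = ("train", "val", "test")


def split_cases(
    case_ids: list[str], fractions: tuple[float, ...], names: tuple[str, ...] = SPLIT_NAMES
) -> dict[str, str]:
    """Assign cases to splits by identifier hash (stable under growth).

    Cases are ordered by the SHA-1 of their identifier; split ``i`` receives
    ``floor(fraction_i * n)`` cases and the final split takes the remainder
    (80/20 over 381 cases gives 304/77).
    """
    if len(fractions) != len(names):
        raise ValueError("one fraction per split name required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    ranked = sorted(case_ids, key=lambda c: hashlib.sha1(c.encode()).hexdigest())
    n = len(ranked)
    out: dict[str, str] = {}
    start = 0
    for i, (frac, name) in enumerate(zip(fractions, names)):
        count = n - start if i == len(fractions) - 1 else int(np.floor(frac * n))
        for cid in ranked[start : start + count]:
            out[cid] = name
        start += count
    return out


@dataclass
class CaseRecord:
    """All arrays of one synthetic case, on a shared grid."""

    case_id: str
    grid: VolumeGrid
    red: np.ndarray
    dose: np.ndarray  # Gy
    integrated: np.ndarray
    painted_mask: np.ndarray
    masks: dict[str, np.ndarray]
    fm_stack: np.ndarray  # (n_angles, n_v, n_u)
    fm_angles: np.ndarray
    fluence_scale: float
    prescription_gy: float
    meta: dict


def _case_jitter(template: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Per-case anatomical variation around the template phantom."""
    organs = []
    for name, shape, center, size, red_range in template.organ_shapes:
        c = (
            center[0] + rng.normal(0, 5.0),
            center[1] + rng.normal(0, 5.0),
            center[2] + rng.normal(0, 3.0),
        )
        s = rng.uniform(0.85, 1.15)
        new_size = size * s if np.isscalar(size) else tuple(v * s for v in size)
        organs.append((name, shape, c, new_size, red_range))
    return replace(
        template,
        body_semi_axes=(
            template.body_semi_axes[0] * rng.uniform(0.9, 1.1),
            template.body_semi_axes[1] * rng.uniform(0.9, 1.1),
        ),
        target_radius=template.target_radius * rng.uniform(0.8, 1.2),
        organ_shapes=organs,
    )


def build_case(
    case_id: str,
    spec: PhantomSpec,
    geometry: BeamGeometry,
    cfg: OracleConfig,
    fm_grid: FluenceGrid,
    plan_seed: int,
    n_arcs: int = 1,
    prescription_gy: float = DEFAULT_PRESCRIPTION_GY,
    fluence_scale: float | None = None,
) -> CaseRecord:
    """Generate one complete case: phantom, plan, fluence, encoding, dose.

    Plan MU is normalised so the mean oracle dose in the PTV equals the
    prescription (the oracle is linear, so dose and fluence scale together).
    ``fluence_scale`` fixes the painted-intensity scale; None auto-scales
    per case. Training archives use a fixed scale so the fluence-to-dose
    gain is identical across cases.
    """
    red, masks = generate_phantom(spec)
    plan = generate_plan(
        masks, geometry, n_arcs=n_arcs, seed=plan_seed, grid=spec.grid, fm_grid=fm_grid
    )
    fms = control_points_to_fluence_maps(plan, geometry, fm_grid)
    dose_raw = oracle_dose_from_fms(red, spec.grid, fms, geometry, cfg)
    ptv_mean = float(dose_raw[masks["ptv"]].mean())
    if ptv_mean <= 0:
        raise RuntimeError(f"case {case_id}: zero PTV dose from oracle")
    mu_scale = prescription_gy / ptv_mean
    plan = plan.scale_mu(mu_scale)
    fms = [
        FluenceMap(f.gantry_angle, f.intensity * mu_scale, f.grid) for f in fms
    ]
    dose = dose_raw * mu_scale
    body_couch = masks["body"] | masks["couch"]
    iv = encode_integrated_volume(
        red, spec.grid, fms, geometry, fluence_scale=fluence_scale,
        body_mask=body_couch, overlap="error",
    )
    return CaseRecord(
        case_id=case_id,
        grid=spec.grid,
        red=red,
        dose=dose,
        integrated=iv.values,
        painted_mask=iv.painted_mask,
        masks=masks,
        fm_stack=np.stack([f.intensity for f in fms]),
        fm_angles=np.array([f.gantry_angle for f in fms]),
        fluence_scale=iv.fluence_scale,
        prescription_gy=prescription_gy,
        meta={"mu_scale": mu_scale, "total_mu": plan.total_mu,
              "plan_seed": plan_seed, "phantom_seed": spec.seed},
    )


def save_case(case: CaseRecord, case_dir: Path) -> None:
    case_dir.mkdir(parents=True, exist_ok=True)
    arrays = {
        "red": case.red,
        "dose": case.dose,
        "integrated": case.integrated,
        "painted_mask": case.painted_mask.astype(np.uint8),
        "fm_stack": case.fm_stack,
        "fm_angles": case.fm_angles,
        "grid_origin": np.asarray(case.grid.origin),
        "grid_spacing": np.asarray(case.grid.spacing),
        "grid_dims": np.asarray(case.grid.dims),
        "fluence_scale": np.asarray(case.fluence_scale),
        "prescription_gy": np.asarray(case.prescription_gy),
    }
    for name, m in case.masks.items():
        arrays[f"mask_{name}"] = m.astype(np.uint8)
    np.savez_compressed(case_dir / "arrays.npz", **arrays)


def load_case(case_dir: Path) -> CaseRecord:
    with np.load(case_dir / "arrays.npz") as z:
        grid = VolumeGrid(
            origin=tuple(z["grid_origin"]),
            spacing=tuple(z["grid_spacing"]),
            dims=tuple(int(v) for v in z["grid_dims"]),
        )
        masks = {
            k[5:]: z[k].astype(bool) for k in z.files if k.startswith("mask_")
        }
        return CaseRecord(
            case_id=Path(case_dir).name,
            grid=grid,
            red=z["red"],
            dose=z["dose"],
            integrated=z["integrated"],
            painted_mask=z["painted_mask"].astype(bool),
            masks=masks,
            fm_stack=z["fm_stack"],
            fm_angles=z["fm_angles"],
            fluence_scale=float(z["fluence_scale"]),
            prescription_gy=float(z["prescription_gy"]),
            meta={},
        )


def make_dataset(
    n_cases: int,
    spec_template: PhantomSpec,
    geometry: BeamGeometry,
    cfg: OracleConfig,
    seed: int,
    out_path: str | Path,
    *,
    fm_grid: FluenceGrid | None = None,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    n_arcs: int = 1,
    prescription_gy: float = DEFAULT_PRESCRIPTION_GY,
    fluence_scale: float | None = None,
    jitter: bool = True,
    overwrite: bool = False,
) -> Path:
    """Generate and persist a case archive; returns the manifest path.

    Deterministic given ``seed``: per-case seeds are spawned from
    ``SeedSequence([seed, case_index])`` and recorded in the manifest.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out_path = Path(out_path)
    manifest_path = out_path / "manifest.yaml"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{out_path} already holds an archive; "
                              "pass overwrite=True to replace it")
    fm_grid = fm_grid or FluenceGrid(pixel_spacing=cfg.beamlet_spacing)
    case_ids = [f"case_{i:04d}" for i in range(n_cases)]
    assignment = split_cases(case_ids, split_fractions)
    entries = []
    for i, cid in enumerate(case_ids):
        ss = np.random.SeedSequence([int(seed), i])
        phantom_seed, plan_seed, jitter_seed = (
            int(s) for s in ss.generate_state(3) % (2**31)
        )
        spec = replace(spec_template, seed=phantom_seed)
        if jitter:
            spec = _case_jitter(spec, np.random.default_rng(jitter_seed))
        case = build_case(
            cid, spec, geometry, cfg, fm_grid, plan_seed,
            n_arcs=n_arcs, prescription_gy=prescription_gy,
            fluence_scale=fluence_scale,
        )
        save_case(case, out_path / cid)
        entries.append(
            {
                "id": cid,
                "split": assignment[cid],
                "phantom_seed": phantom_seed,
                "plan_seed": plan_seed,
                "jitter_seed": jitter_seed,
                "mu_scale": round(float(case.meta["mu_scale"]), 9),
            }
        )
    manifest = {
        "seed": int(seed),
        "n_cases": int(n_cases),
        "split_fractions": [float(f) for f in split_fractions],
        "prescription_gy": float(prescription_gy),
        "geometry": {
            "sad": geometry.sad,
            "plane_distance": geometry.plane_distance,
            "angular_spacing": geometry.angular_spacing,
        },
        "oracle": {
            "mu_eff": cfg.mu_eff,
            "lateral_sigma": cfg.lateral_sigma,
            "beamlet_spacing": cfg.beamlet_spacing,
        },
        "cases": entries,
    }
    out_path.mkdir(parents=True, exist_ok=True)
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def load_dataset(
    path: str | Path, splits: tuple[str, ...] | None = None
) -> list[CaseRecord]:
    """Load cases listed in the archive manifest, optionally by split."""
    path = Path(path)
    manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    records = []
    for entry in manifest["cases"]:
        if splits is not None and entry["split"] not in splits:
            continue
        rec = load_case(path / entry["id"])
        rec.meta.update(entry)
        records.append(rec)
    return records
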