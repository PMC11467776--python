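"""DICOM CT / RTPLAN / RTDOSE I/O and the HU-to-RED calibration curve.

Readers apply rescale and dose-grid scaling and validate series coherence;
writers emit standard-conformant files that round-trip through the readers
(and through any DICOM toolkit) within format quantization. Axial CT series
are assumed; all coordinates are DICOM patient coordinates in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (
    CTImageStorage,
    ExplicitVRLittleEndian,
    RTDoseStorage,
    RTPlanStorage,
    generate_uid,
)

from .grid import VolumeGrid
from .plan import Arc, ControlPoint, PlanModel

_SLICE_TOL = 0.01  # mm tolerance on slice-spacing uniformity


# ---------------------------------------------------------------------------
# HU -> RED calibration


@dataclass(frozen=True)
class HuRedCurve:
    """Piecewise-linear HU -> relative-electron-density calibration.

    Breakpoints must have strictly increasing HU and non-decreasing,
    non-negative RED. Outside the curve range values clamp to the end RED.
    The default anchors (air, water, trabecular bone, cortical-bone-like)
    are placeholders for a site-measured curve.
    """

    breakpoints: tuple[tuple[float, float], ...] = (
        (-1000.0, 0.0),
        (0.0, 1.0),
        (1000.0, 1.5),
        (3000.0, 2.2),
    )

    def __post_init__(self) -> None:
        if len(self.breakpoints) < 2:
            raise ValueError("calibration curve needs at least 2 breakpoints")
        hu = np.array([p[0] for p in self.breakpoints])
        red = np.array([p[1] for p in self.breakpoints])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if np.any(red < 0) or np.any(np.diff(red) < 0):
            raise ValueError("RED values must be non-negative and non-decreasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HuRedCurve":
        data = yaml.safe_load(Path(path).read_text())
        return cls(tuple((float(h), float(r)) for h, r in data["breakpoints"]))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"breakpoints": [list(p) for p in self.breakpoints]})
        )


def hu_to_red(hu: np.ndarray, curve: HuRedCurve | None = None) -> np.ndarray:
    """Convert Hounsfield units to relative electron density."""
    curve = curve or HuRedCurve()
    xs = np.array([p[0] for p in curve.breakpoints])
    ys = np.array([p[1] for p in curve.breakpoints])
    return np.interp(np.asarray(hu, dtype=float), xs, ys)


# ---------------------------------------------------------------------------
# CT series


def read_ct_series(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read one axial CT series from a directory of DICOM files.

    Slices are sorted by z position regardless of file order; rescale
    slope/intercept is applied so values are HU. Mixed series or slice gaps
    beyond tolerance raise with the offending slice named.
    """
    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = []
    for f in files:
        ds = pydicom.dcmread(f)
        if getattr(ds, "SOPClassUID", None) == CTImageStorage or ds.Modality == "CT":
            slices.append((f, ds))
    if not slices:
        raise ValueError(f"no CT slices found under {path}")
    series_uids = {ds.SeriesInstanceUID for _, ds in slices}
    if len(series_uids) > 1:
        raise ValueError(f"mixed CT series in {path}: {sorted(series_uids)}")
    slices.sort(key=lambda fs: float(fs[1].ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for _, ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise ValueError("duplicate or non-monotonic slice positions")
        if np.any(np.abs(dz - dz[0]) > _SLICE_TOL):
            k = int(np.argmax(np.abs(dz - dz[0])))
            raise ValueError(
                f"non-uniform slice spacing at slice {slices[k + 1][0].name}: "
                f"step {dz[k]:.3f} mm vs {dz[0]:.3f} mm"
            )
        spacing_z = float(dz[0])
    else:
        spacing_z = float(getattr(slices[0][1], "SliceThickness", 1.0))
    ds0 = slices[0][1]
    row_sp, col_sp = (float(v) for v in ds0.PixelSpacing)
    origin = tuple(float(v) for v in ds0.ImagePositionPatient)
    hu = np.stack(
        [
            ds.pixel_array.astype(float) * float(getattr(ds, "RescaleSlope", 1.0))
            + float(getattr(ds, "RescaleIntercept", 0.0))
            for _, ds in slices
        ]
    )
    grid = VolumeGrid(
        origin=origin,
        spacing=(col_sp, row_sp, spacing_z),
        dims=(hu.shape[2], hu.shape[1], hu.shape[0]),
    )
    return hu, grid


def _file_meta(sop_class, sop_uid) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _common_tags(ds: Dataset, modality: str) -> None:
    ds.PatientName = "geodose^synthetic"
    ds.PatientID = "GEODOSE"
    ds.StudyInstanceUID = getattr(ds, "StudyInstanceUID", generate_uid())
    ds.Modality = modality


def write_ct_series(
    hu: np.ndarray, grid: VolumeGrid, path: str | Path
) -> list[Path]:
    """Write an axial CT series (int16 HU, identity orientation)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    out = []
    nz = grid.dims[2]
    for k in range(nz):
        sop_uid = generate_uid()
        ds = Dataset()
        ds.file_meta = _file_meta(CTImageStorage, sop_uid)
        _common_tags(ds, "CT")
        ds.StudyInstanceUID = study_uid
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            grid.origin[0],
            grid.origin[1],
            grid.origin[2] + k * grid.spacing[2],
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]  # row, col
        ds.SliceThickness = grid.spacing[2]
        ds.Rows, ds.Columns = grid.dims[1], grid.dims[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.rint(hu[k]).astype(np.int16).tobytes()
        fname = path / f"ct_{k:04d}.dcm"
        ds.save_as(fname, enforce_file_format=True)
        out.append(fname)
    return out


# ---------------------------------------------------------------------------
# RTDOSE


def read_rtdose(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a grid-aligned RTDOSE; returns dose in Gy."""
    ds = pydicom.dcmread(path)
    summation = getattr(ds, "DoseSummationType", "PLAN")
    if summation not in ("PLAN", "FRACTION"):
        raise ValueError(f"unsupported dose summation type '{summation}'")
    if getattr(ds, "DoseUnits", "GY") != "GY":
        raise ValueError(f"unsupported dose units '{ds.DoseUnits}'")
    scaling = float(ds.DoseGridScaling)
    dose = ds.pixel_array.astype(float) * scaling
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    if offsets.size > 1:
        dz = np.diff(offsets)
        if np.any(np.abs(dz - dz[0]) > _SLICE_TOL):
            raise ValueError("non-uniform dose frame offsets")
        spacing_z = float(dz[0])
    else:
        spacing_z = 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    grid = VolumeGrid(
        origin=tuple(float(v) for v in ds.ImagePositionPatient),
        spacing=(col_sp, row_sp, spacing_z),
        dims=(dose.shape[2], dose.shape[1], dose.shape[0]),
    )
    return dose, grid


def write_rtdose(dose: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    """Write a PLAN-summation RTDOSE (uint32 with dose-grid scaling)."""
    grid.validate_volume(dose)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(RTDoseStorage, sop_uid)
    _common_tags(ds, "RTDOSE")
    ds.SOPClassUID = RTDoseStorage
    ds.SOPInstanceUID = sop_uid
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    peak = float(dose.max())
    scaling = peak / (2**32 - 2) if peak > 0 else 1e-8
    ds.DoseGridScaling = scaling
    ds.ImagePositionPatient = list(grid.origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
    ds.GridFrameOffsetVector = [k * grid.spacing[2] for k in range(grid.dims[2])]
    ds.NumberOfFrames = grid.dims[2]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.Rows, ds.Columns = grid.dims[1], grid.dims[0]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.rint(dose / scaling).astype(np.uint32).tobytes()
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# RTPLAN


def read_rtplan(path: str | Path) -> PlanModel:
    """Read a dynamic-arc RTPLAN into the internal plan model.

    Gantry angles are normalized to [0, 360); a static-gantry beam is
    accepted as a one-angle arc. Beams without an MLC sequence, or with
    decreasing cumulative meterset weight, are rejected.
    """
    ds = pydicom.dcmread(path)
    if not getattr(ds, "BeamSequence", None):
        raise ValueError("RTPLAN has no beams")
    beam_mu = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            beam_mu[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    arcs = []
    isocenter = (0.0, 0.0, 0.0)
    for beam in ds.BeamSequence:
        boundaries = None
        jaws_x = jaws_y = None
        for dev in getattr(beam, "BeamLimitingDeviceSequence", []):
            if dev.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                boundaries = np.array(
                    [float(v) for v in dev.LeafPositionBoundaries]
                )
        if boundaries is None:
            raise ValueError(
                f"beam {beam.BeamNumber}: no MLC leaf-position boundaries"
            )
        cps = []
        final_weight = float(beam.FinalCumulativeMetersetWeight)
        gantry = None
        for cp in beam.ControlPointSequence:
            if hasattr(cp, "GantryAngle"):
                gantry = float(cp.GantryAngle) % 360.0
            mlc = None
            for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                t = dev.RTBeamLimitingDeviceType
                pos = [float(v) for v in dev.LeafJawPositions]
                if t in ("MLCX", "MLCY"):
                    mlc = np.array(pos)
                elif t in ("ASYMX", "X"):
                    jaws_x = (pos[0], pos[1])
                elif t in ("ASYMY", "Y"):
                    jaws_y = (pos[0], pos[1])
            if hasattr(cp, "IsocenterPosition"):
                isocenter = tuple(float(v) for v in cp.IsocenterPosition)
            if mlc is None:
                if not cps:
                    raise ValueError(
                        f"beam {beam.BeamNumber}: control point without MLC positions"
                    )
                mlc_a, mlc_b = cps[-1].mlc_a, cps[-1].mlc_b
            else:
                n = mlc.size // 2
                mlc_a, mlc_b = mlc[:n], mlc[n:]
            w = float(cp.CumulativeMetersetWeight) / final_weight
            if cps and w < cps[-1].cumulative_weight - 1e-9:
                raise ValueError(
                    f"beam {beam.BeamNumber}: decreasing cumulative meterset weight"
                )
            cps.append(ControlPoint(gantry, mlc_a.copy(), mlc_b.copy(), w))
        if jaws_x is None:
            jaws_x = (float(boundaries[0]), float(boundaries[-1]))
        if jaws_y is None:
            jaws_y = (float(boundaries[0]), float(boundaries[-1]))
        arcs.append(
            Arc(
                control_points=cps,
                leaf_boundaries=boundaries,
                jaws_x=jaws_x,
                jaws_y=jaws_y,
                beam_mu=beam_mu.get(int(beam.BeamNumber), 1.0),
            )
        )
    return PlanModel(arcs=arcs, isocenter=isocenter,
                     label=str(getattr(ds, "RTPlanLabel", "plan")))


def write_rtplan(plan: PlanModel, path: str | Path) -> Path:
    """Write the plan model as a VMAT RTPLAN readable by :func:`read_rtplan`."""
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(RTPlanStorage, sop_uid)
    _common_tags(ds, "RTPLAN")
    ds.SOPClassUID = RTPlanStorage
    ds.SOPInstanceUID = sop_uid
    ds.SeriesInstanceUID = generate_uid()
    ds.RTPlanLabel = plan.label
    ds.RTPlanGeometry = "PATIENT"

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.ReferencedBeamSequence = []
    ds.BeamSequence = []
    for bi, arc in enumerate(plan.arcs, start=1):
        beam = Dataset()
        beam.BeamNumber = bi
        beam.BeamName = f"arc{bi}"
        beam.BeamType = "DYNAMIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.SourceAxisDistance = 1000.0
        mlc_dev = Dataset()
        mlc_dev.RTBeamLimitingDeviceType = "MLCX"
        mlc_dev.NumberOfLeafJawPairs = len(arc.leaf_boundaries) - 1
        mlc_dev.LeafPositionBoundaries = [float(v) for v in arc.leaf_boundaries]
        beam.BeamLimitingDeviceSequence = [mlc_dev]
        beam.FinalCumulativeMetersetWeight = 1.0
        beam.NumberOfControlPoints = len(arc.control_points)
        beam.ControlPointSequence = []
        for ci, cp in enumerate(arc.control_points):
            c = Dataset()
            c.ControlPointIndex = ci
            c.GantryAngle = cp.gantry_angle
            c.GantryRotationDirection = "CW"
            c.CumulativeMetersetWeight = cp.cumulative_weight
            jaw_x = Dataset()
            jaw_x.RTBeamLimitingDeviceType = "ASYMX"
            jaw_x.LeafJawPositions = [arc.jaws_x[0], arc.jaws_x[1]]
            jaw_y = Dataset()
            jaw_y.RTBeamLimitingDeviceType = "ASYMY"
            jaw_y.LeafJawPositions = [arc.jaws_y[0], arc.jaws_y[1]]
            mlc = Dataset()
            mlc.RTBeamLimitingDeviceType = "MLCX"
            mlc.LeafJawPositions = [float(v) for v in cp.mlc_a] + [
                float(v) for v in cp.mlc_b
            ]
            c.BeamLimitingDevicePositionSequence = [jaw_x, jaw_y, mlc]
            if ci == 0:
                c.IsocenterPosition = list(plan.isocenter)
                c.NominalBeamEnergy = 6.0
            beam.ControlPointSequence.append(c)
        ds.BeamSequence.append(beam)
        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = arc.beam_mu
        fg.ReferencedBeamSequence.append(rb)
    ds.FractionGroupSequence = [fg]
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path
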