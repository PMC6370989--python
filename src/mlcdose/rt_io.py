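"""DICOM-RT reading and writing (CT, RT Plan, RT Structure Set, RT Dose).

Only the attributes this system consumes are handled; axial,
identity-orientation CT geometry is assumed.  Grid arrays are indexed
[iz, iy, ix]; ``origin`` is the center of voxel (0, 0, 0) in patient
millimetres and ``spacing`` is (dx, dy, dz).

Leaf positions follow the DICOM MLCX convention: 120 values at the
isocenter plane, bank A (negative X side) first, bank A <= bank B for
every pair.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian
from skimage.draw import polygon2mask

N_LEAVES = 120
N_PAIRS = 60

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_PLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"
_STRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_DOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_FIXED_DATE = "20190123"


class RTIOError(ValueError):
    """Base class for DICOM-RT interface errors."""


class MissingMLCError(RTIOError):
    """RT Plan control point lacks an MLCX position sequence."""


class UnsupportedDeviceError(RTIOError):
    """MLC device is not a 120-leaf (60-pair) bank."""


class GeometryError(RTIOError):
    """Inconsistent or unsupported image geometry."""


class ContourError(RTIOError):
    """Structure contour does not map onto the CT volume."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ControlPoint:
    index: int
    gantry_angle: float
    collimator_angle: float
    jaw_positions: tuple[float, float, float, float]  # x1,x2,y1,y2 mm at iso
    leaf_positions: np.ndarray  # 120 mm values, bank A then bank B
    cumulative_meterset_weight: float

    def validate(self):
        leaf = np.asarray(self.leaf_positions, dtype=float)
        if leaf.shape != (N_LEAVES,):
            raise RTIOError(f"control point {self.index}: expected {N_LEAVES} "
                            f"leaf positions, got {leaf.shape}")
        a, b = leaf[:N_PAIRS], leaf[N_PAIRS:]
        if np.any(b - a < -1e-6):
            raise RTIOError(f"control point {self.index}: opposing leaves interdigitate")
        if not 0.0 <= self.cumulative_meterset_weight <= 1.0 + 1e-9:
            raise RTIOError(f"control point {self.index}: cumulative meterset "
                            f"weight outside [0, 1]")
        x1, x2, y1, y2 = self.jaw_positions
        if x1 > x2 or y1 > y2:
            raise RTIOError(f"control point {self.index}: jaw intervals not ordered")


@dataclass
class Beam:
    name: str
    number: int
    meterset_mu: float
    isocenter: tuple[float, float, float]
    control_points: list[ControlPoint] = field(default_factory=list)

    def validate(self):
        if len(self.control_points) < 2:
            raise RTIOError(f"beam {self.name!r}: needs >= 2 control points")
        w = [cp.cumulative_meterset_weight for cp in self.control_points]
        if np.any(np.diff(w) < -1e-9):
            raise RTIOError(f"beam {self.name!r}: cumulative meterset weights decrease")
        for cp in self.control_points:
            cp.validate()


@dataclass
class TreatmentPlan:
    plan_label: str
    total_mu: float
    technique: str  # IMRT | VMAT | STATIC
    beams: list[Beam]
    prescribed_dose: float | None = None

    def validate(self):
        if not self.total_mu > 0:
            raise RTIOError("plan total MU must be positive")
        if self.technique not in ("IMRT", "VMAT", "STATIC"):
            raise RTIOError(f"unknown technique {self.technique!r}")
        for b in self.beams:
            b.validate()

    def n_control_points(self) -> int:
        return sum(len(b.control_points) for b in self.beams)


@dataclass
class ROI:
    name: str
    number: int
    contours: list[tuple[float, np.ndarray]]  # (z mm, Nx2 xy mm)
    override_density: float | None = None
    override_composition: dict[str, float] | None = None


@dataclass
class StructureSet:
    rois: list[ROI] = field(default_factory=list)

    def get(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass
class CTVolume:
    hu: np.ndarray  # [iz, iy, ix] int16
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("voxel spacing must be positive on all axes")

    @property
    def shape(self):
        return self.hu.shape

    def slice_positions(self):
        nz = self.hu.shape[0]
        return self.origin[2] + np.arange(nz) * self.spacing[2]


@dataclass
class DoseGrid:
    dose: np.ndarray  # [iz, iy, ix], Gy
    uncertainty: np.ndarray | None  # relative 1 sigma, same shape
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        if np.any(np.asarray(self.dose) < 0):
            raise RTIOError("dose grid contains negative values")
        if self.uncertainty is not None:
            if self.uncertainty.shape != self.dose.shape:
                raise RTIOError("uncertainty grid shape mismatch")
            if np.any(self.uncertainty < 0):
                raise RTIOError("uncertainty grid contains negative values")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("dose grid spacing must be positive")

    @property
    def shape(self):
        return self.dose.shape


# --------------------------------------------------------------------------
# deterministic UIDs and file meta
# --------------------------------------------------------------------------

def deterministic_uid(seed: int, tag: str) -> str:
    h = hashlib.sha256(f"mlcdose:{seed}:{tag}".encode()).hexdigest()
    return "2.25." + str(int(h[:30], 16))


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(sop_class, sop_instance, modality, seed) -> FileDataset:
    ds = FileDataset(None, {}, file_meta=_file_meta(sop_class, sop_instance),
                     preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    ds.Modality = modality
    ds.PatientName = "Water^Phantom"
    ds.PatientID = "MLCDOSE"
    ds.StudyDate = _FIXED_DATE
    ds.ContentDate = _FIXED_DATE
    ds.StudyTime = "000000"
    ds.ContentTime = "000000"
    ds.StudyInstanceUID = deterministic_uid(seed, "study")
    ds.SeriesInstanceUID = deterministic_uid(seed, f"series-{modality}")
    ds.FrameOfReferenceUID = deterministic_uid(seed, "frame")
    return ds


def _ds_float(value, ndigits=10):
    """Format a float so the DS string round-trips exactly."""
    return float(f"{float(value):.{ndigits}g}")


# --------------------------------------------------------------------------
# RT Plan
# --------------------------------------------------------------------------

def read_plan(path: str | Path) -> TreatmentPlan:
    """Read an RT Plan into a :class:`TreatmentPlan`.

    The delivery technique is inferred per beam from gantry motion
    (>0.5 degree change between adjacent control points -> VMAT),
    falling back to IMRT for moving leaves and STATIC otherwise.
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise RTIOError(f"{path}: not an RT Plan object")

    metersets = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    prescribed = None
    for dr in getattr(ds, "DoseReferenceSequence", []):
        if hasattr(dr, "TargetPrescriptionDose"):
            prescribed = float(dr.TargetPrescriptionDose)

    beams = []
    for b in getattr(ds, "BeamSequence", []):
        n_pairs = None
        for bld in getattr(b, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType.startswith("MLC"):
                n_pairs = int(bld.NumberOfLeafJawPairs)
        if n_pairs is None:
            raise MissingMLCError(
                "RT Plan beam has no MLC entry in BeamLimitingDeviceSequence "
                "(300A,00B6); missing RTBeamLimitingDeviceType MLCX")
        if n_pairs != N_PAIRS:
            raise UnsupportedDeviceError(
                f"only 120-leaf (60-pair) MLCs are supported, got {n_pairs} pairs")

        final_w = float(getattr(b, "FinalCumulativeMetersetWeight", 1.0)) or 1.0
        cps = []
        gantry = coll = None
        jaws = None
        leaves = None
        isocenter = (0.0, 0.0, 0.0)
        for i, cp in enumerate(b.ControlPointSequence):
            if hasattr(cp, "GantryAngle"):
                gantry = float(cp.GantryAngle)
            if hasattr(cp, "BeamLimitingDeviceAngle"):
                coll = float(cp.BeamLimitingDeviceAngle)
            if hasattr(cp, "IsocenterPosition"):
                isocenter = tuple(float(v) for v in cp.IsocenterPosition)
            got_mlc = False
            for bldp in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                kind = bldp.RTBeamLimitingDeviceType
                pos = [float(v) for v in bldp.LeafJawPositions]
                if kind in ("X", "ASYMX"):
                    jaws = (pos[0], pos[1], jaws[2] if jaws else 0.0,
                            jaws[3] if jaws else 0.0)
                elif kind in ("Y", "ASYMY"):
                    jaws = (jaws[0] if jaws else 0.0, jaws[1] if jaws else 0.0,
                            pos[0], pos[1])
                elif kind.startswith("MLC"):
                    leaves = np.asarray(pos, dtype=float)
                    got_mlc = True
            if leaves is None:
                raise MissingMLCError(
                    f"control point {i}: no MLCX positions "
                    "(BeamLimitingDevicePositionSequence (300A,011A))")
            if gantry is None or coll is None or jaws is None:
                raise RTIOError(f"control point {i}: incomplete machine state")
            del got_mlc
            cps.append(ControlPoint(
                index=i, gantry_angle=gantry, collimator_angle=coll,
                jaw_positions=jaws, leaf_positions=leaves.copy(),
                cumulative_meterset_weight=float(cp.CumulativeMetersetWeight) / final_w,
            ))
        beams.append(Beam(
            name=str(getattr(b, "BeamName", f"beam{b.BeamNumber}")),
            number=int(b.BeamNumber),
            meterset_mu=metersets.get(int(b.BeamNumber), 0.0),
            isocenter=isocenter,
            control_points=cps,
        ))

    technique = _infer_technique(beams)
    plan = TreatmentPlan(
        plan_label=str(getattr(ds, "RTPlanLabel", "plan")),
        total_mu=sum(b.meterset_mu for b in beams),
        technique=technique,
        beams=beams,
        prescribed_dose=prescribed,
    )
    plan.validate()
    return plan


def _infer_technique(beams: list[Beam]) -> str:
    moving_gantry = moving_leaves = False
    for b in beams:
        g = np.array([cp.gantry_angle for cp in b.control_points])
        dg = np.abs(np.diff(g))
        dg = np.minimum(dg, 360.0 - dg)  # wrap-around
        if np.any(dg > 0.5):
            moving_gantry = True
        leaf = np.array([cp.leaf_positions for cp in b.control_points])
        if np.any(np.ptp(leaf, axis=0) > 1e-6):
            moving_leaves = True
    if moving_gantry:
        return "VMAT"
    if moving_leaves:
        return "IMRT"
    return "STATIC"


def write_plan(plan: TreatmentPlan, path: str | Path, seed: int = 0) -> None:
    """Write a :class:`TreatmentPlan` as an RT Plan file."""
    plan.validate()
    sop = deterministic_uid(seed, "rtplan")
    ds = _base_dataset(_PLAN_SOP, sop, "RTPLAN", seed)
    ds.RTPlanLabel = plan.plan_label
    ds.RTPlanDate = _FIXED_DATE
    ds.RTPlanGeometry = "PATIENT"

    if plan.prescribed_dose is not None:
        dr = Dataset()
        dr.DoseReferenceNumber = 1
        dr.DoseReferenceStructureType = "SITE"
        dr.DoseReferenceType = "TARGET"
        dr.TargetPrescriptionDose = _ds_float(plan.prescribed_dose)
        ds.DoseReferenceSequence = [dr]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.ReferencedBeamSequence = []
    for b in plan.beams:
        rb = Dataset()
        rb.ReferencedBeamNumber = b.number
        rb.BeamMeterset = _ds_float(b.meterset_mu)
        fg.ReferencedBeamSequence.append(rb)
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    # bundled default boundaries: 10x10 + 40x5 + 10x10 mm
    bounds = np.concatenate([[-200.0], -200.0 + np.cumsum(
        [10.0] * 10 + [5.0] * 40 + [10.0] * 10)])
    for b in plan.beams:
        bd = Dataset()
        bd.BeamNumber = b.number
        bd.BeamName = b.name
        bd.BeamType = "DYNAMIC" if plan.technique != "STATIC" else "STATIC"
        bd.RadiationType = "PHOTON"
        bd.TreatmentDeliveryType = "TREATMENT"
        bd.FinalCumulativeMetersetWeight = 1.0
        bd.NumberOfControlPoints = len(b.control_points)
        bd.BeamLimitingDeviceSequence = []
        for kind, n in (("ASYMX", 1), ("ASYMY", 1), ("MLCX", N_PAIRS)):
            e = Dataset()
            e.RTBeamLimitingDeviceType = kind
            e.NumberOfLeafJawPairs = n
            if kind == "MLCX":
                e.LeafPositionBoundaries = [_ds_float(v) for v in bounds]
            bd.BeamLimitingDeviceSequence.append(e)
        bd.ControlPointSequence = []
        for cp in b.control_points:
            c = Dataset()
            c.ControlPointIndex = cp.index
            c.GantryAngle = _ds_float(cp.gantry_angle)
            c.GantryRotationDirection = "NONE"
            c.BeamLimitingDeviceAngle = _ds_float(cp.collimator_angle)
            c.CumulativeMetersetWeight = _ds_float(cp.cumulative_meterset_weight)
            if cp.index == 0:
                c.IsocenterPosition = [_ds_float(v) for v in b.isocenter]
                c.NominalBeamEnergy = 6.0
            x1, x2, y1, y2 = cp.jaw_positions
            seqs = []
            for kind, vals in (("ASYMX", [x1, x2]), ("ASYMY", [y1, y2]),
                               ("MLCX", list(cp.leaf_positions))):
                e = Dataset()
                e.RTBeamLimitingDeviceType = kind
                e.LeafJawPositions = [_ds_float(v) for v in vals]
                seqs.append(e)
            c.BeamLimitingDevicePositionSequence = seqs
            bd.ControlPointSequence.append(c)
        ds.BeamSequence.append(bd)
    ds.save_as(str(path), enforce_file_format=True)


def plans_equal(a: TreatmentPlan, b: TreatmentPlan, tol: float = 0.0) -> bool:
    """Field-for-field plan equality (numeric fields within ``tol``)."""
    def close(x, y):
        return abs(float(x) - float(y)) <= tol

    if (a.plan_label != b.plan_label or a.technique != b.technique
            or not close(a.total_mu, b.total_mu)
            or len(a.beams) != len(b.beams)):
        return False
    if (a.prescribed_dose is None) != (b.prescribed_dose is None):
        return False
    if a.prescribed_dose is not None and not close(a.prescribed_dose, b.prescribed_dose):
        return False
    for ba, bb in zip(a.beams, b.beams):
        if (ba.number != bb.number or not close(ba.meterset_mu, bb.meterset_mu)
                or len(ba.control_points) != len(bb.control_points)):
            return False
        if any(not close(x, y) for x, y in zip(ba.isocenter, bb.isocenter)):
            return False
        for ca, cb in zip(ba.control_points, bb.control_points):
            if ca.index != cb.index:
                return False
            if not (close(ca.gantry_angle, cb.gantry_angle)
                    and close(ca.collimator_angle, cb.collimator_angle)
                    and close(ca.cumulative_meterset_weight,
                              cb.cumulative_meterset_weight)):
                return False
            if any(not close(x, y) for x, y in zip(ca.jaw_positions, cb.jaw_positions)):
                return False
            if tol == 0.0:
                if not np.array_equal(ca.leaf_positions, cb.leaf_positions):
                    return False
            elif np.max(np.abs(ca.leaf_positions - cb.leaf_positions)) > tol:
                return False
    return True


# --------------------------------------------------------------------------
# CT + structures
# --------------------------------------------------------------------------

def read_ct_and_structures(ct_dir: str | Path,
                           rs_path: str | Path | None = None
                           ) -> tuple[CTVolume, StructureSet]:
    """Read a CT series (and optionally an RT Structure Set).

    Slices are sorted by position into one volume; contours are checked
    against the slice grid.
    """
    ct_dir = Path(ct_dir)
    files = sorted(p for p in ct_dir.glob("*.dcm"))
    slices = []
    for p in files:
        ds = pydicom.dcmread(str(p))
        if getattr(ds, "Modality", None) == "CT":
            slices.append(ds)
    if not slices:
        raise GeometryError(f"no CT slices found in {ct_dir}")

    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    orient = np.array([float(v) for v in first.ImageOrientationPatient])
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise GeometryError("only axial identity-orientation CT is supported")
    dy, dx = (float(v) for v in first.PixelSpacing)
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        dzs = np.diff(zs)
        if np.any(np.abs(dzs - dzs[0]) > 1e-3):
            raise GeometryError("inconsistent CT slice spacing")
        dz = float(dzs[0])
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    for s in slices:
        if [float(v) for v in s.PixelSpacing] != [dy, dx]:
            raise GeometryError("inconsistent in-plane pixel spacing")

    hu = np.stack([
        (s.pixel_array.astype(np.float32) * float(getattr(s, "RescaleSlope", 1.0))
         + float(getattr(s, "RescaleIntercept", 0.0)))
        for s in slices
    ])
    hu = np.clip(np.round(hu), -1024, 3500).astype(np.int16)
    origin = (float(first.ImagePositionPatient[0]),
              float(first.ImagePositionPatient[1]), float(zs[0]))
    ct = CTVolume(hu=hu, origin=origin, spacing=(dx, dy, dz))

    structures = StructureSet()
    if rs_path is not None:
        structures = read_structures(rs_path)
        zpos = ct.slice_positions()
        for roi in structures.rois:
            for z, _ in roi.contours:
                if np.min(np.abs(zpos - z)) > 0.51 * dz:
                    raise ContourError(
                        f"ROI {roi.name!r}: contour at z={z} mm references a "
                        "missing CT slice")
    return ct, structures


def read_structures(rs_path: str | Path) -> StructureSet:
    ds = pydicom.dcmread(str(rs_path))
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise RTIOError(f"{rs_path}: not an RT Structure Set")
    names = {int(r.ROINumber): str(r.ROIName)
             for r in getattr(ds, "StructureSetROISequence", [])}
    densities: dict[int, float] = {}
    for obs in getattr(ds, "RTROIObservationsSequence", []):
        for prop in getattr(obs, "ROIPhysicalPropertiesSequence", []):
            if prop.ROIPhysicalProperty == "REL_MASS_DENSITY":
                densities[int(obs.ReferencedROINumber)] = float(
                    prop.ROIPhysicalPropertyValue)
    rois = []
    for rc in getattr(ds, "ROIContourSequence", []):
        num = int(rc.ReferencedROINumber)
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            pts = np.array([float(v) for v in c.ContourData]).reshape(-1, 3)
            if pts.shape[0] < 3:
                raise ContourError(f"ROI {names.get(num)}: degenerate contour")
            if np.ptp(pts[:, 2]) > 1e-6:
                raise ContourError(f"ROI {names.get(num)}: contour is not planar")
            contours.append((float(pts[0, 2]), pts[:, :2].copy()))
        rois.append(ROI(name=names.get(num, f"roi{num}"), number=num,
                        contours=contours,
                        override_density=densities.get(num)))
    return StructureSet(rois=rois)


def write_ct(ct: CTVolume, out_dir: str | Path, seed: int = 0) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nz, ny, nx = ct.hu.shape
    paths = []
    for iz in range(nz):
        sop = deterministic_uid(seed, f"ct-{iz}")
        ds = _base_dataset(_CT_SOP, sop, "CT", seed)
        ds.InstanceNumber = iz + 1
        ds.ImagePositionPatient = [_ds_float(ct.origin[0]), _ds_float(ct.origin[1]),
                                   _ds_float(ct.origin[2] + iz * ct.spacing[2])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [_ds_float(ct.spacing[1]), _ds_float(ct.spacing[0])]
        ds.SliceThickness = _ds_float(ct.spacing[2])
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = np.ascontiguousarray(ct.hu[iz]).astype("<i2").tobytes()
        p = out_dir / f"ct_{iz:03d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


def write_structures(structures: StructureSet, path: str | Path,
                     seed: int = 0) -> None:
    sop = deterministic_uid(seed, "rtstruct")
    ds = _base_dataset(_STRUCT_SOP, sop, "RTSTRUCT", seed)
    ds.StructureSetLabel = "fixtures"
    ds.StructureSetDate = _FIXED_DATE
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for roi in structures.rois:
        r = Dataset()
        r.ROINumber = roi.number
        r.ROIName = roi.name
        r.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        r.ROIGenerationAlgorithm = "MANUAL"
        ds.StructureSetROISequence.append(r)

        rc = Dataset()
        rc.ReferencedROINumber = roi.number
        rc.ContourSequence = []
        for z, xy in roi.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = xy.shape[0]
            data = []
            for x, y in xy:
                data += [_ds_float(x), _ds_float(y), _ds_float(z)]
            c.ContourData = data
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)

        obs = Dataset()
        obs.ObservationNumber = roi.number
        obs.ReferencedROINumber = roi.number
        obs.ROIObservationLabel = roi.name
        obs.RTROIInterpretedType = "ORGAN"
        if roi.override_density is not None:
            prop = Dataset()
            prop.ROIPhysicalProperty = "REL_MASS_DENSITY"
            prop.ROIPhysicalPropertyValue = _ds_float(roi.override_density)
            obs.ROIPhysicalPropertiesSequence = [prop]
        ds.RTROIObservationsSequence.append(obs)
    ds.save_as(str(path), enforce_file_format=True)


def roi_mask(structures: StructureSet, name: str, geometry,
             strict: bool = True) -> np.ndarray:
    """Rasterize an ROI onto a grid (bool array [iz, iy, ix]).

    ``geometry`` needs ``origin``, ``spacing`` and ``shape`` attributes.
    With ``strict`` a contour outside the grid is an error; otherwise it
    is skipped (useful when masking onto a dose grid smaller than the CT).
    """
    roi = structures.get(name)
    nz, ny, nx = geometry.shape
    x0, y0, z0 = geometry.origin
    dx, dy, dz = geometry.spacing
    mask = np.zeros((nz, ny, nx), dtype=bool)
    for z, xy in roi.contours:
        iz = int(round((z - z0) / dz))
        if not 0 <= iz < nz:
            if strict:
                raise ContourError(f"ROI {name!r}: contour z={z} outside grid")
            continue
        poly = np.column_stack([(xy[:, 1] - y0) / dy, (xy[:, 0] - x0) / dx])
        mask[iz] |= polygon2mask((ny, nx), poly)
    return mask


# --------------------------------------------------------------------------
# RT Dose
# --------------------------------------------------------------------------

def write_dose(grid: DoseGrid, path: str | Path, seed: int = 0,
               dose_type: str = "PHYSICAL") -> None:
    """Write a dose grid as an RT Dose file (32-bit scaled integers)."""
    if any(s <= 0 for s in grid.spacing):
        raise GeometryError("refusing to write dose grid with non-monotonic axes")
    dose = np.asarray(grid.dose, dtype=np.float64)
    nz, ny, nx = dose.shape
    peak = float(dose.max())
    scaling = peak / (2**32 - 1) if peak > 0 else 1.0
    pixels = np.round(dose / scaling).astype("<u4")

    sop = deterministic_uid(seed, f"rtdose-{dose_type}")
    ds = _base_dataset(_DOSE_SOP, sop, "RTDOSE", seed)
    ds.DoseUnits = "GY"
    ds.DoseType = dose_type
    ds.DoseSummationType = "PLAN"
    ds.ImagePositionPatient = [_ds_float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [_ds_float(grid.spacing[1]), _ds_float(grid.spacing[0])]
    ds.GridFrameOffsetVector = [_ds_float(i * grid.spacing[2]) for i in range(nz)]
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.Rows, ds.Columns = ny, nx
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseGridScaling = _ds_float(scaling, 16)
    ds.PixelData = np.ascontiguousarray(pixels).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_dose(path: str | Path) -> DoseGrid:
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise RTIOError(f"{path}: not an RT Dose object")
    scaling = float(ds.DoseGridScaling)
    dose = ds.pixel_array.astype(np.float64) * scaling
    if dose.ndim == 2:
        dose = dose[None]
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1:
        dzs = np.diff(offsets)
        if np.any(dzs <= 0) or np.any(np.abs(dzs - dzs[0]) > 1e-6):
            raise GeometryError("non-uniform or non-monotonic dose frame offsets")
        dz = float(dzs[0])
    else:
        dz = 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(dose=dose, uncertainty=None, origin=origin,
                    spacing=(dx, dy, dz))


def __getattr__(name):
    # `rt_io.generate_fixtures` is part of this module's surface; the
    # implementation lives in fixtures.py (lazy to avoid an import cycle)
    if name == "generate_fixtures":
        from .fixtures import generate_fixtures
        return generate_fixtures
    raise AttributeError(name)
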