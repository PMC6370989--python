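"""Self-contained synthetic DICOM-RT fixture sets.

Each fixture emits an internally consistent CT series + RT Plan +
RT Structure Set (and, for the dynamic water cases, a synthetic
reference RT Dose) for a water-box phantom, so the full pipeline can
run without any external download:

``closed_mlc``
    Static beam, all 60 leaf pairs abutting at the midline, 10x10 cm^2
    jaws — the abutting/interleaf leakage configuration.
``open_10x10``
    MLC-defined 10x10 cm^2 aperture inside 15x15 cm^2 jaws; pairs
    outside the aperture are parked closed under the X1 jaw.
``water_imrt``
    One fixed gantry angle, 160 control points, a 2 cm sliding-window
    slit sweeping across the field.
``water_vmat``
    160 control points with gantry spanning 360 degrees and a slowly
    breathing rectangular aperture.

All UIDs, dates and numeric encodings are deterministic functions of
the seed, so a fixture set is byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .rt_io import (Beam, ControlPoint, CTVolume, DoseGrid, ROI, StructureSet,
                    TreatmentPlan, write_ct, write_dose, write_plan,
                    write_structures)

FIXTURE_KINDS = ("water_vmat", "water_imrt", "closed_mlc", "open_10x10")

_PARKED = -80.0  # closed-pair abutment position, mm (under the X1 jaw
                 # whenever the jaw opening is inside +-75 mm)

# default pair boundaries (10x10mm, 40x5mm, 10x10mm)
_BOUNDS = np.concatenate([[-200.0], -200.0 + np.cumsum(
    [10.0] * 10 + [5.0] * 40 + [10.0] * 10)])


def _box_contour(half_x, half_y):
    return np.array([[-half_x, -half_y], [half_x, -half_y],
                     [half_x, half_y], [-half_x, half_y]], dtype=float)


def water_box_ct() -> CTVolume:
    """50-slice water box: HU 0 inside +-120 mm, air outside."""
    nz, ny, nx = 50, 128, 128
    dx = dy = 2.5
    dz = 4.0
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    hu = np.full((nz, ny, nx), -1000, dtype=np.int16)
    inside = (np.abs(x)[None, :] <= 120.0) & (np.abs(y)[:, None] <= 120.0)
    hu[:, inside] = 0
    origin = (float(x[0]), float(y[0]), -(nz - 1) / 2 * dz)
    return CTVolume(hu=hu, origin=origin, spacing=(dx, dy, dz))


def water_structures(ct: CTVolume) -> StructureSet:
    zs = ct.slice_positions()
    body = ROI(name="BODY", number=1,
               contours=[(float(z), _box_contour(120.0, 120.0)) for z in zs])
    ptv = ROI(name="PTV", number=2,
              contours=[(float(z), _box_contour(30.0, 30.0))
                        for z in zs if abs(z) <= 20.0])
    marker_xy = np.array([[40.0, -5.0], [50.0, -5.0], [50.0, 5.0], [40.0, 5.0]])
    iz0 = int(np.argmin(np.abs(zs)))
    marker = ROI(name="MARKER", number=3,
                 contours=[(float(zs[iz0]), marker_xy)],
                 override_density=4.5)
    return StructureSet(rois=[body, ptv, marker])


def _closed_leaves():
    return np.zeros(120)


def _pair_centers():
    return (_BOUNDS[:-1] + _BOUNDS[1:]) / 2.0


def _static_plan(label, jaw_half, leaves, total_mu):
    cps = []
    for i, w in enumerate((0.0, 1.0)):
        cps.append(ControlPoint(
            index=i, gantry_angle=0.0, collimator_angle=0.0,
            jaw_positions=(-jaw_half, jaw_half, -jaw_half, jaw_half),
            leaf_positions=leaves.copy(), cumulative_meterset_weight=w))
    beam = Beam(name=label, number=1, meterset_mu=total_mu,
                isocenter=(0.0, 0.0, 0.0), control_points=cps)
    return TreatmentPlan(plan_label=label, total_mu=total_mu,
                         technique="STATIC", beams=[beam],
                         prescribed_dose=None)


def closed_mlc_plan() -> TreatmentPlan:
    """All 120 leaves abutting at the midline, jaws 10x10 cm^2, 400 MU."""
    return _static_plan("closed-mlc", 50.0, _closed_leaves(), 400.0)


def open_10x10_plan() -> TreatmentPlan:
    """MLC 10x10 cm^2 aperture inside 15x15 cm^2 jaws, 100 MU."""
    leaves = np.full(120, _PARKED)
    centers = _pair_centers()
    open_pairs = (_BOUNDS[:-1] >= -50.0) & (_BOUNDS[1:] <= 50.0)
    leaves[:60][open_pairs] = -50.0
    leaves[60:][open_pairs] = 50.0
    del centers
    plan = _static_plan("open-10x10", 75.0, leaves, 100.0)
    plan.plan_label = "open-10x10"
    return plan


def water_imrt_plan(n_cp: int = 160) -> TreatmentPlan:
    """Unidirectional sliding-window IMRT: fixed gantry, 160 CPs, 191 MU."""
    moving = (_BOUNDS[:-1] >= -40.0) & (_BOUNDS[1:] <= 40.0)
    cps = []
    for i in range(n_cp):
        center = -40.0 + 80.0 * i / (n_cp - 1)
        leaves = np.full(120, _PARKED)
        leaves[:60][moving] = round(center - 10.0, 2)
        leaves[60:][moving] = round(center + 10.0, 2)
        cps.append(ControlPoint(
            index=i, gantry_angle=0.0, collimator_angle=0.0,
            jaw_positions=(-52.0, 52.0, -40.0, 40.0),
            leaf_positions=leaves,
            cumulative_meterset_weight=round(i / (n_cp - 1), 6)))
    beam = Beam(name="imrt", number=1, meterset_mu=191.0,
                isocenter=(0.0, 0.0, 0.0), control_points=cps)
    return TreatmentPlan(plan_label="water-imrt", total_mu=191.0,
                         technique="IMRT", beams=[beam], prescribed_dose=1.39)


def water_vmat_plan(n_cp: int = 160) -> TreatmentPlan:
    """Full-arc VMAT: 160 CPs, gantry spanning 360 degrees, 312.5 MU."""
    open_pairs = (_BOUNDS[:-1] >= -50.0) & (_BOUNDS[1:] <= 50.0)
    cps = []
    for i in range(n_cp):
        phase = 2.0 * np.pi * i / (n_cp - 1)
        leaves = np.full(120, _PARKED)
        leaves[:60][open_pairs] = round(-30.0 + 6.0 * np.sin(phase), 2)
        leaves[60:][open_pairs] = round(30.0 + 6.0 * np.sin(2.0 * phase), 2)
        cps.append(ControlPoint(
            index=i, gantry_angle=round(360.0 * i / (n_cp - 1), 3),
            collimator_angle=10.0,
            jaw_positions=(-40.0, 40.0, -55.0, 55.0),
            leaf_positions=leaves,
            cumulative_meterset_weight=round(i / (n_cp - 1), 6)))
    beam = Beam(name="vmat", number=1, meterset_mu=312.5,
                isocenter=(0.0, 0.0, 0.0), control_points=cps)
    return TreatmentPlan(plan_label="water-vmat", total_mu=312.5,
                         technique="VMAT", beams=[beam], prescribed_dose=1.43)


def synthetic_reference_dose(peak_gy: float) -> DoseGrid:
    """Synthetic stand-in for a TPS reference dose (Gaussian blob).

    This is NOT a planning-system calculation; it exists only so the
    comparison pipeline has a second dose grid to exercise.
    """
    nz, ny, nx = 25, 60, 60
    dx = dy = 4.0
    dz = 4.0
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    z = (np.arange(nz) - (nz - 1) / 2) * dz
    g = np.exp(-(x[None, None, :] ** 2 + y[None, :, None] ** 2) / (2 * 25.0 ** 2)
               - z[:, None, None] ** 2 / (2 * 30.0 ** 2))
    return DoseGrid(dose=peak_gy * g, uncertainty=None,
                    origin=(float(x[0]), float(y[0]), float(z[0])),
                    spacing=(dx, dy, dz))


_PLAN_BUILDERS = {
    "closed_mlc": closed_mlc_plan,
    "open_10x10": open_10x10_plan,
    "water_imrt": water_imrt_plan,
    "water_vmat": water_vmat_plan,
}


def generate_fixtures(kind: str, out_dir: str | Path, seed: int = 0) -> dict:
    """Emit a complete fixture file set; returns the paths written."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"fixture output directory not writable: {out}") from exc

    ct = water_box_ct()
    ct_dir = out / "ct"
    write_ct(ct, ct_dir, seed=seed)

    structures = water_structures(ct)
    rs_path = out / "rtstruct.dcm"
    write_structures(structures, rs_path, seed=seed)

    plan = _PLAN_BUILDERS[kind]()
    plan_path = out / "rtplan.dcm"
    write_plan(plan, plan_path, seed=seed)

    paths = {"ct_dir": ct_dir, "structures": rs_path, "plan": plan_path}
    if kind in ("water_vmat", "water_imrt"):
        peak = 1.59 if kind == "water_vmat" else 1.39
        dose_path = out / "rtdose_tps_synthetic.dcm"
        write_dose(synthetic_reference_dose(peak), dose_path, seed=seed)
        paths["reference_dose"] = dose_path
    return paths
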