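"""Absolute-dose calibration (DSF determination).

The engine outputs dose per simulated run, not per monitor unit.  The
dose scaling factor (DSF) ties the two together on a reference
geometry: a 10x10 cm^2 field formed by the jaws alone on a water
phantom at SSD 100 cm.  The maximum of the central-axis depth-dose
curve from a reference run is matched to the machine calibration dose
(1 Gy per 100 MU at dmax by convention, configurable), normalized to a
nominal reference budget of 2e9 histories.  Applying the DSF to another
run divides by the ratio of its history count to the reference count
and multiplies by the plan MU.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .delivery import DoseScalingFactor, dose_scaling
from .fixtures import _static_plan
from .machine import MachineProfile
from .materials import VoxelPhantom
from .transport import SourceModel, TransportSettings, simulate_dose


def reference_plan():
    """10x10 cm^2 jaw-only field: MLC fully retracted, 100 MU."""
    leaves = np.concatenate([np.full(60, -100.0), np.full(60, 100.0)])
    return _static_plan("dsf-reference", 50.0, leaves, 100.0)


def reference_phantom(depth_mm: float = 250.0, half_width_mm: float = 80.0,
                      voxel_mm: float = 4.0, axial_voxel_mm: float = 2.0
                      ) -> VoxelPhantom:
    """Water slab at SSD 100: surface at the isocenter plane, beam along +y."""
    nx = int(2 * half_width_mm / voxel_mm)
    ny = int(depth_mm / axial_voxel_mm)
    nz = nx
    origin = (-half_width_mm + voxel_mm / 2, axial_voxel_mm / 2,
              -half_width_mm + voxel_mm / 2)
    return VoxelPhantom.water_box((nz, ny, nx),
                                  (voxel_mm, axial_voxel_mm, voxel_mm), origin)


def central_axis_pdd(grid, radius_mm: float = 12.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(depth mm, dose) along the central axis of a reference-phantom run.

    The dose is averaged over a small central column (default 12 mm
    half-width, well inside the flat region of a 10x10 field) to tame
    Monte Carlo noise.
    """
    nz, ny, nx = grid.shape
    cx, cz = nx // 2, nz // 2
    rx = max(1, int(radius_mm / grid.spacing[0]))
    rz = max(1, int(radius_mm / grid.spacing[2]))
    dose = np.asarray(grid.dose)[cz - rz:cz + rz, :, cx - rx:cx + rx].mean(axis=(0, 2))
    depth = grid.origin[1] + np.arange(ny) * grid.spacing[1]
    return depth, dose


def calibrate_dsf(machine: MachineProfile, source: SourceModel,
                  settings: TransportSettings,
                  reference_dose_gy: float = 1.0) -> tuple[DoseScalingFactor, dict]:
    """Determine the DSF on the jaw-only 10x10 reference field.

    Returns the factor plus a provenance record (geometry, budget,
    dmax) suitable for caching to JSON.
    """
    plan = reference_plan()
    phantom = reference_phantom()
    grid = simulate_dose(plan, phantom, source, settings, machine)
    depth, dose = central_axis_pdd(grid)
    # 5-bin moving average stabilizes the dmax pick against MC noise
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(dose, kernel, mode="same")
    i_max = int(np.argmax(smooth))
    d_raw_max = float(smooth[i_max])
    if d_raw_max <= 0:
        raise RuntimeError("reference run produced no central-axis dose")
    ref = DoseScalingFactor(dsf=1.0)  # placeholder for the constants
    dsf_value = reference_dose_gy / (
        d_raw_max * (ref.reference_histories / settings.n_histories))
    dsf = DoseScalingFactor(dsf=dsf_value)
    info = {
        "machine": machine.name,
        "reference_field": "10x10 cm^2 jaws only, water, SSD 100 cm",
        "reference_dose_gy_per_100mu": reference_dose_gy,
        "histories": settings.n_histories,
        "seed": settings.seed,
        "mode": settings.mode,
        "dmax_depth_mm": float(depth[i_max]),
        "raw_dmax": d_raw_max,
        "uncertainty_at_dmax": float(
            np.asarray(grid.uncertainty)[grid.shape[0] // 2, i_max,
                                         grid.shape[2] // 2]),
    }
    return dsf, info


def save_dsf(dsf: DoseScalingFactor, info: dict, path: str | Path) -> None:
    payload = {"dsf": asdict(dsf), "provenance": info}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_dsf(path: str | Path) -> tuple[DoseScalingFactor, dict]:
    payload = json.loads(Path(path).read_text())
    return DoseScalingFactor(**payload["dsf"]), payload.get("provenance", {})


def scale_to_absolute(raw_grid, dsf: DoseScalingFactor, used_histories: int,
                      plan_mu: float):
    """Convenience wrapper around :func:`mlcdose.delivery.dose_scaling`."""
    return dose_scaling(raw_grid, dsf, used_histories, plan_mu)


def profile_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]
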