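"""Delivery sequencing: control-point weighting, phantom rotation, dose scaling.

A dynamic plan is delivered as a sum of weighted static apertures.  The
MU weight of a control point is its segment MU divided by the total MU;
IMRT and VMAT distribute particles differently:

* IMRT — the first control point gets zero particles; each subsequent
  control point gets the increment of the cumulative meterset weight.
* VMAT — the first and last control points get half their MU weight and
  interior control points get the average of the current and previous
  MU weights (the aperture is representative of the arc segment on
  either side).  The literal rule does not sum to one, so fractions are
  renormalized (the pre-normalization sum is recorded).

Gantry rotation is realized by rotating the phantom about the isocenter
instead of the treatment head: rotating the phantom by +theta
reproduces the geometry of a gantry at -theta with a fixed phantom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .rt_io import DoseGrid, TreatmentPlan

log = logging.getLogger(__name__)


@dataclass
class DeliveryWeights:
    """Per-control-point delivery fractions (flattened over beams)."""

    fractions: np.ndarray
    normalized_flag: bool
    total_mu: float
    raw_sum: float  # pre-normalization sum of the VMAT rule
    beam_slices: list[slice]

    def __post_init__(self):
        if np.any(self.fractions < 0):
            raise ValueError("delivery fractions must be non-negative")


@dataclass
class DoseScalingFactor:
    """Absolute-dose calibration: Gy per MC output at the reference run.

    ``dsf`` converts the raw engine output of a run with
    ``reference_histories`` histories and ``reference_mu`` MU to Gy.
    """

    dsf: float
    reference_histories: float = 2e9
    reference_mu: float = 100.0

    def __post_init__(self):
        if not self.dsf > 0:
            raise ValueError("dose scaling factor must be positive")


def _segment_weights(cum, mode: str):
    cum = np.asarray(cum, dtype=float)
    if mode == "delta":
        return np.diff(np.concatenate([[0.0], cum]))
    if mode == "cumulative":
        return cum.copy()
    raise ValueError(f"unknown VMAT weight reading {mode!r}")


def control_point_weights(plan: TreatmentPlan, technique: str | None = None,
                          vmat_weight_mode: str = "delta") -> DeliveryWeights:
    """Particle-allocation fractions for every control point of a plan.

    ``vmat_weight_mode`` selects whether the per-control-point "MU
    weight" entering the VMAT half/average rule is read as the segment
    delta of the cumulative meterset (default) or as the cumulative
    value itself.
    """
    technique = (technique or plan.technique).upper()
    fractions = []
    slices = []
    raw_total = 0.0
    pos = 0
    mu_total = sum(b.meterset_mu for b in plan.beams) or plan.total_mu
    for beam in plan.beams:
        cum = np.array([cp.cumulative_meterset_weight
                        for cp in beam.control_points])
        if technique in ("IMRT", "STATIC"):
            f = np.diff(np.concatenate([[0.0], cum]))
            f[0] = 0.0  # no particles for the first control point
        else:  # VMAT
            w = _segment_weights(cum, vmat_weight_mode)
            f = np.empty_like(w)
            f[0] = w[0] / 2.0
            f[-1] = w[-1] / 2.0
            if len(w) > 2:
                f[1:-1] = (w[1:-1] + w[:-2]) / 2.0
        beam_mu_frac = beam.meterset_mu / mu_total if mu_total else 1.0
        fractions.append(f * beam_mu_frac)
        slices.append(slice(pos, pos + len(f)))
        pos += len(f)
    f = np.concatenate(fractions)
    raw_total = float(f.sum())
    if raw_total <= 0:
        raise ValueError("plan has zero total delivery weight")
    normalized = not math.isclose(raw_total, 1.0, abs_tol=1e-12)
    if normalized:
        log.info("delivery fractions renormalized (pre-normalization sum %.6f)",
                 raw_total)
    return DeliveryWeights(fractions=f / raw_total, normalized_flag=normalized,
                           total_mu=plan.total_mu, raw_sum=raw_total,
                           beam_slices=slices)


def allocate_histories(weights: DeliveryWeights, n_histories: int) -> np.ndarray:
    """Integer histories per control point by largest remainder.

    The total equals ``n_histories`` exactly.
    """
    ideal = weights.fractions * n_histories
    base = np.floor(ideal).astype(np.int64)
    short = n_histories - int(base.sum())
    if short > 0:
        order = np.argsort(-(ideal - base))
        base[order[:short]] += 1
    return base


def phantom_frame_transform(gantry_angle: float, collimator_angle: float = 0.0,
                            isocenter=(0.0, 0.0, 0.0)):
    """Rigid transform (R, t) applied to the phantom for a gantry angle.

    Rotating the phantom by +theta about the isocenter gantry axis
    reproduces a gantry at -theta with a fixed phantom.  Points map as
    ``R @ (p - iso) + iso``; ``t`` folds the isocenter in so the map is
    ``R @ p + t``.  The collimator angle rotates about the beam axis and
    is composed the same way.
    """
    iso = np.asarray(isocenter, dtype=float)
    g = math.radians(gantry_angle)
    # patient frame: x lateral, y anterior(-)->posterior(+), z inferior->superior;
    # the gantry axis is the patient z axis
    cg, sg = math.cos(g), math.sin(g)
    rg = np.array([[cg, -sg, 0.0], [sg, cg, 0.0], [0.0, 0.0, 1.0]])
    if collimator_angle:
        c = math.radians(collimator_angle)
        cc, sc = math.cos(c), math.sin(c)
        # beam axis at gantry 0 is +y; collimator rotates about it
        rc = np.array([[cc, 0.0, sc], [0.0, 1.0, 0.0], [-sc, 0.0, cc]])
        r = rg @ rc
    else:
        r = rg
    t = iso - r @ iso
    return r, t


def beam_to_patient_frame(gantry_angle: float, collimator_angle: float = 0.0,
                          isocenter=(0.0, 0.0, 0.0), sad: float = 1000.0):
    """Map beam-frame points (source at origin, +z toward isocenter) into
    the patient frame for a given gantry/collimator state.

    Inverse companion of :func:`phantom_frame_transform`: instead of
    rotating the phantom by +theta we rotate the beam by -theta, which
    is the same geometry with fewer interpolations.
    """
    iso = np.asarray(isocenter, dtype=float)
    # rotating the phantom by +theta equals rotating the beam by -theta,
    # so a gantry at +g uses the +g rotation on the beam frame
    r, _ = phantom_frame_transform(gantry_angle, 0.0)
    # beam frame at gantry 0: ex=+x_pat, ey=+z_pat, ez(beam axis)=+y_pat,
    # source sits SAD anterior of the isocenter
    basis = np.array([[1.0, 0.0, 0.0],
                      [0.0, 0.0, 1.0],
                      [0.0, 1.0, 0.0]]).T  # columns: beam ex, ey, ez in patient
    if collimator_angle:
        c = math.radians(collimator_angle)
        cc, sc = math.cos(c), math.sin(c)
        rc = np.array([[cc, -sc, 0.0], [sc, cc, 0.0], [0.0, 0.0, 1.0]])
        basis = basis @ rc
    rot = r @ basis
    source = iso + r @ np.array([0.0, -sad, 0.0])
    return rot, source


def dose_scaling(raw_dose: DoseGrid, dsf: DoseScalingFactor,
                 used_histories: float, plan_mu: float) -> DoseGrid:
    """Scale raw engine output to absolute Gy.

    ``scaled = raw * dsf * (reference_histories / used) * (mu / reference_mu)``
    — linear in the raw dose.
    """
    if not used_histories > 0:
        raise ValueError("used_histories must be positive")
    k = dsf.dsf * (dsf.reference_histories / used_histories) * (
        plan_mu / dsf.reference_mu)
    unc = None if raw_dose.uncertainty is None else raw_dose.uncertainty.copy()
    return DoseGrid(dose=raw_dose.dose * k, uncertainty=unc,
                    origin=raw_dose.origin, spacing=raw_dose.spacing,
                    orientation=raw_dose.orientation.copy())
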