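"""Dose-comparison analytics: DVH, dose-volumetric parameters,
difference maps, profile FWHM, and uncertainty summaries.

Dose-volumetric parameters follow the usual clinical definitions:
D95% is the dose received by at least 95% of the ROI volume (near
minimum D98%, near maximum D2%, and the mean).  Scalar and voxel-wise
dose differences are expressed as a percentage of the prescribed dose;
voxel-wise maps resample the coarser grid onto the finer one with
trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .rt_io import DoseGrid


class AnalysisError(ValueError):
    pass


@dataclass
class DVHCurve:
    """Cumulative DVH: volume fraction with dose >= each bin edge."""

    dose_bins: np.ndarray  # Gy, ascending
    cumulative_volume_fraction: np.ndarray  # in [0, 1], non-increasing

    def __post_init__(self):
        v = self.cumulative_volume_fraction
        if np.any(np.diff(self.dose_bins) <= 0):
            raise AnalysisError("DVH dose bins must be strictly ascending")
        if np.any(np.diff(v) > 1e-12) or v[0] > 1 + 1e-12 or np.any(v < -1e-12):
            raise AnalysisError("DVH must be non-increasing within [0, 1]")


def dvh_curve(dose: DoseGrid, mask: np.ndarray, bin_width: float = 0.01,
              roi_name: str = "ROI") -> DVHCurve:
    """Cumulative DVH of the masked voxels.

    ``cumulative_volume_fraction[k]`` is the fraction of masked voxels
    with dose >= ``dose_bins[k]``; the curve starts at 1.0 for zero
    dose and reaches 0 beyond the maximum dose.
    """
    if bin_width <= 0:
        raise AnalysisError("bin width must be positive")
    vals = np.asarray(dose.dose)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise AnalysisError(f"ROI {roi_name!r}: empty mask")
    top = float(vals.max()) + 2 * bin_width
    bins = np.arange(0.0, top, bin_width)
    # 1e-9 Gy guard so doses sitting exactly on a bin edge (e.g. after
    # RT Dose quantization) count as >= that edge
    frac = 1.0 - np.searchsorted(np.sort(vals), bins - 1e-9,
                                 side="left") / vals.size
    return DVHCurve(dose_bins=bins, cumulative_volume_fraction=frac)


def dose_at_volume(curve: DVHCurve, volume_percent: float) -> float:
    """Dose covering at least ``volume_percent`` of the volume (Dx%).

    The largest dose whose cumulative volume fraction is still >= the
    requested fraction, linearly interpolated between bin edges.
    """
    if not 0.0 < volume_percent < 100.0:
        raise AnalysisError("volume percent must be in (0, 100)")
    target = volume_percent / 100.0
    v = curve.cumulative_volume_fraction
    d = curve.dose_bins
    above = v >= target
    if not above.any():
        return float(d[0])
    k = int(np.nonzero(above)[0][-1])
    if k + 1 >= d.size or v[k] == v[k + 1]:
        return float(d[k])
    # interpolate within the bin where the curve crosses the target
    return float(d[k] + (d[k + 1] - d[k]) * (v[k] - target) / (v[k] - v[k + 1]))


def dose_metrics(dose: DoseGrid, mask: np.ndarray, bin_width: float = 0.01,
                 roi_name: str = "ROI") -> dict:
    """D95%, Dmean, D98%, D2% [Gy] for one ROI."""
    curve = dvh_curve(dose, mask, bin_width, roi_name)
    vals = np.asarray(dose.dose)[np.asarray(mask, dtype=bool)]
    return {
        "D95%": dose_at_volume(curve, 95.0),
        "Dmean": float(vals.mean()),
        "D98%": dose_at_volume(curve, 98.0),
        "D2%": dose_at_volume(curve, 2.0),
    }


def relative_difference(d_a, d_b, prescribed: float):
    """Dose difference as percent of the prescribed dose.

    ``100 * (d_a - d_b) / prescribed``, scalar- or array-wise.
    """
    if not prescribed > 0:
        raise AnalysisError("prescribed dose must be positive")
    a = np.asarray(d_a, dtype=float)
    b = np.asarray(d_b, dtype=float)
    out = 100.0 * (a - b) / prescribed
    return float(out) if out.ndim == 0 else out


def resample_to(grid: DoseGrid, reference: DoseGrid) -> np.ndarray:
    """Trilinearly resample ``grid`` onto ``reference``'s voxel centers."""
    nz, ny, nx = reference.shape
    zs = reference.origin[2] + np.arange(nz) * reference.spacing[2]
    ys = reference.origin[1] + np.arange(ny) * reference.spacing[1]
    xs = reference.origin[0] + np.arange(nx) * reference.spacing[0]
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    iz = (gz - grid.origin[2]) / grid.spacing[2]
    iy = (gy - grid.origin[1]) / grid.spacing[1]
    ix = (gx - grid.origin[0]) / grid.spacing[0]
    return map_coordinates(np.asarray(grid.dose, dtype=float),
                           [iz.ravel(), iy.ravel(), ix.ravel()],
                           order=1, mode="constant", cval=0.0
                           ).reshape(nz, ny, nx)


def difference_map(d_a: DoseGrid, d_b: DoseGrid, prescribed: float) -> DoseGrid:
    """Voxel-wise (a - b) difference in percent of prescribed dose.

    The coarser grid (larger voxel volume) is resampled onto the finer.
    Returned as a DoseGrid whose ``dose`` holds |diff| percent and whose
    signed values are in ``.signed_percent``.
    """
    vol_a = np.prod(d_a.spacing)
    vol_b = np.prod(d_b.spacing)
    fine, coarse = (d_a, d_b) if vol_a <= vol_b else (d_b, d_a)
    sign = 1.0 if vol_a <= vol_b else -1.0
    other = resample_to(coarse, fine)
    diff = sign * relative_difference(np.asarray(fine.dose), other, prescribed)
    out = DoseGrid(dose=np.abs(diff), uncertainty=None,
                   origin=fine.origin, spacing=fine.spacing)
    out.signed_percent = diff
    return out


def profile_fwhm(values, coords) -> float:
    """Full width at half maximum of a profile's main peak.

    The half-maximum level is baseline + (peak - baseline)/2, with the
    baseline taken as the median of the outer 20% of samples (the peak
    of a closed-field profile sits on an interleaf-leakage pedestal);
    crossings are located by linear interpolation.  The width is in the
    units of ``coords``.
    """
    v = np.asarray(values, dtype=float)
    x = np.asarray(coords, dtype=float)
    if v.size != x.size or v.size < 5:
        raise AnalysisError("profile needs matched coordinates and >= 5 samples")
    n_edge = max(1, int(round(0.1 * v.size)))
    baseline = float(np.median(np.concatenate([v[:n_edge], v[-n_edge:]])))
    i_pk = int(np.argmax(v))
    peak = float(v[i_pk])
    if not (0 < i_pk < v.size - 1) or peak <= baseline:
        raise AnalysisError("profile has no interior peak above its baseline")
    half = baseline + (peak - baseline) / 2.0
    # walk outward from the peak to the first half-maximum crossings
    left = right = None
    for i in range(i_pk, 0, -1):
        if v[i - 1] < half <= v[i]:
            left = x[i - 1] + (x[i] - x[i - 1]) * (half - v[i - 1]) / (v[i] - v[i - 1])
            break
    for i in range(i_pk, v.size - 1):
        if v[i + 1] < half <= v[i]:
            left_x, right_x = x[i], x[i + 1]
            right = left_x + (right_x - left_x) * (v[i] - half) / (v[i] - v[i + 1])
            break
    if left is None or right is None:
        raise AnalysisError("half-maximum crossings not found inside the profile")
    return float(right - left)


def voxel_uncertainty_summary(dose: DoseGrid, region: np.ndarray,
                              threshold_fraction: float = 0.5) -> float:
    """Mean relative 1-sigma uncertainty [%] over the high-dose part of a region.

    Voxels below ``threshold_fraction`` of the region's maximum dose are
    excluded (zero-dose voxels carry no meaningful relative error).
    """
    if dose.uncertainty is None:
        raise AnalysisError("dose grid carries no uncertainty estimate")
    m = np.asarray(region, dtype=bool)
    if not m.any():
        raise AnalysisError("empty uncertainty region")
    d = np.asarray(dose.dose)
    sel = m & (d >= threshold_fraction * float(d[m].max()))
    return float(np.mean(np.asarray(dose.uncertainty)[sel]) * 100.0)


@dataclass
class DoseReport:
    """Per-ROI metric table plus difference-map/profile artifacts."""

    table: pd.DataFrame
    prescribed: float
    diff_map: DoseGrid | None = None
    profiles: dict = field(default_factory=dict)
    lp_stats: object = None

    def to_text(self) -> str:
        lines = [f"prescribed dose: {self.prescribed:.2f} Gy",
                 self.table.to_string(index=False)]
        if self.lp_stats is not None:
            lines.append(
                f"LP<{self.lp_stats.threshold:g}mm in-field ratio: "
                f"{self.lp_stats.ratio:.3f}")
        return "\n".join(lines)


def compare_doses(mc: DoseGrid, tps: DoseGrid, masks: dict[str, np.ndarray],
                  prescribed: float, bin_width: float = 0.01,
                  lp_stats=None) -> DoseReport:
    """Per-ROI TPS/MC dose-volumetric comparison (masks on the MC grid)."""
    tps_on_mc = DoseGrid(dose=resample_to(tps, mc), uncertainty=None,
                         origin=mc.origin, spacing=mc.spacing)
    rows = []
    for name, mask in masks.items():
        m_mc = dose_metrics(mc, mask, bin_width, name)
        m_tps = dose_metrics(tps_on_mc, mask, bin_width, name)
        for key in ("D95%", "Dmean", "D98%", "D2%"):
            rows.append({
                "ROI": name, "metric": key,
                "TPS_Gy": round(m_tps[key], 4), "MC_Gy": round(m_mc[key], 4),
                "diff_%prescribed": round(
                    relative_difference(m_tps[key], m_mc[key], prescribed), 1),
            })
    table = pd.DataFrame(rows)
    dmap = difference_map(tps, mc, prescribed)
    return DoseReport(table=table, prescribed=prescribed, diff_map=dmap,
                      lp_stats=lp_stats)
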