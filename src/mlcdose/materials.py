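"""HU-to-material conversion and voxel phantoms.

CT numbers are mapped to mass density and elemental composition by a
stoichiometric binning table in the style of Schneider's method: an
ordered list of contiguous HU intervals, each carrying a density ramp
and a fixed composition.  The shipped 24-bin table is explicit,
editable data — the calibration is inherently scanner-specific, so the
table is configuration, not a constant.  ROI overrides let structures
(fiducial markers, virtual water, couch) force a density/composition
regardless of HU, and a body mask can force everything outside the
BODY contour to air.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .xsec import AIR, Material

log = logging.getLogger(__name__)

HU_MIN, HU_MAX = -1024, 3500


class MaterialTableError(ValueError):
    pass


_ELEMENT_COLUMNS = ["H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl", "Ar", "K", "Ca"]


@dataclass(frozen=True)
class MaterialBin:
    hu_lo: float
    hu_hi: float
    name: str
    density_lo: float
    density_hi: float
    composition: dict[str, float]

    def density_at(self, hu):
        """Linear density ramp across the bin."""
        hu = np.asarray(hu, dtype=float)
        if self.hu_hi == self.hu_lo:
            return np.full_like(hu, self.density_lo)
        t = np.clip((hu - self.hu_lo) / (self.hu_hi - self.hu_lo), 0.0, 1.0)
        return self.density_lo + t * (self.density_hi - self.density_lo)


@dataclass
class MaterialTable:
    """Ordered, contiguous HU bins covering [-1024, 3500]."""

    bins: list[MaterialBin]

    def __post_init__(self):
        if not self.bins:
            raise MaterialTableError("empty material table")
        if self.bins[0].hu_lo != HU_MIN or self.bins[-1].hu_hi != HU_MAX:
            raise MaterialTableError(
                f"bins must cover [{HU_MIN}, {HU_MAX}]"
            )
        for a, b in zip(self.bins, self.bins[1:]):
            if a.hu_hi != b.hu_lo:
                raise MaterialTableError(
                    f"bins {a.name!r}/{b.name!r} are not contiguous"
                )
        for b in self.bins:
            total = sum(b.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise MaterialTableError(
                    f"mass fractions of bin {b.name!r} sum to {total}"
                )
            if b.density_lo < 0 or b.density_hi < 0:
                raise MaterialTableError(f"negative density in bin {b.name!r}")
        self._edges = np.array([b.hu_lo for b in self.bins] + [HU_MAX], dtype=float)

    @staticmethod
    def from_csv(path: str | Path) -> "MaterialTable":
        bins = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            hu_lo, hu_hi = float(parts[0]), float(parts[1])
            name = parts[2]
            rho_lo, rho_hi = float(parts[3]), float(parts[4])
            fracs = [float(v) for v in parts[5:5 + len(_ELEMENT_COLUMNS)]]
            total = sum(fracs)
            comp = {el: w / total for el, w in zip(_ELEMENT_COLUMNS, fracs) if w > 0}
            bins.append(MaterialBin(hu_lo, hu_hi, name, rho_lo, rho_hi, comp))
        return MaterialTable(bins)

    @staticmethod
    def default() -> "MaterialTable":
        ref = resources.files("mlcdose.data") / "schneider_materials.csv"
        with resources.as_file(ref) as p:
            return MaterialTable.from_csv(p)

    def bin_index(self, hu):
        """Bin index per HU value; values outside coverage are clamped."""
        hu = np.asarray(hu, dtype=float)
        n_out = int(np.count_nonzero((hu < HU_MIN) | (hu >= HU_MAX)))
        if n_out:
            log.info("clamped %d HU values outside [%d, %d]", n_out, HU_MIN, HU_MAX)
        hu = np.clip(hu, HU_MIN, HU_MAX - 1e-9)
        return np.clip(np.searchsorted(self._edges, hu, side="right") - 1,
                       0, len(self.bins) - 1)

    def materials(self) -> list[Material]:
        """One :class:`~mlcdose.xsec.Material` per bin (nominal mid-bin density)."""
        return [
            Material.normalized(b.name, 0.5 * (b.density_lo + b.density_hi),
                                b.composition)
            for b in self.bins
        ]


@dataclass
class VoxelPhantom:
    """Voxelized patient/phantom model on a CT-like grid.

    ``material_index`` indexes into ``materials``; ``density`` is the
    per-voxel mass density in g/cm^3.  Arrays are [iz, iy, ix]; origin
    is the center of voxel (0,0,0) in mm, spacing is (dx, dy, dz).
    """

    material_index: np.ndarray
    density: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    materials: list[Material] = field(default_factory=list)

    def __post_init__(self):
        if self.material_index.shape != self.density.shape:
            raise ValueError("material_index and density shapes differ")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.materials:
            if int(self.material_index.max()) >= len(self.materials):
                raise ValueError("material index out of range")

    @property
    def shape(self):
        return self.material_index.shape

    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @staticmethod
    def water_box(shape, spacing, origin) -> "VoxelPhantom":
        """Uniform water phantom (convenience for commissioning-style runs)."""
        from .xsec import WATER
        idx = np.zeros(shape, dtype=np.int16)
        rho = np.full(shape, 1.0, dtype=np.float32)
        return VoxelPhantom(idx, rho, tuple(origin), tuple(spacing), [WATER])


def hu_to_material(ct, table: MaterialTable | None = None) -> VoxelPhantom:
    """Convert a CT volume to a voxel phantom via the binning table.

    Deterministic: bin assignment by HU interval, density from the
    bin's linear ramp.  Out-of-coverage HU are clamped (count logged).
    """
    if table is None:
        table = MaterialTable.default()
    hu = np.asarray(ct.hu, dtype=float)
    idx = table.bin_index(hu).astype(np.int16)
    rho = np.empty(hu.shape, dtype=np.float32)
    for i, b in enumerate(table.bins):
        m = idx == i
        if np.any(m):
            rho[m] = b.density_at(hu[m])
    return VoxelPhantom(
        material_index=idx,
        density=rho,
        origin=tuple(ct.origin),
        spacing=tuple(ct.spacing),
        materials=table.materials(),
    )


def apply_roi_overrides(
    phantom: VoxelPhantom,
    structures,
    mask_outside_body: bool = True,
    body_roi_name: str = "BODY",
) -> VoxelPhantom:
    """Apply structure-set physical-property overrides to a phantom.

    Overrides are applied in structure-file order (later ROIs win on
    overlap); if ``mask_outside_body`` and a BODY ROI exists, voxels
    outside it become air first.
    """
    from .rt_io import roi_mask  # local import to avoid a cycle

    idx = phantom.material_index.copy()
    rho = phantom.density.copy()
    mats = list(phantom.materials)

    geometry = _GridGeom(phantom)
    if mask_outside_body:
        body = next((r for r in structures.rois
                     if r.name.upper() == body_roi_name.upper()), None)
        if body is not None:
            inside = roi_mask(structures, body.name, geometry)
            air_idx = _ensure_material(mats, AIR)
            idx[~inside] = air_idx
            rho[~inside] = AIR.density

    for roi in structures.rois:
        if roi.override_density is None:
            continue
        comp = roi.override_composition
        if comp is None:
            comp = {"H": 0.111898, "O": 0.888102}  # water-equivalent default
        mat = Material.normalized(f"roi:{roi.name}", roi.override_density, comp)
        mat_idx = _ensure_material(mats, mat)
        m = roi_mask(structures, roi.name, geometry)
        idx[m] = mat_idx
        rho[m] = roi.override_density

    return VoxelPhantom(idx, rho, phantom.origin, phantom.spacing, mats)


def _ensure_material(mats: list[Material], mat: Material) -> int:
    for i, m in enumerate(mats):
        if m.name == mat.name:
            return i
    mats.append(mat)
    return len(mats) - 1


class _GridGeom:
    """Minimal geometry view (origin/spacing/shape) for rasterization."""

    def __init__(self, phantom: VoxelPhantom):
        self.origin = phantom.origin
        self.spacing = phantom.spacing
        self.shape = phantom.shape
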