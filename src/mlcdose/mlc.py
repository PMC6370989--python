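"""Parametric 120-leaf Millennium-style MLC model.

The bank is 60 leaf pairs (full, half and outboard widths) whose leaf
ends are rounded: the tip cross-section is a composite of a central
circular arc, two tangent flats and two tangent side arcs, mirrored
about the leaf mid-height.  The tungsten path length a ray sees behind
a leaf tip is an analytic, piecewise function of the depth behind the
tip apex; a degenerate pure-circular-tip configuration is available so
the composite can be checked against the classic chord formula.

Leaf positions live in millimetres at the isocenter plane (DICOM
convention, bank A on the negative-X side, bank A position <= bank B
position per pair).  Divergence projection to the physical MLC plane is
the similar-triangles ratio source-to-MLC / SAD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .xsec import AttenuationTable, Material

N_PAIRS = 60
N_LEAVES = 2 * N_PAIRS


class MachineConfigError(ValueError):
    """Invalid machine-geometry configuration."""


@dataclass(frozen=True)
class TipProfile:
    """Rounded leaf-end boundary: central arc + flats + side arcs.

    All lengths in mm.  ``central_angle_deg`` is the half-angle of the
    central arc measured from the apex; the flats continue tangentially,
    then the side arcs turn the boundary by up to ``side_arc_angle_deg``
    toward the leaf top/bottom faces at ``+-height/2``.
    """

    height: float
    central_radius: float
    central_angle_deg: float = 90.0
    flat_length: float = 0.0
    side_arc_radius: float = 0.0
    side_arc_angle_deg: float = 0.0

    @staticmethod
    def pure_circular(radius: float, height: float) -> "TipProfile":
        return TipProfile(height=height, central_radius=radius)

    def __post_init__(self):
        if self.height <= 0 or self.central_radius <= 0:
            raise MachineConfigError("tip height and radius must be positive")
        if self.central_radius < self.height / 2:
            raise MachineConfigError(
                "tip radius must span the leaf height (radius >= height/2)"
            )
        if not 0 < self.central_angle_deg <= 90:
            raise MachineConfigError("central arc half-angle must be in (0, 90]")
        if self.flat_length < 0 or self.side_arc_radius < 0 or self.side_arc_angle_deg < 0:
            raise MachineConfigError("tip segment lengths must be non-negative")

    def _pieces(self):
        """Breakpoints (u = depth behind apex, z = half-thickness)."""
        rc = self.central_radius
        th_c = math.radians(self.central_angle_deg)
        h2 = self.height / 2.0
        # central arc may reach h/2 on its own (pure circular case)
        z1 = rc * math.sin(th_c)
        u1 = rc * (1.0 - math.cos(th_c))
        if z1 >= h2:
            u_cap = rc - math.sqrt(rc * rc - h2 * h2)
            return {"rc": rc, "th_c": th_c, "u1": u_cap, "z1": h2,
                    "flat": None, "arc": None, "u_full": u_cap}
        flat = None
        u2, z2 = u1, z1
        if self.flat_length > 0:
            u2 = u1 + self.flat_length * math.sin(th_c)
            z2 = z1 + self.flat_length * math.cos(th_c)
            flat = (u1, z1, u2, min(z2, h2))
            if z2 >= h2:
                u_at_h = u1 + (h2 - z1) * math.tan(th_c)
                return {"rc": rc, "th_c": th_c, "u1": u1, "z1": z1,
                        "flat": (u1, z1, u_at_h, h2), "arc": None,
                        "u_full": u_at_h}
        arc = None
        u3, z3 = u2, z2
        if self.side_arc_radius > 0 and self.side_arc_angle_deg > 0:
            rs = self.side_arc_radius
            cu = u2 + rs * math.cos(th_c)
            cz = z2 - rs * math.sin(th_c)
            a_end = min(th_c + math.radians(self.side_arc_angle_deg),
                        math.pi / 2.0)
            s = (h2 - cz) / rs
            if -1.0 <= s <= 1.0:
                a_h = math.asin(min(1.0, max(-1.0, s)))
                if th_c < a_h < a_end:
                    a_end = a_h
            u3 = cu - rs * math.cos(a_end)
            z3 = cz + rs * math.sin(a_end)
            arc = (cu, cz, rs, th_c, a_end)
        return {"rc": rc, "th_c": th_c, "u1": u1, "z1": z1,
                "flat": flat, "arc": arc, "u_full": u3}

    @property
    def full_depth(self) -> float:
        """Depth behind the apex at which the body thickness is reached."""
        return self._pieces()["u_full"]

    def thickness(self, depth_mm):
        """Tungsten path [mm] along the beam axis at ``depth_mm`` behind the apex.

        Zero at and beyond the apex (depth <= 0), monotone non-decreasing,
        saturating at the physical height past the composite tip region.
        """
        scalar = np.ndim(depth_mm) == 0
        d = np.atleast_1d(np.asarray(depth_mm, dtype=float))
        p = self._pieces()
        h2 = self.height / 2.0
        z = np.zeros_like(d)

        m = (d > 0) & (d <= p["u1"])
        rc = p["rc"]
        z[m] = np.sqrt(np.maximum(rc * rc - (rc - d[m]) ** 2, 0.0))
        last_u = p["u1"]
        if p["flat"] is not None:
            u1, z1, u2, _ = p["flat"]
            m = (d > u1) & (d <= u2)
            z[m] = z1 + (d[m] - u1) / math.tan(p["th_c"])
            last_u = u2
        if p["arc"] is not None:
            cu, cz, rs, a0, a1 = p["arc"]
            m = (d > last_u) & (d <= cu - rs * math.cos(a1))
            z[m] = cz + np.sqrt(np.maximum(rs * rs - (cu - d[m]) ** 2, 0.0))
            last_u = cu - rs * math.cos(a1)
        z[d > p["u_full"]] = h2
        out = 2.0 * np.minimum(z, h2)
        out[d <= 0] = 0.0
        return float(out[0]) if scalar else out


@dataclass(frozen=True)
class LeafSpec:
    """One leaf's geometry and material (lengths in mm, density g/cm^3)."""

    leaf_type: str  # full | half | outboard
    width_at_iso: float
    physical_height: float
    tip_radius: float
    tip_central_angle_deg: float = 90.0
    tip_flat_length: float = 0.0
    tip_side_arc_radius: float = 0.0
    tip_side_arc_angle_deg: float = 0.0
    tongue_width: float = 0.0
    groove_width: float = 0.0
    material: str = "tungsten_alloy"
    density: float = 18.0

    def __post_init__(self):
        if self.leaf_type not in ("full", "half", "outboard"):
            raise MachineConfigError(f"unknown leaf type {self.leaf_type!r}")
        if self.width_at_iso <= 0 or self.physical_height <= 0:
            raise MachineConfigError("leaf dimensions must be positive")

    def tip_profile(self) -> TipProfile:
        return TipProfile(
            height=self.physical_height,
            central_radius=self.tip_radius,
            central_angle_deg=self.tip_central_angle_deg,
            flat_length=self.tip_flat_length,
            side_arc_radius=self.tip_side_arc_radius,
            side_arc_angle_deg=self.tip_side_arc_angle_deg,
        )


@dataclass
class MLCBank:
    """60 mirrored leaf pairs ordered inferior -> superior along Y."""

    pairs: list[LeafSpec]
    source_to_mlc_distance: float
    sad: float
    collimator_angle: float = 0.0
    interleaf_band_width: float = 0.3
    interleaf_path_fraction: float = 0.78

    def __post_init__(self):
        if len(self.pairs) != N_PAIRS:
            raise MachineConfigError(f"expected {N_PAIRS} leaf pairs, got {len(self.pairs)}")
        if not (self.sad > self.source_to_mlc_distance > 0):
            raise MachineConfigError("need sad > source_to_mlc_distance > 0")
        widths = np.array([p.width_at_iso for p in self.pairs])
        edges = np.concatenate([[0.0], np.cumsum(widths)])
        self.boundaries = edges - edges[-1] / 2.0  # 61 values, iso mm

    @property
    def y_extent(self) -> float:
        return float(self.boundaries[-1] - self.boundaries[0])

    @property
    def magnification(self) -> float:
        """Iso-plane -> MLC-plane scale factor (source_to_mlc / SAD)."""
        return self.source_to_mlc_distance / self.sad


def default_leaf_pairs(
    physical_height: float = 67.0,
    tip_radius: float = 80.0,
    tip_central_angle_deg: float = 18.0,
    tip_flat_length: float = 6.0,
    tip_side_arc_radius: float = 12.0,
    tip_side_arc_angle_deg: float = 45.0,
    density: float = 18.0,
    material: str = "tungsten_alloy",
) -> list[LeafSpec]:
    """Millennium-120 arrangement: 10 outboard+half, 40 full, 10 half+outboard."""

    def spec(leaf_type, width):
        return LeafSpec(
            leaf_type=leaf_type, width_at_iso=width,
            physical_height=physical_height, tip_radius=tip_radius,
            tip_central_angle_deg=tip_central_angle_deg,
            tip_flat_length=tip_flat_length,
            tip_side_arc_radius=tip_side_arc_radius,
            tip_side_arc_angle_deg=tip_side_arc_angle_deg,
            tongue_width=0.4, groove_width=0.4,
            material=material, density=density,
        )

    outer = [spec("outboard" if i == 0 else "half", 10.0) for i in range(10)]
    inner = [spec("full", 5.0) for _ in range(40)]
    tail = [spec("half" if i < 9 else "outboard", 10.0) for i in range(10)]
    return outer + inner + tail


def project_leaf_positions(iso_positions, bank: MLCBank):
    """Project isocenter-plane leaf positions to the physical MLC plane.

    Pure similar-triangles scaling by source_to_mlc / SAD; exact inverse
    is :func:`unproject_leaf_positions`.
    """
    return np.asarray(iso_positions, dtype=float) * bank.magnification


def unproject_leaf_positions(physical_positions, bank: MLCBank):
    return np.asarray(physical_positions, dtype=float) / bank.magnification


def tip_thickness_profile(depth_behind_tip, spec: LeafSpec):
    """Tungsten path length [mm] along the beam axis behind a leaf tip."""
    return spec.tip_profile().thickness(depth_behind_tip)


@dataclass
class Jaws:
    """Jaw opening at isocenter scale: (x1, x2, y1, y2) mm."""

    x1: float
    x2: float
    y1: float
    y2: float

    def __post_init__(self):
        if self.x1 > self.x2 or self.y1 > self.y2:
            raise MachineConfigError("jaw intervals must be ordered (x1<=x2, y1<=y2)")

    @staticmethod
    def square(half_side_mm: float) -> "Jaws":
        s = float(half_side_mm)
        return Jaws(-s, s, -s, s)


@dataclass
class MachineProfile:
    """Complete collimation geometry + materials for one linac profile."""

    name: str
    bank: MLCBank
    mlc_material: Material
    jaw_material: Material
    x_jaw_z: float = 406.0
    x_jaw_thickness: float = 78.0
    y_jaw_z: float = 319.0
    y_jaw_thickness: float = 78.0

    def __post_init__(self):
        self._mlc_atten = AttenuationTable(self.mlc_material)
        self._jaw_atten = AttenuationTable(self.jaw_material)
        types: dict[tuple, TipProfile] = {}
        self._pair_profile_key = []
        for p in self.bank.pairs:
            key = (p.leaf_type, p.tip_radius, p.tip_central_angle_deg,
                   p.tip_flat_length, p.tip_side_arc_radius,
                   p.tip_side_arc_angle_deg, p.physical_height)
            types.setdefault(key, p.tip_profile())
            self._pair_profile_key.append(key)
        self._profiles = types

    # -- aperture geometry -------------------------------------------------
    def mlc_path_mm(self, x_iso, y_iso, leaf_iso_positions):
        """Tungsten path [mm, normal incidence] through the MLC for points
        given in iso-projected transverse coordinates."""
        x = np.asarray(x_iso, dtype=float)
        y = np.asarray(y_iso, dtype=float)
        leaf = np.asarray(leaf_iso_positions, dtype=float)
        if leaf.shape != (N_LEAVES,):
            raise MachineConfigError(f"expected {N_LEAVES} leaf positions")
        bnd = self.bank.boundaries
        pair = np.clip(np.searchsorted(bnd, y, side="right") - 1, 0, N_PAIRS - 1)
        inside_bank = (y >= bnd[0]) & (y <= bnd[-1])
        mag = self.bank.magnification
        tip_a = leaf[pair]
        tip_b = leaf[N_PAIRS + pair]
        depth_a = (tip_a - x) * mag  # physical mm behind bank-A tip
        depth_b = (x - tip_b) * mag

        path = np.zeros_like(x)
        keys = np.array([self._profiles_index(k) for k in self._pair_profile_key])
        pair_key = keys[pair]
        for idx, prof in enumerate(self._profiles.values()):
            m = (pair_key == idx) & inside_bank
            if not np.any(m):
                continue
            path[m] = np.minimum(
                prof.thickness(depth_a[m]) + prof.thickness(depth_b[m]),
                prof.height,
            )
        # interleaf gap / tongue-and-groove: reduced path in a narrow band
        # around each inter-leaf boundary
        band_iso = self.bank.interleaf_band_width / mag / 2.0
        inner = bnd[1:-1]
        j = np.clip(np.searchsorted(inner, y), 0, inner.size - 1)
        d_lo = np.abs(y - inner[np.maximum(j - 1, 0)])
        d_hi = np.abs(y - inner[j])
        near_boundary = np.minimum(d_lo, d_hi) <= band_iso
        path = np.where(near_boundary, path * self.bank.interleaf_path_fraction, path)
        return np.where(inside_bank, path, 0.0)

    def _profiles_index(self, key):
        return list(self._profiles.keys()).index(key)

    def jaw_paths_mm(self, x_iso_at_xjaw, y_iso_at_yjaw, jaws: Jaws):
        """(x-jaw, y-jaw) tungsten paths [mm, normal incidence]."""
        x = np.asarray(x_iso_at_xjaw, dtype=float)
        y = np.asarray(y_iso_at_yjaw, dtype=float)
        px = np.where((x < jaws.x1) | (x > jaws.x2), self.x_jaw_thickness, 0.0)
        py = np.where((y < jaws.y1) | (y > jaws.y2), self.y_jaw_thickness, 0.0)
        return px, py


def ray_transmission(
    origins,
    directions,
    energies,
    machine: MachineProfile,
    jaws: Jaws,
    leaf_iso_positions,
    collimator_angle: float = 0.0,
):
    """Transmission fraction in [0, 1] for source-frame rays.

    Rays originate near the source plane (z=0) and travel toward +z
    (the isocenter is at z=SAD).  Transmission is exp(-sum mu_i l_i)
    over the traversed jaw and MLC segments; 1 through an open aperture.
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    e = np.atleast_1d(np.asarray(energies, dtype=float))
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    if np.any(d[:, 2] <= 0):
        raise ValueError("rays must travel toward +z (the patient)")
    sad = machine.bank.sad

    def iso_coords_at(z_plane):
        t = (z_plane - o[:, 2]) / d[:, 2]
        x = o[:, 0] + d[:, 0] * t
        y = o[:, 1] + d[:, 1] * t
        s = sad / z_plane
        return x * s, y * s

    if collimator_angle:
        c, s = math.cos(math.radians(collimator_angle)), math.sin(
            math.radians(collimator_angle))
    else:
        c, s = 1.0, 0.0

    def rotate(x, y):
        if collimator_angle:
            return c * x + s * y, -s * x + c * y
        return x, y

    # MLC evaluated at its upstream-face distance (the projection reference)
    xm, ym = iso_coords_at(machine.bank.source_to_mlc_distance)
    xm, ym = rotate(xm, ym)
    mlc_path = machine.mlc_path_mm(xm, ym, leaf_iso_positions)

    xj, yj_unused = iso_coords_at(machine.x_jaw_z)
    xj, _ = rotate(xj, yj_unused)
    xu, yu = iso_coords_at(machine.y_jaw_z)
    _, yjaw = rotate(xu, yu)
    px, py = machine.jaw_paths_mm(xj, yjaw, jaws)

    obliq = 1.0 / d[:, 2]
    mu_mlc = machine._mlc_atten.linear_attenuation(e)   # 1/cm
    mu_jaw = machine._jaw_atten.linear_attenuation(e)
    tau = (mu_mlc * mlc_path + mu_jaw * (px + py)) * obliq / 10.0
    out = np.exp(-tau)
    return out if np.ndim(origins) > 1 else float(out[0])


@dataclass
class LeafPairDistanceMap:
    """Tip-gap matrix [n_control_points x 60] at isocenter scale [mm]."""

    distances: np.ndarray
    threshold: float
    in_field: np.ndarray  # bool, same shape
    ratio: float

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if np.any(self.distances < -1e-9):
            raise ValueError("leaf pairs may not interdigitate past each other")


def leaf_pair_distance_stats(plan, threshold: float = 10.0) -> LeafPairDistanceMap:
    """Leaf-pair tip distances per control point and the short-gap ratio.

    The ratio counts entries with distance < ``threshold`` among pairs
    inside the jaw-defined field: the pair's width interval overlaps the
    jaw Y opening and its tip-gap interval lies across the jaw X
    opening (a pair parked closed under a jaw does not count).
    """
    widths = None
    rows, infield = [], []
    from .machine import load_machine_profile  # default pair widths
    for beam in plan.beams:
        for cp in beam.control_points:
            leaf = np.asarray(cp.leaf_positions, dtype=float)
            a, b = leaf[:N_PAIRS], leaf[N_PAIRS:]
            rows.append(b - a)
            x1, x2, y1, y2 = cp.jaw_positions
            if widths is None:
                bank = load_machine_profile().bank
                widths = bank.boundaries
            y_lo, y_hi = widths[:-1], widths[1:]
            over_y = (y_hi > y1) & (y_lo < y2)
            over_x = (b >= x1) & (a <= x2)
            infield.append(over_y & over_x)
    distances = np.vstack(rows)
    in_field = np.vstack(infield)
    if in_field.any():
        ratio = float(np.mean(distances[in_field] < threshold))
    else:
        ratio = 0.0
    return LeafPairDistanceMap(distances=distances, threshold=threshold,
                               in_field=in_field, ratio=ratio)
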