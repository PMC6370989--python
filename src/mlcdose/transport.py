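"""Desk-scale photon transport in a voxel phantom.

The linac head is replaced by a parameterized point-like photon source:
a tabulated 6 MV spectrum, a Gaussian focal spot, and uniform energy
fluence across the isocenter-plane sampling window (the flattened-beam
idealization).  Photons are collimated by the jaw + MLC transmission
model (attenuation becomes statistical weight, a standard variance
reduction), then transported through the voxel phantom with Woodcock
(delta) tracking:

* incoherent scattering — exact Klein–Nishina sampling via Kahn's
  rejection method, the recoil-electron energy deposited on the spot,
* photoelectric absorption — full local deposition,
* pair production above 1.022 MeV — kinetic energy deposited locally,
  annihilation photons re-emitted at 0.511 MeV.

Charged particles are not tracked (collision-kerma approximation); an
optional lateral spread kernel, sized from the CSDA range of the mean
Compton-electron energy, restores the dominant effect of secondary
electron transport on sub-centimetre dose structures.  Per-voxel
statistical uncertainty comes from batch variance.  All randomness runs
through counter-based Philox streams keyed by (seed, batch, control
point, chunk), so a fixed seed reproduces the dose grid bit for bit
regardless of chunking order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import delivery
from .materials import VoxelPhantom
from .mlc import Jaws, MachineProfile, ray_transmission
from .rt_io import ControlPoint, DoseGrid, TreatmentPlan
from .xsec import (MEC2_MEV, MEV_PER_GRAM_TO_GY, PAIR_THRESHOLD_MEV,
                   AttenuationTable, EnergyRangeError)

_PHSP_MAGIC = b"MLCPHSP1"

# electron CSDA range in water, (kinetic energy MeV -> g/cm^2);
# standard range data, log-log interpolated
_CSDA_E = np.array([0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0, 1.5, 2.0, 3.0,
                    4.0, 5.0, 6.0])
_CSDA_R = np.array([0.00431, 0.0143, 0.0449, 0.0842, 0.1766, 0.2740,
                    0.4367, 0.7075, 0.9785, 1.514,
                    2.037, 2.550, 3.052])


def csda_range_water(energy_mev) -> np.ndarray:
    """CSDA range [g/cm^2] of electrons in water (log-log interpolation)."""
    e = np.clip(np.asarray(energy_mev, dtype=float), _CSDA_E[0], _CSDA_E[-1])
    return np.exp(np.interp(np.log(e), np.log(_CSDA_E), np.log(_CSDA_R)))


@dataclass
class SourceModel:
    """Point-like bremsstrahlung source at the target position.

    ``spectrum_energies``/``spectrum_probabilities`` tabulate the photon
    line spectrum; ``focal_spot_sigma`` is the Gaussian source size in
    mm.  ``commissioning_metadata`` carries the electron-beam tuning
    parameters of the machine this spectrum stands in for — they are
    informational only (the head itself is not simulated).
    """

    spectrum_energies: np.ndarray
    spectrum_probabilities: np.ndarray
    focal_spot_sigma: float = 1.06
    commissioning_metadata: dict = field(default_factory=lambda: {
        "electron_mean_energy_mev": 5.9,
        "electron_energy_sigma_mev": 0.83,
        "electron_radial_sigma_mm": 1.06,
    })

    def __post_init__(self):
        e = np.asarray(self.spectrum_energies, dtype=float)
        p = np.asarray(self.spectrum_probabilities, dtype=float)
        if e.shape != p.shape or e.ndim != 1 or e.size == 0:
            raise ValueError("spectrum must be parallel 1-D energy/probability arrays")
        if np.any(e <= 0) or np.any(p < 0):
            raise ValueError("spectrum energies must be positive, weights non-negative")
        total = p.sum()
        if total <= 0:
            raise ValueError("spectrum has zero total probability")
        self.spectrum_energies = e
        self.spectrum_probabilities = p / total
        self._cdf = np.cumsum(self.spectrum_probabilities)

    @staticmethod
    def default_6mv(focal_spot_sigma: float = 1.06) -> "SourceModel":
        ref = resources.files("mlcdose.data") / "spectrum_6mv.txt"
        rows = [ln.split() for ln in ref.read_text().splitlines()
                if ln.strip() and not ln.startswith("#")]
        e = np.array([float(r[0]) for r in rows])
        p = np.array([float(r[1]) for r in rows])
        return SourceModel(e, p, focal_spot_sigma=focal_spot_sigma)

    @staticmethod
    def monoenergetic(energy_mev: float, focal_spot_sigma: float = 0.0) -> "SourceModel":
        return SourceModel(np.array([energy_mev]), np.array([1.0]),
                           focal_spot_sigma=focal_spot_sigma)

    @property
    def max_energy(self) -> float:
        return float(self.spectrum_energies.max())

    def mean_energy(self) -> float:
        return float(self.spectrum_energies @ self.spectrum_probabilities)

    def sample_energies(self, rng, n: int) -> np.ndarray:
        idx = np.searchsorted(self._cdf, rng.random(n))
        return self.spectrum_energies[np.minimum(idx, self._cdf.size - 1)]

    def mean_compton_electron_energy(self) -> float:
        """Fluence- and cross-section-weighted mean recoil-electron energy
        in water, used to size the electron spread kernel."""
        from .xsec import WATER
        t = _water_table()
        e = self.spectrum_energies
        sigma = t._interp(e, t.mu_compton)
        f_tr = np.interp(np.log(e), t._log_e, t.compton_transfer)
        w = self.spectrum_probabilities * sigma
        return float((w * f_tr * e).sum() / w.sum())


_WATER_TABLE = None


def _water_table() -> AttenuationTable:
    global _WATER_TABLE
    if _WATER_TABLE is None:
        from .xsec import WATER
        _WATER_TABLE = AttenuationTable(WATER)
    return _WATER_TABLE


@dataclass
class TransportSettings:
    n_histories: int = 1_000_000
    seed: int = 0
    energy_cutoff: float = 0.05
    mode: str = "mc_full"  # mc_full | raytrace_primary
    batch_count: int = 10
    follow_scatter: bool = True
    enable_pair: bool = True
    electron_spread: str | float = "auto"  # "auto" | "off" | sigma in mm
    field_margin_mm: float = 10.0
    chunk_size: int = 400_000

    def __post_init__(self):
        if self.n_histories <= 0:
            raise ValueError("n_histories must be positive")
        if self.mode not in ("mc_full", "raytrace_primary"):
            raise ValueError(f"unknown transport mode {self.mode!r}")
        if self.batch_count < 2:
            raise ValueError("batch_count must be >= 2 for uncertainty estimates")
        if not 0.01 <= self.energy_cutoff <= 10.0:
            raise ValueError("energy cutoff outside cross-section table range")


# --------------------------------------------------------------------------
# phase space
# --------------------------------------------------------------------------

PHSP_DTYPE = np.dtype([("energy", "<f8"), ("x", "<f8"), ("y", "<f8"),
                       ("u", "<f8"), ("v", "<f8"), ("w", "<f8"),
                       ("weight", "<f8")])


class PhaseSpaceError(ValueError):
    pass


def make_phase_space(energy, x, y, u, v, w, weight) -> np.ndarray:
    rec = np.zeros(len(np.atleast_1d(energy)), dtype=PHSP_DTYPE)
    rec["energy"], rec["x"], rec["y"] = energy, x, y
    rec["u"], rec["v"], rec["w"], rec["weight"] = u, v, w, weight
    norm = np.sqrt(rec["u"] ** 2 + rec["v"] ** 2 + rec["w"] ** 2)
    if np.any(np.abs(norm - 1.0) > 1e-9):
        raise PhaseSpaceError("direction cosines must be unit vectors")
    if np.any(rec["weight"] <= 0):
        raise PhaseSpaceError("statistical weights must be positive")
    return rec


def write_phase_space(records: np.ndarray, path: str | Path,
                      plane_z: float) -> None:
    """Binary phase-space file: 8-byte magic, record count (int64),
    plane z [mm] (float64), then (energy,x,y,u,v,w,weight) float64 LE."""
    with open(path, "wb") as fh:
        fh.write(_PHSP_MAGIC)
        fh.write(np.int64(len(records)).tobytes())
        fh.write(np.float64(plane_z).tobytes())
        fh.write(np.ascontiguousarray(records.astype(PHSP_DTYPE)).tobytes())


def read_phase_space(path: str | Path) -> tuple[np.ndarray, float]:
    raw = Path(path).read_bytes()
    if len(raw) < 24 or raw[:8] != _PHSP_MAGIC:
        raise PhaseSpaceError(f"{path}: not a phase-space file")
    count = int(np.frombuffer(raw, "<i8", count=1, offset=8)[0])
    plane_z = float(np.frombuffer(raw, "<f8", count=1, offset=16)[0])
    body = raw[24:]
    if len(body) != count * PHSP_DTYPE.itemsize:
        raise PhaseSpaceError(f"{path}: truncated phase-space file "
                              f"({len(body)} payload bytes for {count} records)")
    return np.frombuffer(body, PHSP_DTYPE).copy(), plane_z


def phsp_roundtrip(records: np.ndarray, path: str | Path,
                   plane_z: float = 500.0) -> np.ndarray:
    """Write then read back a record list (identity at stored precision)."""
    write_phase_space(records, path, plane_z)
    out, _ = read_phase_space(path)
    return out


def replay_records(records: np.ndarray, reuse_factor: int) -> np.ndarray:
    """Replay a phase space ``reuse_factor`` times (downstream randomness
    stays independent because RNG streams are keyed per chunk)."""
    if reuse_factor < 1:
        raise ValueError("reuse factor must be >= 1")
    return np.tile(records, reuse_factor)


# --------------------------------------------------------------------------
# source sampling
# --------------------------------------------------------------------------

def _rng_for(seed: int, *stream) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                spawn_key=tuple(int(s) for s in stream))
    return np.random.Generator(np.random.Philox(ss))


def sample_rays(model: SourceModel, rng, n: int, rect, sad: float):
    """Sample beam-frame rays: origins near z=0 (focal spot), directions
    toward points uniform in ``rect=(x1,x2,y1,y2)`` at the iso plane."""
    e = model.sample_energies(rng, n)
    ox = rng.normal(0.0, model.focal_spot_sigma, n) if model.focal_spot_sigma > 0 \
        else np.zeros(n)
    oy = rng.normal(0.0, model.focal_spot_sigma, n) if model.focal_spot_sigma > 0 \
        else np.zeros(n)
    x1, x2, y1, y2 = rect
    ax = rng.uniform(x1, x2, n)
    ay = rng.uniform(y1, y2, n)
    d = np.column_stack([ax - ox, ay - oy, np.full(n, sad)])
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    o = np.column_stack([ox, oy, np.zeros(n)])
    return o, d, e, np.ones(n)


def sample_source(model: SourceModel, rng, n: int, machine: MachineProfile,
                  rect=None) -> np.ndarray:
    """Sample source photons, recorded on the plane just upstream of the MLC."""
    sad = machine.bank.sad
    if rect is None:
        half = 200.0
        rect = (-half, half, -half, half)
    plane_z = machine.bank.source_to_mlc_distance - 1.0
    o, d, e, w = sample_rays(model, rng, n, rect, sad)
    t = (plane_z - o[:, 2]) / d[:, 2]
    x = o[:, 0] + d[:, 0] * t
    y = o[:, 1] + d[:, 1] * t
    return make_phase_space(e, x, y, d[:, 0], d[:, 1], d[:, 2], w)


# --------------------------------------------------------------------------
# collimator transmission map
# --------------------------------------------------------------------------

@dataclass
class TransmissionMap:
    values: np.ndarray  # [ny, nx]
    x: np.ndarray  # iso-plane mm
    y: np.ndarray


def collimator_transmission_map(aperture: ControlPoint, machine: MachineProfile,
                                resolution: float = 1.0,
                                energy: float | None = None,
                                margin: float = 10.0) -> TransmissionMap:
    """Point-source transmission map of one aperture on the iso plane."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if energy is None:
        energy = SourceModel.default_6mv().mean_energy()
    x1, x2, y1, y2 = aperture.jaw_positions
    xs = np.arange(x1 - margin, x2 + margin + resolution / 2, resolution)
    ys = np.arange(y1 - margin, y2 + margin + resolution / 2, resolution)
    gx, gy = np.meshgrid(xs, ys)
    sad = machine.bank.sad
    d = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, sad)])
    o = np.zeros_like(d)
    t = ray_transmission(o, d, np.full(gx.size, energy), machine,
                         Jaws(*aperture.jaw_positions), aperture.leaf_positions,
                         collimator_angle=aperture.collimator_angle)
    return TransmissionMap(values=t.reshape(gy.shape), x=xs, y=ys)


# --------------------------------------------------------------------------
# phantom transport
# --------------------------------------------------------------------------

class _PhantomTables:
    """Per-material attenuation tables + Woodcock majorant for a phantom."""

    def __init__(self, phantom: VoxelPhantom):
        self.phantom = phantom
        self.mats_present = np.unique(phantom.material_index)
        self.tables = {}
        self.rho_max = {}
        for m in self.mats_present:
            mat = phantom.materials[int(m)]
            self.tables[int(m)] = AttenuationTable(mat)
            sel = phantom.material_index == m
            self.rho_max[int(m)] = float(phantom.density[sel].max())
        t0 = self.tables[int(self.mats_present[0])]
        self._grid_e = t0.energies
        self._log_e = np.log(self._grid_e)
        maj = np.zeros_like(self._grid_e)
        for m in self.mats_present:
            maj = np.maximum(maj, self.tables[int(m)].mu_total * self.rho_max[int(m)])
        self._maj = np.maximum(maj, 1e-12)
        self._log_maj = np.log(self._maj)

    def majorant(self, e):
        return np.exp(np.interp(np.log(e), self._log_e, self._log_maj))

    def mu_total_voxel(self, e, mat_idx, rho):
        mu = np.zeros_like(e)
        for m in self.mats_present:
            sel = mat_idx == m
            if np.any(sel):
                mu[sel] = self.tables[int(m)].mass_attenuation(e[sel]) * rho[sel]
        return mu

    def channel_mu_voxel(self, e, mat_idx, rho):
        c = np.zeros_like(e)
        p = np.zeros_like(e)
        pp = np.zeros_like(e)
        ft = np.zeros_like(e)
        for m in self.mats_present:
            sel = mat_idx == m
            if np.any(sel):
                t = self.tables[int(m)]
                cc, pc, ppc = t.channel_mass_attenuation(e[sel])
                c[sel] = cc * rho[sel]
                p[sel] = pc * rho[sel]
                pp[sel] = ppc * rho[sel]
                ft[sel] = np.interp(np.log(e[sel]), t._log_e, t.compton_transfer)
        return c, p, pp, ft

    def mu_transfer_voxel(self, e, mat_idx, rho):
        mu = np.zeros_like(e)
        for m in self.mats_present:
            sel = mat_idx == m
            if np.any(sel):
                mu[sel] = self.tables[int(m)].mass_energy_transfer(e[sel]) * rho[sel]
        return mu


def _aabb_entry(o, d, lo, hi):
    """Parametric entry/exit distances of rays into an axis box (mm)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - o) / d
        t2 = (hi[None, :] - o) / d
    tmin = np.minimum(t1, t2)
    tmax = np.maximum(t1, t2)
    tmin = np.where(np.isfinite(tmin), tmin, -np.inf)
    tmax = np.where(np.isfinite(tmax), tmax, np.inf)
    # rays parallel to an axis but outside the slab never enter
    par = d == 0
    out = (o < lo[None, :]) | (o > hi[None, :])
    bad = np.any(par & out, axis=1)
    t_enter = np.max(tmin, axis=1)
    t_exit = np.min(tmax, axis=1)
    t_enter = np.where(bad, np.inf, t_enter)
    return t_enter, t_exit


def _sample_kahn(rng, e_mev):
    """Klein–Nishina sampling (Kahn's rejection): returns (e_out, cos_theta)."""
    k = e_mev / MEC2_MEV
    n = k.size
    x = np.empty(n)  # E/E' ratio
    todo = np.ones(n, dtype=bool)
    while np.any(todo):
        idx = np.nonzero(todo)[0]
        kk = k[idx]
        r1 = rng.random(idx.size)
        r2 = rng.random(idx.size)
        r3 = rng.random(idx.size)
        branch = r1 <= (1.0 + 2.0 * kk) / (9.0 + 2.0 * kk)
        xx = np.where(branch, 1.0 + 2.0 * kk * r2,
                      (1.0 + 2.0 * kk) / (1.0 + 2.0 * kk * r2))
        t = 1.0 - (xx - 1.0) / kk
        acc_a = r3 <= 4.0 * (1.0 / xx - 1.0 / xx**2)
        acc_b = r3 <= 0.5 * (t**2 + 1.0 / xx)
        accept = np.where(branch, acc_a, acc_b)
        x[idx[accept]] = xx[accept]
        todo[idx[accept]] = False
    cos_t = 1.0 - (x - 1.0) / k
    return e_mev / x, np.clip(cos_t, -1.0, 1.0)


def _rotate_directions(d, cos_t, rng):
    """Rotate unit vectors by polar angle acos(cos_t), uniform azimuth."""
    n = d.shape[0]
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    # orthonormal frame around each direction
    dz = d[:, 2]
    small = np.abs(dz) > 0.99999
    a = np.where(small[:, None], np.array([1.0, 0.0, 0.0])[None, :],
                 np.array([0.0, 0.0, 1.0])[None, :])
    u = np.cross(a, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (d * cos_t[:, None]
           + u * (sin_t * np.cos(phi))[:, None]
           + v * (sin_t * np.sin(phi))[:, None])
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _transport_chunk_mc(o, d, e, w, tables: _PhantomTables, settings,
                        rng, dep_flat):
    """Analog (Woodcock) transport of one photon chunk; deposits MeV*weight."""
    ph = tables.phantom
    nz, ny, nx = ph.shape
    dx, dy, dz = ph.spacing
    lo = np.array(ph.origin) - np.array([dx, dy, dz]) / 2.0
    hi = lo + np.array([nx * dx, ny * dy, nz * dz])
    mat_flat = ph.material_index.ravel()
    rho_flat = np.asarray(ph.density, dtype=float).ravel()
    cutoff = settings.energy_cutoff

    t_enter, t_exit = _aabb_entry(o, d, lo, hi)
    hit = (t_enter < t_exit) & (t_exit > 0)
    o = o[hit] + d[hit] * np.maximum(t_enter[hit], 0.0)[:, None] * (1 + 1e-12)
    d, e, w = d[hit], e[hit], w[hit]

    for _ in range(10_000):
        if e.size == 0:
            break
        maj = tables.majorant(e)  # 1/cm
        step_mm = -np.log(rng.random(e.size)) / maj * 10.0
        o = o + d * step_mm[:, None]
        ij = np.floor((o - lo[None, :]) / np.array([dx, dy, dz])[None, :]).astype(np.int64)
        inside = ((ij[:, 0] >= 0) & (ij[:, 0] < nx) & (ij[:, 1] >= 0)
                  & (ij[:, 1] < ny) & (ij[:, 2] >= 0) & (ij[:, 2] < nz))
        o, d, e, w, ij, maj = o[inside], d[inside], e[inside], w[inside], \
            ij[inside], maj[inside]
        if e.size == 0:
            break
        flat = (ij[:, 2] * ny + ij[:, 1]) * nx + ij[:, 0]
        mat_i = mat_flat[flat]
        rho_i = rho_flat[flat]
        mu_real = tables.mu_total_voxel(e, mat_i, rho_i)
        interact = rng.random(e.size) < mu_real / maj
        if np.any(interact):
            ii = np.nonzero(interact)[0]
            ei, wi, flati = e[ii], w[ii], flat[ii]
            c, p, pp, ftr = tables.channel_mu_voxel(ei, mat_i[ii], rho_i[ii])
            del ftr
            tot = c + p + pp
            u = rng.random(ii.size) * tot
            is_pe = u < p
            is_pair = (~is_pe) & (u < p + pp) & (ei > PAIR_THRESHOLD_MEV)
            is_compton = ~(is_pe | is_pair)

            # photoelectric: full absorption
            if np.any(is_pe):
                np.add.at(dep_flat, flati[is_pe], ei[is_pe] * wi[is_pe])
                e[ii[is_pe]] = 0.0
            # pair production: kinetic energy local, annihilation photons on
            if np.any(is_pair):
                sel = ii[is_pair]
                np.add.at(dep_flat, flati[is_pair],
                          (ei[is_pair] - PAIR_THRESHOLD_MEV) * wi[is_pair])
                if settings.follow_scatter and settings.enable_pair:
                    # two back-to-back 511 keV photons carried as one
                    # isotropic photon of double weight
                    e[sel] = MEC2_MEV
                    w[sel] = w[sel] * 2.0
                    cos_iso = rng.uniform(-1.0, 1.0, sel.size)
                    d[sel] = _rotate_directions(d[sel], cos_iso, rng)
                else:
                    np.add.at(dep_flat, flati[is_pair],
                              PAIR_THRESHOLD_MEV * wi[is_pair])
                    e[sel] = 0.0
            # Compton: deposit recoil energy, follow the scattered photon
            if np.any(is_compton):
                sel = ii[is_compton]
                e_new, cos_t = _sample_kahn(rng, e[sel])
                np.add.at(dep_flat, flati[is_compton],
                          (e[sel] - e_new) * w[sel])
                if settings.follow_scatter:
                    d[sel] = _rotate_directions(d[sel], cos_t, rng)
                    e[sel] = e_new
                else:
                    e[sel] = 0.0
            # cutoff: absorb locally
            low = interact & (e <= cutoff) & (e > 0)
            if np.any(low):
                np.add.at(dep_flat, flat[low], e[low] * w[low])
            kill = interact & (e <= cutoff)
            keep = ~kill
            o, d, e, w = o[keep], d[keep], e[keep], w[keep]


def _transport_chunk_primary(o, d, e, w, tables: _PhantomTables, dep_flat):
    """Primary-only collision-kerma ray trace (Siddon-style exact paths)."""
    ph = tables.phantom
    nz, ny, nx = ph.shape
    dx, dy, dz = ph.spacing
    spac = np.array([dx, dy, dz])
    lo = np.array(ph.origin) - spac / 2.0
    hi = lo + spac * np.array([nx, ny, nz])
    mat_flat = ph.material_index.ravel()
    rho_flat = np.asarray(ph.density, dtype=float).ravel()

    t_enter, t_exit = _aabb_entry(o, d, lo, hi)
    hit = (t_enter < t_exit) & (t_exit > 0)
    o, d, e, w = o[hit], d[hit], e[hit], w[hit]
    t = np.maximum(t_enter[hit], 0.0)
    t_end = t_exit[hit]
    atten = np.ones(e.size)  # cumulative exp(-tau)

    alive = np.ones(e.size, dtype=bool)
    for _ in range(nx + ny + nz + 4):
        if not np.any(alive):
            break
        pos = o + d * t[:, None]
        with np.errstate(divide="ignore"):
            idx_f = (pos - lo[None, :]) / spac[None, :]
            ij = np.clip(np.floor(idx_f + 1e-9 * np.sign(d)).astype(np.int64),
                         0, np.array([nx, ny, nz]) - 1)
            nxt = np.where(d > 0, (ij + 1) * spac[None, :] + lo[None, :],
                           ij * spac[None, :] + lo[None, :])
            t_step = np.where(d != 0, (nxt - o) / d, np.inf)
        t_next = np.minimum(np.min(t_step, axis=1), t_end)
        seg_mm = np.maximum(t_next - t, 0.0)
        use = alive & (seg_mm > 1e-12)
        if np.any(use):
            flat = (ij[use, 2] * ny + ij[use, 1]) * nx + ij[use, 0]
            mat_i = mat_flat[flat]
            rho_i = rho_flat[flat]
            mu = tables.mu_total_voxel(e[use], mat_i, rho_i)
            mu_tr = tables.mu_transfer_voxel(e[use], mat_i, rho_i)
            tau = mu * seg_mm[use] / 10.0
            frac = np.where(mu > 0, mu_tr / np.maximum(mu, 1e-30), 0.0)
            dE = e[use] * w[use] * atten[use] * (1.0 - np.exp(-tau)) * frac
            np.add.at(dep_flat, flat, dE)
            atten[use] = atten[use] * np.exp(-tau)
        t = t_next + 1e-9
        alive = alive & (t < t_end)


# --------------------------------------------------------------------------
# the dose engine
# --------------------------------------------------------------------------

@dataclass
class RunInfo:
    histories: int
    emitted_energy_mev: float
    deposited_energy_mev: float
    electron_spread_sigma_mm: float
    per_cp_histories: np.ndarray


def electron_spread_sigma(source: SourceModel) -> float:
    """Lateral secondary-electron spread kernel sigma [mm in water].

    0.4 x CSDA range of the mean Compton recoil energy of the spectrum.
    """
    e_mean = source.mean_compton_electron_energy()
    return 0.4 * float(csda_range_water(e_mean)) * 10.0


def simulate_dose(plan: TreatmentPlan, phantom: VoxelPhantom,
                  source: SourceModel, settings: TransportSettings,
                  machine: MachineProfile) -> DoseGrid:
    """Recompute the dose of a plan on a voxel phantom.

    Histories are allocated to control points by the delivery weights,
    collimated by the jaw+MLC transmission model, and transported in
    the phantom.  Output is raw engine dose in Gy-per-run units (use
    :func:`mlcdose.delivery.dose_scaling` with a calibrated DSF for
    absolute Gy); ``.run_info`` on the result carries the energy
    bookkeeping.  Identical (plan, phantom, seed, settings) give a
    bit-identical grid.
    """
    plan.validate()
    if settings.energy_cutoff >= source.max_energy:
        raise ValueError("energy cutoff is above the spectrum maximum")
    weights = delivery.control_point_weights(plan)
    tables = _PhantomTables(phantom)
    sad = machine.bank.sad

    cps = [(b, cp) for b in plan.beams for cp in b.control_points]
    nz, ny, nx = phantom.shape
    dep_sum = np.zeros(nz * ny * nx)
    dep_sq = np.zeros(nz * ny * nx)
    emitted = 0.0
    total_alloc = np.zeros(len(cps), dtype=np.int64)

    sigma_mm = 0.0
    if settings.electron_spread == "auto":
        sigma_mm = electron_spread_sigma(source)
    elif settings.electron_spread not in ("off", None):
        sigma_mm = float(settings.electron_spread)
    sigma_vox = (np.array([phantom.spacing[2], phantom.spacing[1],
                           phantom.spacing[0]]) ** -1) * sigma_mm

    per_batch = np.full(settings.batch_count,
                        settings.n_histories // settings.batch_count,
                        dtype=np.int64)
    per_batch[: settings.n_histories % settings.batch_count] += 1

    for b_idx in range(settings.batch_count):
        dep = np.zeros(nz * ny * nx)
        alloc = delivery.allocate_histories(weights, int(per_batch[b_idx]))
        total_alloc += alloc
        for cp_idx, ((beam, cp), n_cp) in enumerate(zip(cps, alloc)):
            if n_cp == 0:
                continue
            rot, src_pos = delivery.beam_to_patient_frame(
                cp.gantry_angle, cp.collimator_angle, beam.isocenter, sad)
            x1, x2, y1, y2 = cp.jaw_positions
            m = settings.field_margin_mm
            rect = (x1 - m, x2 + m, y1 - m, y2 + m)
            jaws = Jaws(x1, x2, y1, y2)
            done = 0
            chunk_no = 0
            while done < n_cp:
                n = int(min(settings.chunk_size, n_cp - done))
                rng = _rng_for(settings.seed, b_idx, cp_idx, chunk_no)
                o, d, e, w = sample_rays(source, rng, n, rect, sad)
                emitted += float((e * w).sum())
                # collimator angle is already folded into the beam basis,
                # so the aperture is evaluated unrotated
                w = w * ray_transmission(o, d, e, machine, jaws,
                                         cp.leaf_positions)
                o_pat = src_pos[None, :] + o @ rot.T
                d_pat = d @ rot.T
                if settings.mode == "mc_full":
                    _transport_chunk_mc(o_pat, d_pat, e, w, tables,
                                        settings, rng, dep)
                else:
                    _transport_chunk_primary(o_pat, d_pat, e, w, tables, dep)
                done += n
                chunk_no += 1
        if sigma_mm > 0:
            dep = gaussian_filter(dep.reshape(nz, ny, nx), sigma=sigma_vox,
                                  mode="constant", cval=0.0).ravel()
        dep_sum += dep
        dep_sq += dep * dep

    mass_g = (np.asarray(phantom.density, dtype=float).ravel()
              * phantom.voxel_volume_cm3())
    with np.errstate(divide="ignore", invalid="ignore"):
        dose = np.where(mass_g > 0, dep_sum / mass_g, 0.0) * MEV_PER_GRAM_TO_GY

    nb = settings.batch_count
    mean_b = dep_sum / nb
    var_b = np.maximum(dep_sq / nb - mean_b**2, 0.0) * nb / max(nb - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(dep_sum > 0, np.sqrt(var_b / nb) / np.maximum(mean_b, 1e-300),
                       0.0)

    grid = DoseGrid(dose=dose.reshape(nz, ny, nx),
                    uncertainty=rel.reshape(nz, ny, nx).astype(np.float32),
                    origin=phantom.origin, spacing=phantom.spacing)
    grid.run_info = RunInfo(
        histories=int(total_alloc.sum()),
        emitted_energy_mev=emitted,
        deposited_energy_mev=float(dep_sum.sum()),
        electron_spread_sigma_mm=sigma_mm,
        per_cp_histories=total_alloc,
    )
    return grid
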