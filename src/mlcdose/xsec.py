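"""Photon interaction cross sections for megavoltage transport.

Per-element cross sections are built from standard analytic forms —
exact Klein–Nishina incoherent scattering on free electrons, a
``Z^4.5/E^3`` photoelectric parameterization normalized at a high-Z
reference point, and a ``Z^2``-scaled universal pair-production shape —
then tabulated on a logarithmic energy grid and log-log interpolated.
Coherent (Rayleigh) scattering is neglected, which is the usual
approximation above a few tens of keV where it deflects without
depositing energy.

Macroscopic coefficients are exposed per interaction channel together
with the energy-transfer fraction of each channel, so both analog
Monte Carlo sampling and collision-kerma ray tracing can share one
material description.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# classical electron radius [cm], electron rest energy [MeV], Avogadro
R_E_CM = 2.8179403262e-13
MEC2_MEV = 0.51099895
N_AVOGADRO = 6.02214076e23
# pair production threshold [MeV]
PAIR_THRESHOLD_MEV = 2.0 * MEC2_MEV
# MeV -> J/kg conversion for dose in Gy when mass is in grams
MEV_PER_GRAM_TO_GY = 1.602176634e-10

#: element symbol -> (Z, atomic mass g/mol)
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "Al": (13, 26.982),
    "Si": (14, 28.085), "P": (15, 30.974), "S": (16, 32.06),
    "Cl": (17, 35.45), "Ar": (18, 39.948), "K": (19, 39.098),
    "Ca": (20, 40.078), "Ti": (22, 47.867), "Fe": (26, 55.845),
    "Ni": (28, 58.693), "Cu": (29, 63.546), "W": (74, 183.84),
    "Pb": (82, 207.2),
}

# photoelectric normalization: per-atom tau = C_PE * Z^4.5 * g(E),
# g = E^-3 below 0.5 MeV joining a 1/E tail above; C_PE pinned to the
# photoelectric component of lead at 0.5 MeV.
_C_PE_CM2 = 7.56e-33
_PE_KNEE_MEV = 0.5

# universal pair-production shape f(E) in kappa = alpha*r_e^2 * Z^2 * f(E),
# anchored to water pair attenuation in the 1.5-10 MeV range.
_PAIR_E = np.array([PAIR_THRESHOLD_MEV, 1.25, 1.5, 2.0, 3.0, 4.0,
                    5.0, 6.0, 8.0, 10.0, 20.0])
_PAIR_F = np.array([0.0, 0.03, 0.086, 0.30, 0.72, 1.14,
                    1.50, 1.83, 2.55, 3.20, 5.10])
_ALPHA_RE2_CM2 = R_E_CM ** 2 / 137.035999


class EnergyRangeError(ValueError):
    """Photon energy outside the tabulated cross-section range."""


def klein_nishina_total(energy_mev):
    """Total Klein–Nishina cross section per electron [cm^2].

    Exact closed form for unpolarized photons on free electrons.
    """
    k = np.asarray(energy_mev, dtype=float) / MEC2_MEV
    lg = np.log1p(2.0 * k)
    term1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - lg / k)
    term2 = lg / (2.0 * k)
    term3 = -(1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return 2.0 * np.pi * R_E_CM**2 * (term1 + term2 + term3)


def klein_nishina_mean_scatter_fraction(energy_mev, n_theta: int = 4001):
    """Mean scattered-photon energy fraction <E'>/E under Klein–Nishina.

    Numerically integrates the differential cross section over the
    scattering angle; 1 minus this is the mean fraction transferred to
    the Compton electron (the collision-kerma weight of the incoherent
    channel).
    """
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    k = e[:, None] / MEC2_MEV
    theta = np.linspace(0.0, np.pi, n_theta)[None, :]
    ratio = 1.0 / (1.0 + k * (1.0 - np.cos(theta)))  # E'/E
    dsdo = 0.5 * ratio**2 * (ratio + 1.0 / ratio - np.sin(theta) ** 2)
    w = dsdo * np.sin(theta)
    num = np.trapezoid(w * ratio, theta, axis=1)
    den = np.trapezoid(w, theta, axis=1)
    out = num / den
    return out if np.ndim(energy_mev) else float(out[0])


def photoelectric_atom(energy_mev, z: int):
    """Parameterized per-atom photoelectric cross section [cm^2]."""
    e = np.asarray(energy_mev, dtype=float)
    g = np.where(
        e <= _PE_KNEE_MEV,
        e**-3.0,
        _PE_KNEE_MEV**-3.0 * (_PE_KNEE_MEV / e),
    )
    return _C_PE_CM2 * z**4.5 * g


def pair_atom(energy_mev, z: int):
    """Per-atom nuclear pair-production cross section [cm^2]."""
    e = np.asarray(energy_mev, dtype=float)
    f = np.interp(e, _PAIR_E, _PAIR_F, left=0.0, right=_PAIR_F[-1])
    return _ALPHA_RE2_CM2 * z**2 * f


@dataclass(frozen=True)
class Material:
    """A homogeneous material: name, density [g/cm^3], mass fractions."""

    name: str
    density: float
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.density < 0:
            raise ValueError(f"negative density for material {self.name!r}")
        unknown = set(self.composition) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown elements {sorted(unknown)} in {self.name!r}")
        total = sum(self.composition.values())
        if self.composition and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1"
            )

    @staticmethod
    def normalized(name, density, composition):
        total = sum(composition.values())
        comp = {el: w / total for el, w in composition.items()}
        return Material(name, density, comp)

    def electrons_per_gram(self) -> float:
        return sum(
            w * ELEMENTS[el][0] / ELEMENTS[el][1] * N_AVOGADRO
            for el, w in self.composition.items()
        )


WATER = Material("water", 1.0, {"H": 0.111898, "O": 0.888102})
AIR = Material.normalized(
    "air", 0.00120479, {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827}
)


class AttenuationTable:
    """Log-log tabulated mass attenuation coefficients for one material.

    Channels: incoherent (Compton), photoelectric, pair production.
    All coefficients are mass coefficients [cm^2/g]; multiply by the
    local density for macroscopic values.
    """

    def __init__(self, material: Material, e_min: float = 0.01,
                 e_max: float = 10.0, n: int = 256):
        if not material.composition:
            raise ValueError(f"material {material.name!r} has no composition")
        self.material = material
        self.e_min = float(e_min)
        self.e_max = float(e_max)
        self.energies = np.geomspace(self.e_min, self.e_max, n)
        e = self.energies

        compton = np.zeros_like(e)
        photo = np.zeros_like(e)
        pair = np.zeros_like(e)
        for el, w in material.composition.items():
            z, a = ELEMENTS[el]
            atoms_per_g = w * N_AVOGADRO / a
            compton += atoms_per_g * z * klein_nishina_total(e)
            photo += atoms_per_g * photoelectric_atom(e, z)
            pair += atoms_per_g * pair_atom(e, z)
        self.mu_compton = compton
        self.mu_photo = photo
        self.mu_pair = pair
        self.mu_total = compton + photo + pair
        # mean Compton energy-transfer fraction on the same grid
        self.compton_transfer = 1.0 - klein_nishina_mean_scatter_fraction(e)
        self._log_e = np.log(e)

    def _check(self, energy):
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.e_min) or np.any(e > self.e_max):
            raise EnergyRangeError(
                f"energy outside table range [{self.e_min}, {self.e_max}] MeV"
            )
        return e

    def _interp(self, energy, table):
        e = self._check(energy)
        loge = np.log(e)
        out = np.exp(np.interp(loge, self._log_e, np.log(np.maximum(table, 1e-300))))
        return np.where(out < 1e-290, 0.0, out)

    def mass_attenuation(self, energy):
        """Total mass attenuation coefficient [cm^2/g] (no coherent)."""
        return self._interp(energy, self.mu_total)

    def channel_mass_attenuation(self, energy):
        """(compton, photoelectric, pair) mass coefficients [cm^2/g]."""
        return (self._interp(energy, self.mu_compton),
                self._interp(energy, self.mu_photo),
                self._interp(energy, self.mu_pair))

    def mass_energy_transfer(self, energy):
        """Mass energy-transfer coefficient [cm^2/g] (collision kerma weight)."""
        e = self._check(energy)
        c, p, pp = self.channel_mass_attenuation(e)
        f_c = np.interp(np.log(e), self._log_e, self.compton_transfer)
        f_pp = np.where(e > PAIR_THRESHOLD_MEV,
                        (e - PAIR_THRESHOLD_MEV) / np.maximum(e, 1e-12), 0.0)
        return c * f_c + p + pp * f_pp

    def linear_attenuation(self, energy, density: float | None = None):
        """Linear attenuation coefficient [1/cm] at the given density."""
        rho = self.material.density if density is None else density
        return self.mass_attenuation(energy) * rho
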