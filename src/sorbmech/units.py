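"""Reduced-unit bookkeeping.

The simulator works throughout in dimensionless Lennard-Jones style units:
lengths in units of a characteristic bead diameter ``sigma``, energies in
units of ``epsilon`` and masses in units of a bead mass ``m``.  A single
:class:`UnitSystem` maps those to physical units (nm, kJ/mol, g/mol) for
report tables; nothing inside the dynamics ever touches physical units.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

from . import constants


@dataclass(frozen=True)
class UnitSystem:
    """Conversion between reduced simulation units and physical units.

    Parameters
    ----------
    sigma_nm:
        Physical length of one reduced length unit, in nm.
    epsilon_kj_mol:
        Physical energy of one reduced energy unit, in kJ/mol.
    mass_g_mol:
        Physical mass of one reduced mass unit, in g/mol.
    """

    sigma_nm: float = 0.47
    epsilon_kj_mol: float = 2.5
    mass_g_mol: float = 96.23

    @property
    def time_ps(self) -> float:
        """Physical duration of one reduced time unit, in ps.

        tau = sigma * sqrt(m / epsilon), evaluated in SI and reported in ps.
        """
        sigma_m = self.sigma_nm * 1e-9
        eps_j = self.epsilon_kj_mol * 1000.0 / constants.NA
        mass_kg = self.mass_g_mol * 1e-3 / constants.NA
        return sigma_m * math.sqrt(mass_kg / eps_j) * 1e12

    @property
    def temperature_k(self) -> float:
        """Physical temperature of reduced T = 1, in kelvin."""
        return self.epsilon_kj_mol * 1000.0 / constants.R_GAS

    @property
    def pressure_kpa(self) -> float:
        """Physical pressure of reduced P = 1, in kPa."""
        eps_j = self.epsilon_kj_mol * 1000.0 / constants.NA
        sigma_m = self.sigma_nm * 1e-9
        return eps_j / sigma_m**3 / 1000.0

    def to_dict(self) -> dict:
        return {
            "sigma_nm": self.sigma_nm,
            "epsilon_kj_mol": self.epsilon_kj_mol,
            "mass_g_mol": self.mass_g_mol,
            "time_ps": self.time_ps,
            "temperature_k": self.temperature_k,
            "pressure_kpa": self.pressure_kpa,
        }


def rate_nm_ps_to_cm_s(rate_nm_ps: float) -> float:
    """Convert a pulling rate from nm/ps to cm/s.

    1 nm/ps = 1e-9 m / 1e-12 s = 1000 m/s = 1e5 cm/s, so the deformation
    rate 0.00001 nm/ps used in tensile protocols equals exactly 1.0 cm/s.
    """
    return rate_nm_ps * 1.0e5


def rate_cm_s_to_nm_ps(rate_cm_s: float) -> float:
    """Inverse of :func:`rate_nm_ps_to_cm_s`."""
    return rate_cm_s / 1.0e5
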