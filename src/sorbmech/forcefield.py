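"""Pair and bonded interactions for the coarse model.

Truncated Lennard-Jones non-bonded interactions over species-pair
tables (Lorentz-Berthelot combination of per-species values, with
optional per-pair overrides) plus harmonic bonds.  One particle may be
designated *fractional*: its pair interactions are scaled by a coupling
function f(lambda) and soft-core-regularized so the energy and
dU/dlambda stay finite at any separation while lambda < 1.

Numba kernels do the per-pair work; everything is in reduced units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["ForceField", "coupling_f", "coupling_df", "SOFTCORE_ALPHA"]

#: soft-core strength in r_sc^2 = r^2 + alpha (1-lambda)^2 sigma^2
SOFTCORE_ALPHA = 0.5
#: exponent of the polynomial coupling function f(lambda) = lambda^n
COUPLING_EXPONENT = 5


def coupling_f(lam: float, n: int = COUPLING_EXPONENT) -> float:
    """Coupling function f(lambda) = lambda^n: f(0)=0, f(1)=1, C1, monotone."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda = {lam} outside [0, 1]")
    return lam**n


def coupling_df(lam: float, n: int = COUPLING_EXPONENT) -> float:
    """Derivative f'(lambda) of the coupling function."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda = {lam} outside [0, 1]")
    return n * lam ** (n - 1)


@dataclass
class ForceField:
    """Species-pair LJ tables, harmonic-bond parameters and cutoffs.

    ``epsilon``/``sigma``/``mass`` map species name -> per-species
    value; unlike pairs use Lorentz-Berthelot rules (arithmetic sigma,
    geometric epsilon) unless overridden in ``pair_overrides``, a dict
    mapping a species pair (either order) to an ``(epsilon, sigma)``
    tuple — used e.g. to make a solvent wet or de-wet the matrix
    independently of its self-interaction.  ``r_list`` must exceed
    ``r_cut``; the margin is the Verlet skin.  ``tail_correction``
    enables the standard mean-field energy tail beyond the cutoff (for
    homogeneous phases; switch off for cavity analyses).
    """

    epsilon: dict = field(
        default_factory=lambda: {"backbone": 1.0, "cys": 1.0, "solvent": 1.0}
    )
    sigma: dict = field(
        default_factory=lambda: {"backbone": 1.0, "cys": 1.0, "solvent": 1.0}
    )
    mass: dict = field(
        default_factory=lambda: {"backbone": 1.0, "cys": 1.0, "solvent": 1.0}
    )
    pair_overrides: dict = field(default_factory=dict)
    bond_k: float = 1000.0
    bond_r0: float = 1.0
    r_cut: float = 2.5
    r_list: float = 2.75
    tail_correction: bool = False

    def __post_init__(self) -> None:
        if not self.r_list > self.r_cut > 0:
            raise ValueError("require r_list > r_cut > 0")
        self.species_order = sorted(self.epsilon)
        n = len(self.species_order)
        self.eps_table = np.empty((n, n))
        self.sig_table = np.empty((n, n))
        for i, a in enumerate(self.species_order):
            for j, b in enumerate(self.species_order):
                eps = float(np.sqrt(self.epsilon[a] * self.epsilon[b]))
                sig = 0.5 * (self.sigma[a] + self.sigma[b])
                if (a, b) in self.pair_overrides:
                    eps, sig = self.pair_overrides[(a, b)]
                elif (b, a) in self.pair_overrides:
                    eps, sig = self.pair_overrides[(b, a)]
                self.eps_table[i, j] = eps
                self.sig_table[i, j] = sig
        if not np.allclose(self.eps_table, self.eps_table.T) or not np.allclose(
            self.sig_table, self.sig_table.T
        ):
            raise ValueError("pair tables must be symmetric")

    # ------------------------------------------------------------------
    def species_index(self, species: np.ndarray) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(self.species_order)}
        return np.array([lookup[s] for s in species], dtype=np.intp)

    def per_particle_mass(self, species: np.ndarray) -> np.ndarray:
        return np.array([self.mass[s] for s in species], dtype=float)

    def pair_params(self, sp_a: str, sp_b: str) -> tuple[float, float]:
        """Combined (epsilon, sigma) for a species pair."""
        ia = self.species_order.index(sp_a)
        ib = self.species_order.index(sp_b)
        return float(self.eps_table[ia, ib]), float(self.sig_table[ia, ib])

    def tail_energy_per_particle(
        self, eps: float, sig: float, rho: float
    ) -> float:
        """Standard LJ mean-field tail energy for one particle in a
        homogeneous background of density ``rho``."""
        sr3 = (sig / self.r_cut) ** 3
        return (8.0 / 3.0) * np.pi * rho * eps * sig**3 * (sr3**3 / 3.0 - sr3)


# ----------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------
@njit(cache=True)
def lj_pair_kernel(
    pos, pi, pj, sp, eps_t, sig_t, box, rcut, frac_idx, f_lam, sc_a
):
    """Truncated LJ over a pair list with one optional fractional particle.

    Returns (forces, energy, virial 3x3, frac_energy, bad_index).
    ``sc_a`` is alpha*(1-lambda)^2; pairs involving ``frac_idx`` use the
    soft-core separation s = r^2 + sc_a*sigma_ij^2 and are scaled by
    f_lam (``frac_energy`` is their already-scaled energy sum);
    dU/dlambda is computed by :func:`lj_frac_dudl_kernel`.
    ``bad_index`` flags a non-fractional pair below the numerical floor.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    energy = 0.0
    e_frac = 0.0
    bad = -1
    rcut2 = rcut * rcut
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rcut2:
            continue
        e = eps_t[sp[i], sp[j]]
        s2 = sig_t[sp[i], sp[j]]
        s2 = s2 * s2
        is_frac = i == frac_idx or j == frac_idx
        if is_frac:
            sep = r2 + sc_a * s2
        else:
            if r2 < 1e-12:
                bad = k
                continue
            sep = r2
        inv = s2 / sep
        inv3 = inv * inv * inv
        inv6 = inv3 * inv3
        u = 4.0 * e * (inv6 - inv3)
        # du/d(sep)
        dus = 4.0 * e * (-6.0 * inv6 + 3.0 * inv3) / sep
        if is_frac:
            energy += f_lam * u
            e_frac += f_lam * u
            fpref = -f_lam * dus * 2.0
        else:
            energy += u
            fpref = -dus * 2.0
        fx = fpref * dx
        fy = fpref * dy
        fz = fpref * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 0] += dy * fx
        virial[1, 1] += dy * fy
        virial[1, 2] += dy * fz
        virial[2, 0] += dz * fx
        virial[2, 1] += dz * fy
        virial[2, 2] += dz * fz
    return forces, energy, virial, e_frac, bad


@njit(cache=True)
def lj_frac_dudl_kernel(
    pos, pi, pj, sp, eps_t, sig_t, box, rcut, frac_idx, f_lam, df_lam,
    sc_a, dsc_dlam,
):
    """dU/dlambda of the fractional particle over the pair list.

    Separate pass so the chain-rule soft-core term (which needs
    d(sc_a)/dlambda) stays readable; cost is O(neighbours of one
    particle).
    """
    dudl = 0.0
    rcut2 = rcut * rcut
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        if i != frac_idx and j != frac_idx:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rcut2:
            continue
        e = eps_t[sp[i], sp[j]]
        s2 = sig_t[sp[i], sp[j]]
        s2 = s2 * s2
        sep = r2 + sc_a * s2
        inv = s2 / sep
        inv3 = inv * inv * inv
        inv6 = inv3 * inv3
        u = 4.0 * e * (inv6 - inv3)
        dus = 4.0 * e * (-6.0 * inv6 + 3.0 * inv3) / sep
        dudl += df_lam * u + f_lam * dus * dsc_dlam * s2
    return dudl


@njit(cache=True)
def bond_kernel(pos, bonds, k_bond, r0, box):
    """Harmonic bonds u = k (r - r0)^2; returns forces, energy, virial."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    virial = np.zeros((3, 3))
    energy = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        energy += k_bond * (r - r0) * (r - r0)
        fpref = -2.0 * k_bond * (r - r0) / r
        fx = fpref * dx
        fy = fpref * dy
        fz = fpref * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += dx * fx
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 0] += dy * fx
        virial[1, 1] += dy * fy
        virial[1, 2] += dy * fz
        virial[2, 0] += dz * fx
        virial[2, 1] += dz * fy
        virial[2, 2] += dz * fz
    return forces, energy, virial
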