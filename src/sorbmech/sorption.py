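"""Sorption isotherms, GAB fitting, swelling and unit conversions.

The Guggenheim-Anderson-de-Boer (GAB) multilayer sorption model

    C(a) = Cm b K a / ((1 - b a)(1 - b a + b K a))

relates the equilibrium sorbate content C (g sorbate per 100 g sorbent)
to the sorbate activity a (relative humidity / 100).  Cm is the
monolayer capacity; K and b are energetic constants, with
K = exp(dH / RT) for the first-layer/liquefaction enthalpy difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import constants

__all__ = [
    "SorptionIsotherm",
    "GABParams",
    "ConcentrationRecord",
    "gab_evaluate",
    "gab_fit",
    "gab_enthalpy",
    "isotherm_point_from_trace",
    "convert_concentration",
    "swelling_ratio",
    "effective_dielectric",
]


@dataclass
class SorptionIsotherm:
    """(activity, content, error) points of one sorption isotherm.

    Activities are fractions in [0, 1]; contents and errors are in
    g sorbate per 100 g sorbent.  Points are kept sorted by activity.
    """

    activity: np.ndarray
    content: np.ndarray
    error: np.ndarray | None = None
    temperature: float = constants.T_REF

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.content = np.asarray(self.content, dtype=float)
        if self.activity.shape != self.content.shape:
            raise ValueError("activity and content must have equal length")
        if np.any((self.activity < 0) | (self.activity > 1)):
            raise ValueError("activities must lie in [0, 1]")
        if np.any(self.content < 0):
            raise ValueError("contents must be non-negative")
        if self.error is None:
            self.error = np.zeros_like(self.content)
        else:
            self.error = np.asarray(self.error, dtype=float)
            if np.any(self.error < 0):
                raise ValueError("errors must be non-negative")
        order = np.argsort(self.activity)
        self.activity = self.activity[order]
        self.content = self.content[order]
        self.error = self.error[order]

    def __len__(self) -> int:
        return self.activity.size


@dataclass
class GABParams:
    """Fitted GAB coefficients (and optional sorption enthalpy)."""

    cm: float
    k: float
    b: float
    dh: float | None = None  # kJ/mol
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("monolayer capacity Cm must be positive")
        if self.k <= 0:
            raise ValueError("K must be positive")
        if not 0.0 < self.b < 1.0:
            raise ValueError("b must lie in (0, 1) for finite C on [0, 1]")


def gab_evaluate(a, params: GABParams) -> np.ndarray | float:
    """GAB content C(a); strictly increasing in a for valid parameters."""
    a_arr = np.asarray(a, dtype=float)
    if np.any((a_arr < 0) | (a_arr > 1)):
        raise ValueError("activity must lie in [0, 1]")
    ba = params.b * a_arr
    if np.any(ba >= 1.0):
        raise ValueError("b*a >= 1: GAB pole inside the requested domain")
    c = params.cm * params.b * params.k * a_arr / (
        (1.0 - ba) * (1.0 - ba + params.b * params.k * a_arr)
    )
    return float(c) if np.isscalar(a) else c


_GRID_CM = (0.5, 1.0, 2.0, 4.0, 7.0, 10.0)
_GRID_K = (1.0, 3.0, 10.0, 20.0, 50.0)
_GRID_B = (0.1, 0.3, 0.5, 0.7, 0.85, 0.95)


def gab_fit(
    isotherm: SorptionIsotherm,
    weights: str = "relative",
    temperature: float | None = None,
) -> GABParams:
    """Least-squares GAB fit with multi-start over a coarse grid.

    ``weights`` selects the error model:

    * ``'relative'`` (default) — residuals divided by the content, i.e.
      constant relative error.  Sorption-point uncertainties derived
      from particle-number fluctuations grow roughly in proportion to
      the uptake, so this is the natural model when no explicit errors
      are given; it is also far better conditioned than absolute
      residuals on data spanning an order of magnitude in C.
    * ``'none'`` — unweighted in C.
    * ``'errors'`` — residuals divided by the per-point errors (zero
      errors replaced by the mean of the nonzero ones).

    Keeps the best (weighted) sum of squared residuals over all starts;
    the fit report (SSE, residuals, start used) lands in
    ``diagnostics``.  Note the GAB objective is nearly flat along a
    valley trading K against Cm and b: Cm and b are well determined,
    K only to tens of percent.
    """
    if len(isotherm) < 4:
        raise ValueError("need at least 4 isotherm points to fit 3 parameters")
    if np.any(isotherm.content <= 0):
        raise ValueError("contents must be positive for fitting")
    a = isotherm.activity
    c = isotherm.content
    if weights == "relative":
        w = c.copy()
    elif weights == "none":
        w = np.ones_like(c)
    elif weights == "errors":
        w = isotherm.error.copy()
        w[w <= 0] = w[w > 0].mean() if np.any(w > 0) else 1.0
    else:
        raise ValueError("weights must be 'relative', 'none' or 'errors'")

    def resid(theta):
        cm, k, b = theta
        ba = b * a
        model = cm * b * k * a / ((1.0 - ba) * (1.0 - ba + b * k * a))
        return (model - c) / w

    best = None
    lo = (1e-6, 1e-6, 1e-6)
    hi = (np.inf, np.inf, 1.0 - 1e-9)
    for cm0 in _GRID_CM:
        for k0 in _GRID_K:
            for b0 in _GRID_B:
                try:
                    sol = least_squares(
                        resid, x0=(cm0, k0, b0), bounds=(lo, hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    )
                except ValueError:
                    continue
                sse = float(np.sum(sol.fun**2))
                if sol.success and (best is None or sse < best[0]):
                    best = (sse, sol, (cm0, k0, b0))
    if best is None:
        raise RuntimeError("GAB fit did not converge from any grid start")
    sse, sol, start = best
    cm, k, b = (float(v) for v in sol.x)
    t = temperature if temperature is not None else isotherm.temperature
    return GABParams(
        cm=cm, k=k, b=b, dh=gab_enthalpy(k, t),
        diagnostics={
            "sse": sse,
            "residuals": (sol.fun * w).tolist(),
            "start": start,
            "n_points": len(isotherm),
            "weights": weights,
        },
    )


def gab_enthalpy(k: float, temperature: float) -> float:
    """Sorption enthalpy difference dH = R T ln K, in kJ/mol."""
    if k <= 0 or temperature <= 0:
        raise ValueError("K and T must be positive")
    return constants.R_GAS_KJ * temperature * float(np.log(k))


# ----------------------------------------------------------------------
def isotherm_point_from_trace(
    n_trace: np.ndarray,
    keratin_mass_g_per_mol_total: float,
    sorbate_molar_mass: float = constants.M_WATER,
    segment: slice | None = None,
) -> tuple[float, float]:
    """One isotherm point (C, err) from a particle-count time series.

    ``n_trace`` is the sorbate count over the stationary segment;
    ``keratin_mass_g_per_mol_total`` the total sorbent mass in g/mol
    (sum of residue molar masses).  C is the segment mean converted to
    g per 100 g sorbent; err is the root-mean-square deviation of the
    per-sample C about its mean, in the same units.
    """
    n = np.asarray(n_trace, dtype=float)
    if segment is not None:
        n = n[segment]
    if n.size == 0:
        raise ValueError("empty stationary segment")
    conv = 100.0 * sorbate_molar_mass / keratin_mass_g_per_mol_total
    c_series = n * conv
    c = float(c_series.mean())
    err = float(np.sqrt(np.mean((c_series - c) ** 2)))
    return c, err


# ----------------------------------------------------------------------
@dataclass
class ConcentrationRecord:
    """Mutually consistent representations of a sorbate concentration.

    C: g sorbate / 100 g sorbent; number_density in 1/nm^3; per_residue
    in molecules per residue; vol_percent in %; rho_k the sorbent mass
    density in the mixture (g/cm^3); v_w the molecular volume of the
    sorbed sorbate (nm^3).
    """

    c: float | None = None
    number_density: float | None = None
    per_residue: float | None = None
    vol_percent: float | None = None
    rho_k: float | None = None
    m_w: float = constants.M_WATER
    m_res: float | None = None
    v_w: float | None = None


def convert_concentration(
    record: ConcentrationRecord, rtol: float = 1e-6
) -> ConcentrationRecord:
    """Complete a concentration record from any sufficient field subset.

    Closure relations (reduced to g, nm):
      number_density [1/nm^3] = (C/100) * rho_k * NA / m_w  (rho_k in g/cm^3)
      per_residue             = (C/100) * m_res / m_w
      vol_percent             = number_density * v_w * 100
    Fields already present are checked against the recomputed values;
    an inconsistent over-determined input raises with the clashing field.
    """
    r = ConcentrationRecord(**vars(record))
    # g/cm^3 * 1/(g/mol) * NA = molecules/cm^3; 1 cm^3 = 1e21 nm^3
    dens_conv = constants.NA / 1e21

    for _ in range(3):  # closure needs at most a few sweeps
        if r.c is not None and r.c == 0.0:
            r.number_density = r.number_density or 0.0
            r.per_residue = r.per_residue or 0.0
            r.vol_percent = r.vol_percent or 0.0
        if (
            r.number_density is None
            and None not in (r.c, r.rho_k)
        ):
            r.number_density = r.c / 100.0 * r.rho_k / r.m_w * dens_conv
        if r.rho_k is None and None not in (r.c, r.number_density) and r.c > 0:
            r.rho_k = r.number_density * r.m_w / dens_conv / (r.c / 100.0)
        if r.per_residue is None and None not in (r.c, r.m_res):
            r.per_residue = r.c / 100.0 * r.m_res / r.m_w
        if r.m_res is None and None not in (r.c, r.per_residue) and r.c > 0:
            r.m_res = r.per_residue * r.m_w / (r.c / 100.0)
        if r.c is None and None not in (r.per_residue, r.m_res):
            r.c = 100.0 * r.per_residue * r.m_w / r.m_res
        if r.vol_percent is None and None not in (r.number_density, r.v_w):
            r.vol_percent = r.number_density * r.v_w * 100.0
        if r.v_w is None and None not in (r.number_density, r.vol_percent):
            if r.number_density > 0:
                r.v_w = r.vol_percent / 100.0 / r.number_density

    # consistency check on any over-determined input
    checks = []
    if None not in (record.number_density, r.c, r.rho_k):
        checks.append(
            ("number_density", record.number_density,
             r.c / 100.0 * r.rho_k / r.m_w * dens_conv)
        )
    if None not in (record.per_residue, r.c, r.m_res):
        checks.append(
            ("per_residue", record.per_residue, r.c / 100.0 * r.m_res / r.m_w)
        )
    if None not in (record.vol_percent, r.number_density, r.v_w):
        checks.append(
            ("vol_percent", record.vol_percent,
             r.number_density * r.v_w * 100.0)
        )
    for name, given, computed in checks:
        if not np.isclose(given, computed, rtol=rtol, atol=1e-12):
            raise ValueError(
                f"inconsistent over-determined input: {name} given as "
                f"{given} but closure gives {computed}"
            )
    return r


def swelling_ratio(v_mixture: float, v_keratin: float) -> float:
    """Volume swelling in percent relative to the dry sorbent volume."""
    if v_keratin <= 0:
        raise ValueError("dry volume must be positive")
    if v_mixture <= 0:
        raise ValueError("mixture volume must be positive")
    return (v_mixture - v_keratin) / v_keratin * 100.0


def effective_dielectric(
    vol_fraction_water: float,
    eps_water: float = constants.EPS_WATER,
    eps_matrix: float = constants.EPS_KERATIN,
) -> float:
    """Volume-fraction mixing rule for the effective dielectric constant.

    eps_eff = phi * eps_water + (1 - phi) * eps_matrix, the linear
    addition of each component's dielectric constant weighted by its
    volume fraction.
    """
    if not 0.0 <= vol_fraction_water <= 1.0:
        raise ValueError("volume fraction must lie in [0, 1]")
    return vol_fraction_water * eps_water + (1.0 - vol_fraction_water) * eps_matrix
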