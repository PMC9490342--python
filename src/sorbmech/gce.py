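"""Grand-canonical sampling by fractional-particle lambda-dynamics.

One solvent particle is *fractional*: its interactions are scaled by a
smooth coupling function f(lambda) with soft-core regularization.  The
coupling parameter evolves under an extended-Hamiltonian equation of
motion

    W d2(lambda)/dt2 = -dU/dlambda + mu_ex_target - kT ln(N_eff / (rho_ref V))

where N_eff counts full solvent particles plus lambda.  The last term is
the ideal-gas part of the chemical-potential difference against a
reference density ``rho_ref``; it makes the stationary solvent density
well defined even for a non-interacting solvent and turns the target
into a full chemical potential mu = mu_ex_target + kT ln(rho_ref
Lambda^3).  When lambda reaches 1 the fractional particle becomes a full
one and a fresh fractional particle is inserted (continuing at
lambda - 1, uniform random position); when it reaches 0 the fractional
particle is deleted and a randomly chosen full solvent particle is
designated fractional (continuing at lambda + 1).  Both event types
keep N_eff and the total potential energy continuous, and the lambda
velocity is carried through, so lambda behaves as one continuous
extended coordinate whose unit intervals step the particle number.  A
Langevin thermostat on lambda keeps it thermal so it can cross the
coupling-work barrier between the decoupled and coupled states.

The module also provides Widom test-particle insertion as an independent
estimator of the excess chemical potential, and the chemical-potential
bookkeeping linking sorbent phase, vapour phase and relative humidity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants
from .forcefield import (
    SOFTCORE_ALPHA,
    ForceField,
    coupling_df,
    coupling_f,
    lj_frac_dudl_kernel,
)
from .md import IntegratorSettings, MDEngine
from .system import SystemConfiguration, minimum_image

__all__ = [
    "GCEState",
    "ChemState",
    "GCEResult",
    "fractional_potential",
    "step_lambda",
    "run_gce",
    "widom_mu_ex",
    "mu_pressure_expand",
    "rh_to_gas_state",
    "ideal_gas_log_term",
]


# ----------------------------------------------------------------------
@dataclass
class GCEState:
    """State of the coupling degree of freedom and its bookkeeping."""

    lam: float = 0.5
    lam_velocity: float = 0.0
    w_mass: float = 5.0
    fractional_index: int = -1
    mu_ex_target: float = 0.0
    insertions: int = 0
    deletions: int = 0

    def __post_init__(self) -> None:
        if self.w_mass <= 0:
            raise ValueError("lambda inertial mass W must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")


@dataclass
class ChemState:
    """Thermodynamic bookkeeping of the two-phase equilibrium.

    The internal-degrees-of-freedom term B(T) of the ideal-gas chemical
    potential is fixed to 0: it is a temperature-only common factor that
    cancels between the two phases at equal T.
    """

    temperature: float
    p_vapour: float                 # Pa
    rho_wg: float                   # vapour mass density, g/m^3
    number_density: float           # vapour number density, 1/m^3
    p_keratin: float | None = None  # Pa
    v_wk: float | None = None       # molecular volume of sorbate, nm^3
    mu_ex_keratin: float | None = None  # kJ/mol
    mu_ex_gas: float | None = None      # kJ/mol
    m_sorbate: float = constants.M_WATER  # g/mol
    b_internal: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.p_vapour <= 0:
            raise ValueError("vapour pressure must be positive")
        if self.b_internal != 0.0:
            raise ValueError("B(T) is fixed to 0 (cancels between phases)")


@dataclass
class GCEResult:
    """Output of one grand-canonical run."""

    n_trace: np.ndarray          # full-solvent count per recorded step
    lam_trace: np.ndarray
    n_eff_trace: np.ndarray      # N + lambda
    events: list[tuple[int, str]]
    stationary: bool
    state: GCEState
    config: SystemConfiguration
    records: list = field(default_factory=list)


# ----------------------------------------------------------------------
def fractional_potential(
    lam: float,
    r: np.ndarray | float,
    epsilon: float = 1.0,
    sigma: float = 1.0,
    alpha: float = SOFTCORE_ALPHA,
) -> tuple[float, float]:
    """Scaled soft-core pair energy of the fractional particle.

    For separations ``r`` (scalar or array) the pair energy is
    f(lambda) * 4 eps [ (sig^2/s)^6 - (sig^2/s)^3 ],
    s = r^2 + alpha (1-lambda)^2 sig^2.  Returns the summed energy and
    its analytic dU/dlambda; both are finite at any separation while
    lambda < 1, and at lambda = 1 the energy is the plain LJ energy.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda = {lam} outside [0, 1]")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    s2 = sigma * sigma
    sep = r * r + alpha * (1.0 - lam) ** 2 * s2
    inv = s2 / sep
    u = 4.0 * epsilon * (inv**6 - inv**3)
    f = coupling_f(lam)
    df = coupling_df(lam)
    du_dsep = 4.0 * epsilon * (-6.0 * inv**6 + 3.0 * inv**3) / sep
    dsep_dlam = -2.0 * alpha * (1.0 - lam) * s2
    energy = float(np.sum(f * u))
    dudl = float(np.sum(df * u + f * du_dsep * dsep_dlam))
    return energy, dudl


def step_lambda(
    state: GCEState,
    dU_dlambda: float,
    dt: float,
    ideal_term: float = 0.0,
    friction: float = 0.0,
    noise: float = 0.0,
) -> tuple[GCEState, str | None]:
    """One leapfrog step of the coupling parameter.

    Force on lambda: -dU/dlambda + mu_ex_target - ideal_term.  The
    lambda degree of freedom is thermostatted like the particles: the
    caller may pass a Langevin ``friction`` coefficient and the matching
    pre-sampled velocity ``noise`` impulse, which keep lambda thermal
    and able to cross coupling-work barriers.  Reaching 1
    from the interior converts the fractional particle into a full one
    (event 'insertion'; the fresh fractional particle continues at
    lambda - 1); reaching 0 deletes it (event 'deletion'; the newly
    designated fractional particle continues at lambda + 1).

    The lambda velocity is *preserved* through events: lambda is a
    continuous extended coordinate and the total potential energy is
    continuous across a crossing (the fractional identity merely
    relabels which interactions are scaled), so momentum-conserving
    hand-off keeps the extended dynamics energy-consistent.  Zeroing
    the velocity instead injects a detailed-balance violation that
    biases the stationary density by O(kT) in the chemical potential.

    Returns (new state, event) with event in {None, 'insertion',
    'deletion'}; the caller is responsible for the matching particle
    bookkeeping.
    """
    if state.w_mass <= 0:
        raise ValueError("lambda inertial mass W must be positive")
    force = -dU_dlambda + state.mu_ex_target - ideal_term
    v = state.lam_velocity + dt * (
        force / state.w_mass - friction * state.lam_velocity
    ) + noise
    lam = state.lam + dt * v
    event = None
    if lam >= 1.0:
        event = "insertion"
        return (
            replace(state, lam=min(lam - 1.0, 1.0), lam_velocity=v,
                    insertions=state.insertions + 1),
            event,
        )
    if lam <= 0.0:
        event = "deletion"
        return (
            replace(state, lam=max(lam + 1.0, 0.0), lam_velocity=v,
                    deletions=state.deletions + 1),
            event,
        )
    return replace(state, lam=lam, lam_velocity=v), event


# ----------------------------------------------------------------------
def _insertion_tail_energy(
    config: SystemConfiguration, ff: ForceField, species: str = "solvent"
) -> float:
    """Mean-field tail energy gained by inserting one ``species`` particle."""
    if not ff.tail_correction:
        return 0.0
    du = 0.0
    v = config.volume
    for other in np.unique(config.species):
        idx = config.species_indices(str(other))
        if idx.size == 0:
            continue
        eps, sig = ff.pair_params(species, str(other))
        du += 2.0 * ff.tail_energy_per_particle(eps, sig, idx.size / v)
    return du


def _frac_dudl(engine: MDEngine, state: GCEState, ff: ForceField) -> float:
    lam = state.lam
    pairs = engine.pairs
    pi = np.ascontiguousarray(pairs[:, 0]) if pairs.size else np.empty(0, np.intp)
    pj = np.ascontiguousarray(pairs[:, 1]) if pairs.size else np.empty(0, np.intp)
    sp = ff.species_index(engine.config.species)
    dudl = lj_frac_dudl_kernel(
        engine.config.positions, pi, pj, sp, ff.eps_table, ff.sig_table,
        engine.config.box, ff.r_cut, state.fractional_index,
        coupling_f(lam), coupling_df(lam),
        SOFTCORE_ALPHA * (1.0 - lam) ** 2, -2.0 * SOFTCORE_ALPHA * (1.0 - lam),
    )
    dudl += coupling_df(lam) * _insertion_tail_energy(engine.config, ff)
    return float(dudl)


def _sync_engine_lambda(engine: MDEngine, state: GCEState) -> None:
    engine.frac_idx = state.fractional_index
    engine.f_lam = coupling_f(state.lam)
    engine.sc_a = SOFTCORE_ALPHA * (1.0 - state.lam) ** 2


def _add_particle(engine: MDEngine, pos, vel, species: str, ff) -> int:
    cfg = engine.config
    cfg.positions = np.vstack([cfg.positions, pos])
    cfg.species = np.concatenate([cfg.species, np.array([species], dtype=object)])
    engine.velocities = np.vstack([engine.velocities, vel])
    cfg.velocities = engine.velocities
    engine.masses = ff.per_particle_mass(cfg.species)
    return cfg.n_particles - 1


def _remove_particle(engine: MDEngine, idx: int, ff) -> None:
    cfg = engine.config
    keep = np.arange(cfg.n_particles) != idx
    cfg.positions = cfg.positions[keep]
    cfg.species = cfg.species[keep]
    engine.velocities = engine.velocities[keep]
    cfg.velocities = engine.velocities
    # bonded topology never involves solvent particles; indices above idx shift
    for name in ("bonds", "crosslinks"):
        pairs = getattr(cfg, name)
        if pairs.size:
            setattr(cfg, name, np.where(pairs > idx, pairs - 1, pairs))
    engine.masses = ff.per_particle_mass(cfg.species)


def run_gce(
    config: SystemConfiguration,
    ff: ForceField,
    settings: IntegratorSettings,
    mu_ex_target: float,
    n_steps: int,
    seed: int = 0,
    rho_ref: float | None = None,
    w_mass: float = 5.0,
    lam_gamma: float = 1.0,
    clamp_lambda: float | None = None,
    record_every: int = 1,
) -> GCEResult:
    """Coupled particle + lambda dynamics at fixed V and T.

    ``rho_ref`` is the reference solvent number density of the ideal-gas
    bookkeeping (defaults to the initial N_eff/V).  ``lam_gamma`` is the
    Langevin friction on the lambda velocity (0 disables its
    thermostat); lambda needs thermal kicks to cross the coupling-work
    barrier between the decoupled and fully coupled states at liquid
    densities.  ``clamp_lambda`` freezes lambda at a fixed value
    (clamping at 1 reduces the run to plain NVT with one extra ordinary
    particle).

    Returns a :class:`GCEResult` with the full N(t) trace and a
    stationarity flag from a two-halves mean comparison.
    """
    if settings.barostat != "off":
        raise ValueError("grand-canonical runs are constant-volume")
    rng = np.random.default_rng(seed)
    cfg = config.copy()
    cfg.wrap()

    engine = MDEngine(cfg, ff, settings)
    # designate the fractional particle: a freshly inserted solvent bead
    start_lam = clamp_lambda if clamp_lambda is not None else 0.5
    vel = rng.normal(size=3) * np.sqrt(
        settings.t_target / ff.mass["solvent"]
    )
    frac = _add_particle(
        engine, rng.uniform(0, 1, 3) * cfg.box, vel, "solvent", ff
    )
    state = GCEState(
        lam=start_lam, w_mass=w_mass, fractional_index=frac,
        mu_ex_target=mu_ex_target,
    )
    _sync_engine_lambda(engine, state)
    engine.rebuild_neighbors()
    engine.forces, engine.potential, engine.virial = engine._forces()

    n_full = int(np.sum(cfg.species == "solvent")) - 1
    if rho_ref is None:
        rho_ref = (n_full + state.lam) / cfg.volume
    kt = settings.t_target

    n_trace, lam_trace, neff_trace = [], [], []
    events: list[tuple[int, str]] = []
    for step_i in range(n_steps):
        if clamp_lambda is None:
            dudl = _frac_dudl(engine, state, ff)
            n_eff = n_full + state.lam
            ideal = kt * np.log(max(n_eff, 1e-12) / (rho_ref * cfg.volume))
            noise = (
                np.sqrt(2.0 * lam_gamma * kt * settings.dt / w_mass)
                * rng.normal()
                if lam_gamma > 0
                else 0.0
            )
            state, event = step_lambda(
                state, dudl, settings.dt, ideal,
                friction=lam_gamma, noise=noise,
            )
            if event == "insertion":
                n_full += 1
                vel = rng.normal(size=3) * np.sqrt(
                    settings.t_target / ff.mass["solvent"]
                )
                frac = _add_particle(
                    engine, rng.uniform(0, 1, 3) * cfg.box, vel, "solvent", ff
                )
                state = replace(state, fractional_index=frac)
                events.append((step_i, event))
            elif event == "deletion":
                _remove_particle(engine, state.fractional_index, ff)
                solvent = cfg.species_indices("solvent")
                if solvent.size:
                    n_full -= 1
                    new_frac = int(rng.choice(solvent))
                    state = replace(state, fractional_index=new_frac)
                else:
                    # no full solvent left: re-insert a fresh fractional
                    vel = rng.normal(size=3) * np.sqrt(
                        settings.t_target / ff.mass["solvent"]
                    )
                    frac = _add_particle(
                        engine, rng.uniform(0, 1, 3) * cfg.box, vel,
                        "solvent", ff,
                    )
                    state = replace(state, fractional_index=frac, lam=0.0)
                events.append((step_i, event))
            if event is not None:
                _sync_engine_lambda(engine, state)
                engine.rebuild_neighbors()
                engine.forces, engine.potential, engine.virial = (
                    engine._forces()
                )
            else:
                _sync_engine_lambda(engine, state)
        engine.step()
        if (step_i + 1) % record_every == 0:
            n_trace.append(n_full)
            lam_trace.append(state.lam)
            neff_trace.append(n_full + state.lam)

    if state.insertions == 0 and state.deletions == 0 and clamp_lambda is None:
        warnings.warn(
            "no insertions or deletions over the run (lambda stuck or "
            "oscillating inside one interval)",
            stacklevel=2,
        )

    neff = np.asarray(neff_trace)
    stationary = _two_halves_stationary(neff)
    return GCEResult(
        n_trace=np.asarray(n_trace),
        lam_trace=np.asarray(lam_trace),
        n_eff_trace=neff,
        events=events,
        stationary=stationary,
        state=state,
        config=cfg,
    )


def _two_halves_stationary(x: np.ndarray, n_blocks: int = 10) -> bool:
    """True when the two halves' means differ by < 1 combined block SE."""
    if x.size < 2 * n_blocks:
        return False
    half = x.size // 2
    means, ses = [], []
    for seg in (x[:half], x[half:]):
        blocks = np.array_split(seg, n_blocks)
        bm = np.array([b.mean() for b in blocks])
        means.append(bm.mean())
        ses.append(bm.std(ddof=1) / np.sqrt(n_blocks))
    combined = float(np.hypot(*ses))
    if combined == 0.0:
        return means[0] == means[1]
    return abs(means[0] - means[1]) < combined


def prescan_density(
    config: SystemConfiguration,
    ff: ForceField,
    settings: IntegratorSettings,
    mu_ex_target: float,
    n_steps: int = 5000,
    seed: int = 0,
    **gce_kwargs,
) -> float:
    """Short exploratory grand-canonical run; returns a density guess.

    Production runs converge fastest when started near the equilibrium
    solvent density; this runs a brief exchange simulation at the
    target chemical potential and returns the mean effective density
    over its final quarter, to be used when preparing the initial
    configuration of the long run.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_gce(config, ff, settings, mu_ex_target, n_steps,
                      seed=seed, **gce_kwargs)
    tail = res.n_eff_trace[3 * len(res.n_eff_trace) // 4:]
    return float(tail.mean()) / res.config.volume


# ----------------------------------------------------------------------
def widom_mu_ex(
    config: SystemConfiguration | list[SystemConfiguration],
    ff: ForceField,
    temperature: float,
    n_insertions: int,
    seed: int = 0,
    species: str = "solvent",
    chunk: int = 256,
) -> tuple[float, float]:
    """Widom test-particle estimate of the excess chemical potential.

    mu_ex = -kT ln < exp(-dU/kT) > over uniform random trial insertions
    of one ``species`` particle; returns (estimate, standard error), in
    reduced energy units.  ``config`` may be a single configuration or a
    list of decorrelated frames (insertions are spread evenly over the
    frames; a single frame measures that snapshot only, not the
    ensemble).  If every insertion overlaps (dU -> +inf) the estimate
    tends to +inf and a warning is issued.
    """
    if n_insertions < 1:
        raise ValueError("n_insertions must be >= 1")
    frames = [config] if isinstance(config, SystemConfiguration) else list(config)
    rng = np.random.default_rng(seed)
    boltz = np.empty(n_insertions)
    done = 0
    per_frame = int(np.ceil(n_insertions / len(frames)))
    for frame in frames:
        pos = frame.positions % frame.box
        sp = ff.species_index(frame.species)
        sp_t = ff.species_order.index(species)
        eps_t = ff.eps_table[sp_t, sp]
        sig_t = ff.sig_table[sp_t, sp]
        tail = _insertion_tail_energy(frame, ff, species)
        left = min(per_frame, n_insertions - done)
        while left > 0:
            m = min(chunk, left)
            trials = rng.uniform(0, 1, size=(m, 3)) * frame.box
            dr = minimum_image(
                trials[:, None, :] - pos[None, :, :], frame.box
            )
            r2 = np.einsum("ijk,ijk->ij", dr, dr)
            mask = r2 < ff.r_cut**2
            with np.errstate(divide="ignore", over="ignore"):
                inv = np.where(
                    mask, sig_t[None, :] ** 2 / np.maximum(r2, 1e-14), 0.0
                )
                du = np.sum(
                    4.0 * eps_t[None, :] * (inv**6 - inv**3) * mask, axis=1
                )
            du += tail
            with np.errstate(over="ignore"):
                boltz[done : done + m] = np.exp(-du / temperature)
            done += m
            left -= m
        if done >= n_insertions:
            break

    mean = float(boltz.mean())
    if mean == 0.0:
        warnings.warn(
            "all trial insertions overlapped; mu_ex estimate tends to +inf",
            stacklevel=2,
        )
        return np.inf, np.inf
    se_b = float(boltz.std(ddof=1) / np.sqrt(n_insertions)) if n_insertions > 1 else np.inf
    mu = -temperature * np.log(mean)
    # delta method: sigma_mu = kT * sigma_B / B
    return float(mu), temperature * se_b / mean


# ----------------------------------------------------------------------
def mu_pressure_expand(
    mu_ex_at_pprime: float,
    v_wk_nm3: float,
    p_prime: float,
    p: float,
    temperature: float,
) -> float:
    """Pressure expansion of the sorbent-phase excess chemical potential.

    mu_ex(P) = mu_ex(P') + v_wk (P - P') + kT ln(P'/P), with ``v_wk`` the
    molecular volume of the sorbate in the sorbent phase (nm^3),
    pressures in Pa, temperature in K; the result (and input mu) in
    kJ/mol.
    """
    if p_prime <= 0 or p <= 0:
        raise ValueError("pressures must be positive")
    v_term = v_wk_nm3 * 1e-27 * (p - p_prime) * constants.NA / 1000.0
    log_term = constants.R_GAS_KJ * temperature * np.log(p_prime / p)
    return mu_ex_at_pprime + v_term + log_term


def rh_to_gas_state(
    rh_percent: float,
    temperature: float = constants.T_REF,
    p_sat: float | None = None,
) -> ChemState:
    """Vapour-phase state at a given relative humidity.

    P = (RH/100) * P_sat(T); the vapour is treated as an ideal gas, so
    its number density is P/(kB T).  Only the saturation pressure at
    300 K is built in; other temperatures need ``p_sat``.
    """
    if rh_percent <= 0:
        raise ValueError("relative humidity must be positive")
    if rh_percent > 100:
        raise ValueError("relative humidity cannot exceed 100%")
    if p_sat is None:
        if abs(temperature - constants.T_REF) > 1e-9:
            raise ValueError("supply p_sat for temperatures other than 300 K")
        p_sat = constants.P_SAT_WATER_300K
    p = rh_percent / 100.0 * p_sat
    n_dens = p / (constants.KB * temperature)          # 1/m^3
    rho_wg = n_dens / constants.NA * constants.M_WATER  # g/m^3
    return ChemState(
        temperature=temperature, p_vapour=p, rho_wg=rho_wg,
        number_density=n_dens,
    )


def ideal_gas_log_term(
    solubility_c: float,
    rho_k_g_cm3: float,
    gas: ChemState,
) -> float:
    """Ideal-gas part of the phase-equilibrium condition, in kJ/mol.

    kT ln( C rho_k / (100 rho_wg) ) with C in g sorbate per 100 g
    sorbent, rho_k the sorbent mass density in the mixture (g/cm^3) and
    rho_wg the vapour mass density; the temperature-only term involving
    the thermal wavelength and B(T) cancels between phases and is
    omitted.
    """
    if solubility_c <= 0:
        raise ValueError("solubility must be positive for the log term")
    rho_keratin_phase = solubility_c / 100.0 * rho_k_g_cm3 * 1e6  # g/m^3
    return (
        constants.R_GAS_KJ
        * gas.temperature
        * float(np.log(rho_keratin_phase / gas.rho_wg))
    )
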