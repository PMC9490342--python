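"""Velocity-Verlet molecular-dynamics core.

Protocol mirrors the standard glassy-polymer tensile setup: velocity
Verlet integration, a Nose-Hoover thermostat (the differential form of
the Nose scheme, with the same stationary distribution), a Berendsen
barostat in isotropic or semi-isotropic mode (the frozen axis is never
touched by the barostat), and a Verlet neighbour list rebuilt on a fixed
schedule and additionally whenever any particle has moved more than half
the list skin.

All quantities are in reduced units; ``UnitSystem`` maps them to
physical units for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import ForceField, bond_kernel, lj_pair_kernel
from .system import SystemConfiguration

__all__ = [
    "IntegratorSettings",
    "ThermoRecord",
    "MDEngine",
    "build_neighbor_list",
    "compute_forces",
    "step_nvt",
    "step_npt",
    "deform_uniaxial",
    "push_off",
]


@dataclass(frozen=True)
class IntegratorSettings:
    """Time step, thermostat, barostat and neighbour-list settings.

    ``thermostat_mass`` is the Nose inertial parameter Q (reduced
    analogue of 5.0 kJ/mol ps^2); ``tau_p`` the Berendsen pressure
    coupling time, defaulting to 100*dt when None.
    """

    dt: float = 0.005
    t_target: float = 1.0
    thermostat: bool = True
    thermostat_mass: float = 5.0
    barostat: str = "off"  # 'off' | 'isotropic' | 'semi-isotropic'
    frozen_axis: int | None = None
    p_target: float = 0.0
    compressibility: float = 0.05
    tau_p: float | None = None
    neighbor_update: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.neighbor_update < 1:
            raise ValueError("neighbour-update interval must be >= 1")
        if self.barostat not in ("off", "isotropic", "semi-isotropic"):
            raise ValueError(f"unknown barostat mode {self.barostat!r}")
        if self.barostat == "semi-isotropic" and self.frozen_axis is None:
            raise ValueError("semi-isotropic barostat needs a frozen axis")

    @property
    def tau_p_eff(self) -> float:
        return self.tau_p if self.tau_p is not None else 100.0 * self.dt


@dataclass
class ThermoRecord:
    """One thermodynamic sample of a running simulation."""

    time: float
    temperature: float
    pressure_tensor: np.ndarray  # (xx, yy, zz, xy, xz, yz)
    potential: float
    kinetic: float
    box: np.ndarray

    def __post_init__(self) -> None:
        if self.kinetic < 0:
            raise ValueError("kinetic energy must be non-negative")
        self.box = np.asarray(self.box, dtype=float)
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def pressure(self) -> float:
        return float(np.mean(self.pressure_tensor[:3]))


# ----------------------------------------------------------------------
def build_neighbor_list(
    config: SystemConfiguration, r_list: float
) -> np.ndarray:
    """All particle pairs with minimum-image distance < ``r_list``.

    Returns an (M, 2) array with i < j.  Requires every box edge to
    exceed 2*r_list so that the minimum-image convention is valid.
    """
    if np.any(config.box <= 2.0 * r_list):
        raise ValueError(
            f"box {config.box} too small for neighbour search radius "
            f"{r_list} (need every edge > 2*r_list)"
        )
    pos = config.positions % config.box
    tree = cKDTree(pos, boxsize=config.box)
    pairs = tree.query_pairs(r_list, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.intp)
    return np.sort(pairs.astype(np.intp), axis=1)


def compute_forces(
    config: SystemConfiguration,
    ff: ForceField,
    pairs: np.ndarray,
    frac_idx: int = -1,
    f_lam: float = 1.0,
    sc_a: float = 0.0,
):
    """Forces, potential energy and virial tensor for a configuration.

    Non-bonded truncated LJ over ``pairs`` plus harmonic bonds.  Pairs
    involving ``frac_idx`` (if >= 0) are scaled by ``f_lam`` with
    soft-core parameter ``sc_a`` = alpha*(1-lambda)^2.

    Returns (forces, potential, virial 3x3).
    """
    sp = ff.species_index(config.species)
    pi = np.ascontiguousarray(pairs[:, 0]) if pairs.size else np.empty(0, np.intp)
    pj = np.ascontiguousarray(pairs[:, 1]) if pairs.size else np.empty(0, np.intp)
    f, e, w, _, bad = lj_pair_kernel(
        config.positions, pi, pj, sp, ff.eps_table, ff.sig_table,
        config.box, ff.r_cut, frac_idx, f_lam, sc_a,
    )
    if bad >= 0:
        i, j = int(pi[bad]), int(pj[bad])
        raise FloatingPointError(
            f"particles {i} and {j} overlap below the numerical floor"
        )
    bonds = config.all_bonds()
    if bonds.size:
        fb, eb, wb = bond_kernel(
            config.positions, np.ascontiguousarray(bonds), ff.bond_k,
            ff.bond_r0, config.box,
        )
        f += fb
        e += eb
        w += wb
    return f, e, w


# ----------------------------------------------------------------------
class MDEngine:
    """Stateful integrator bound to one configuration and force field.

    Keeps velocities, the Nose-Hoover friction variable, the neighbour
    list and its rebuild bookkeeping.  ``step`` advances one velocity-
    Verlet step including (optionally) thermostat and barostat.
    """

    def __init__(
        self,
        config: SystemConfiguration,
        ff: ForceField,
        settings: IntegratorSettings,
    ):
        self.config = config
        self.ff = ff
        self.settings = settings
        self.time = 0.0
        self.xi = 0.0  # Nose-Hoover friction
        self.masses = ff.per_particle_mass(config.species)
        if config.velocities is None:
            self._init_velocities()
        self.velocities = config.velocities
        # fractional-particle state (used by the grand-canonical driver)
        self.frac_idx = -1
        self.f_lam = 1.0
        self.sc_a = 0.0
        self._pairs_pos = None
        self.rebuild_neighbors()
        self.forces, self.potential, self.virial = self._forces()

    # -- setup ----------------------------------------------------------
    def _init_velocities(self) -> None:
        rng = np.random.default_rng(self.settings.seed)
        n = self.config.n_particles
        v = rng.normal(size=(n, 3)) * np.sqrt(
            self.settings.t_target / self.masses[:, None]
        )
        v -= np.average(v, axis=0, weights=self.masses)
        self.config.velocities = v

    @property
    def n_dof(self) -> int:
        return 3 * self.config.n_particles - 3

    # -- neighbour list -------------------------------------------------
    def rebuild_neighbors(self) -> None:
        self.config.wrap()
        self.pairs = build_neighbor_list(self.config, self.ff.r_list)
        self._pairs_pos = self.config.positions.copy()
        self._steps_since_rebuild = 0

    def _skin_violated(self) -> bool:
        disp = self.config.positions - self._pairs_pos
        disp -= self.config.box * np.round(disp / self.config.box)
        max_disp = np.sqrt((disp**2).sum(axis=1).max())
        return max_disp > 0.5 * (self.ff.r_list - self.ff.r_cut)

    # -- forces ---------------------------------------------------------
    def _forces(self):
        return compute_forces(
            self.config, self.ff, self.pairs,
            frac_idx=self.frac_idx, f_lam=self.f_lam, sc_a=self.sc_a,
        )

    # -- observables ----------------------------------------------------
    @property
    def kinetic(self) -> float:
        return 0.5 * float(np.sum(self.masses[:, None] * self.velocities**2))

    @property
    def temperature(self) -> float:
        return 2.0 * self.kinetic / self.n_dof

    def pressure_tensor(self) -> np.ndarray:
        """Instantaneous pressure tensor (xx, yy, zz, xy, xz, yz)."""
        v = self.velocities
        m = self.masses[:, None]
        kin = (m * v).T @ v
        p = (kin + self.virial) / self.config.volume
        return np.array(
            [p[0, 0], p[1, 1], p[2, 2], p[0, 1], p[0, 2], p[1, 2]]
        )

    def record(self) -> ThermoRecord:
        return ThermoRecord(
            time=self.time,
            temperature=self.temperature,
            pressure_tensor=self.pressure_tensor(),
            potential=self.potential,
            kinetic=self.kinetic,
            box=self.config.box.copy(),
        )

    # -- one step -------------------------------------------------------
    def step(self) -> None:
        s = self.settings
        dt = s.dt
        m = self.masses[:, None]
        a = self.forces / m
        # half kick (with Nose-Hoover friction if thermostatted)
        self.velocities += 0.5 * dt * (a - self.xi * self.velocities)
        # drift
        self.config.positions += dt * self.velocities
        self.time += dt
        self._steps_since_rebuild += 1
        if (
            self._steps_since_rebuild >= s.neighbor_update
            or self._skin_violated()
        ):
            self.rebuild_neighbors()
        self.forces, self.potential, self.virial = self._forces()
        if not np.all(np.isfinite(self.config.positions)):
            raise FloatingPointError(
                f"non-finite coordinate at t = {self.time:.6g}"
            )
        if s.thermostat:
            ke2 = float(np.sum(m * self.velocities**2))
            self.xi += dt * (ke2 - self.n_dof * s.t_target) / s.thermostat_mass
            self.velocities = (
                self.velocities + 0.5 * dt * self.forces / m
            ) / (1.0 + 0.5 * dt * self.xi)
        else:
            self.velocities += 0.5 * dt * self.forces / m
        if s.barostat != "off":
            self._apply_barostat()

    # -- barostat -------------------------------------------------------
    def _apply_barostat(self) -> None:
        s = self.settings
        p = self.pressure_tensor()
        scale = np.ones(3)
        pref = s.compressibility * s.dt / s.tau_p_eff
        if s.barostat == "isotropic":
            mu = (1.0 - pref * (s.p_target - float(np.mean(p[:3])))) ** (1 / 3)
            scale[:] = mu
        else:  # semi-isotropic
            axes = [ax for ax in range(3) if ax != s.frozen_axis]
            p_t = float(np.mean(p[axes]))
            mu = (1.0 - pref * (s.p_target - p_t)) ** (1 / 3)
            for ax in axes:
                scale[ax] = mu
        new_box = self.config.box * scale
        if np.any(new_box <= 0):
            raise FloatingPointError("barostat produced a non-positive box")
        self.config.positions *= scale
        self.config.box = new_box
        if self._pairs_pos is not None:
            self._pairs_pos *= scale

    # -- runs -----------------------------------------------------------
    def run(self, n_steps: int, record_every: int = 0) -> list[ThermoRecord]:
        out: list[ThermoRecord] = []
        for k in range(n_steps):
            self.step()
            if record_every and (k + 1) % record_every == 0:
                out.append(self.record())
        return out


# ----------------------------------------------------------------------
def step_nvt(
    config: SystemConfiguration,
    ff: ForceField,
    settings: IntegratorSettings,
    n_steps: int,
    record_every: int = 10,
) -> list[ThermoRecord]:
    """Advance ``n_steps`` at constant N, V (and T if thermostatted).

    With the thermostat disabled this is exact velocity-Verlet (NVE).
    """
    if settings.barostat != "off":
        raise ValueError("step_nvt requires barostat 'off'")
    engine = MDEngine(config, ff, settings)
    return engine.run(n_steps, record_every)


def step_npt(
    config: SystemConfiguration,
    ff: ForceField,
    settings: IntegratorSettings,
    n_steps: int,
    record_every: int = 10,
) -> list[ThermoRecord]:
    """Advance ``n_steps`` with thermostat and Berendsen barostat."""
    if settings.barostat == "off":
        raise ValueError("step_npt requires a barostat mode")
    engine = MDEngine(config, ff, settings)
    return engine.run(n_steps, record_every)


def sample_frames(
    config: SystemConfiguration,
    ff: ForceField,
    settings: IntegratorSettings,
    n_frames: int,
    steps_between: int,
    n_equil: int = 0,
) -> list[SystemConfiguration]:
    """Decorrelated configuration snapshots from an NVT run.

    Advances ``n_equil`` steps, then collects a copy of the
    configuration every ``steps_between`` steps.  The input
    configuration is advanced in place.
    """
    engine = MDEngine(config, ff, settings)
    engine.run(n_equil)
    frames = []
    for _ in range(n_frames):
        engine.run(steps_between)
        frames.append(engine.config.copy())
    return frames


def push_off(
    config: SystemConfiguration,
    ff: ForceField,
    n_steps: int = 200,
    max_move: float = 0.05,
) -> None:
    """Displacement-capped steepest descent to relax overlaps in place.

    Used to make freshly built (random-walk) networks integrable before
    any dynamics; moves each particle along its force, at most
    ``max_move`` per sweep.
    """
    for _ in range(n_steps):
        pairs = build_neighbor_list(config, ff.r_list)
        sp = ff.species_index(config.species)
        pi = np.ascontiguousarray(pairs[:, 0]) if pairs.size else np.empty(0, np.intp)
        pj = np.ascontiguousarray(pairs[:, 1]) if pairs.size else np.empty(0, np.intp)
        # arbitrarily large overlap forces are tolerated because each
        # sweep caps the displacement, not the force
        f, _, _, _, _ = lj_pair_kernel(
            config.positions, pi, pj, sp, ff.eps_table, ff.sig_table,
            config.box, ff.r_cut, -2, 1.0, 0.0,
        )
        bonds = config.all_bonds()
        if bonds.size:
            fb, _, _ = bond_kernel(
                config.positions, np.ascontiguousarray(bonds), ff.bond_k,
                ff.bond_r0, config.box,
            )
            f += fb
        norm = np.linalg.norm(f, axis=1, keepdims=True)
        step = f * (max_move / np.maximum(norm, max_move / 0.02))
        config.positions += step
        config.wrap()


def minimize_fire(
    config: SystemConfiguration,
    ff: ForceField,
    max_steps: int = 3000,
    f_tol: float = 0.05,
    dt_start: float = 0.002,
    dt_max: float = 0.02,
) -> float:
    """FIRE energy minimization in place; returns the final max force.

    Fast inertial relaxation: velocity-projected damped dynamics with
    adaptive time step.  Used to take a glassy sample to its inherent
    structure before athermal elastic measurements.
    """
    v = np.zeros_like(config.positions)
    dt = dt_start
    alpha = 0.1
    n_good = 0
    pairs = build_neighbor_list(config, ff.r_list)
    ref = config.positions.copy()
    f, _, _ = compute_forces(config, ff, pairs)
    for _ in range(max_steps):
        power = float(np.sum(f * v))
        if power > 0:
            n_good += 1
            fnorm = np.linalg.norm(f)
            vnorm = np.linalg.norm(v)
            if fnorm > 0:
                v = (1 - alpha) * v + alpha * vnorm * f / fnorm
            if n_good > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha = 0.1
            n_good = 0
        v += dt * f
        config.positions += dt * v
        disp = config.positions - ref
        disp -= config.box * np.round(disp / config.box)
        if np.sqrt((disp**2).sum(axis=1).max()) > 0.5 * (ff.r_list - ff.r_cut):
            config.wrap()
            pairs = build_neighbor_list(config, ff.r_list)
            ref = config.positions.copy()
        f, _, _ = compute_forces(config, ff, pairs)
        fmax = float(np.sqrt((f**2).sum(axis=1).max()))
        if fmax < f_tol:
            break
    config.wrap()
    return fmax


def athermal_axial_stiffness(
    config: SystemConfiguration,
    ff: ForceField,
    axis: int = 2,
    delta: float = 0.004,
    f_tol: float = 0.05,
) -> float:
    """Athermal quasi-static axial stiffness of a glassy sample.

    Minimizes the configuration, applies affine strains of +/-``delta``
    along ``axis`` (transverse box fixed), re-minimizes, and returns the
    central-difference slope of the axial virial stress.  Free of
    thermal noise, so it resolves stiffness differences that a small
    finite-temperature tensile run cannot.
    """

    def axial_stress(c: SystemConfiguration) -> float:
        pairs = build_neighbor_list(c, ff.r_list)
        _, _, w = compute_forces(c, ff, pairs)
        return -w[axis, axis] / c.volume

    base = config.copy()
    minimize_fire(base, ff, f_tol=f_tol)
    stresses = []
    for sgn in (+1, -1):
        c = base.copy()
        scale = 1.0 + sgn * delta
        c.positions[:, axis] *= scale
        c.box[axis] *= scale
        minimize_fire(c, ff, max_steps=1500, f_tol=f_tol)
        stresses.append(axial_stress(c))
    return (stresses[0] - stresses[1]) / (2.0 * delta)


def deform_uniaxial(
    config: SystemConfiguration,
    ff: ForceField,
    settings: IntegratorSettings,
    rate: float,
    max_strain: float,
    axis: int = 2,
    record_every: int = 50,
    frame_every: int = 0,
):
    """Constant-rate uniaxial tension with affine rescaling.

    The box length along ``axis`` grows by ``rate*dt`` each step and all
    coordinates are rescaled accordingly; the two transverse axes couple
    to a semi-isotropic Berendsen barostat (the pulled axis follows the
    imposed schedule only).  Stress is the negative axial diagonal
    pressure-tensor component (tension positive); each recorded sample
    is the average over its ``record_every``-step interval (instantaneous
    stress in a small box is noise-dominated), and the recorded strain
    and transverse length are the interval midpoints.

    Returns (StressStrainCurve, records, frames); ``frames`` are copies
    of the configuration sampled every ``frame_every`` recorded samples
    (empty when 0).  If the dynamics fail mid-pull the partial curve is
    returned with ``metadata['failed'] = True``.
    """
    from .mechanics import StressStrainCurve

    settings = replace(
        settings, barostat="semi-isotropic", frozen_axis=axis
    )
    engine = MDEngine(config, ff, settings)
    l0 = float(config.box[axis])
    tr_axes = [ax for ax in range(3) if ax != axis]
    # unstrained sample
    rec0 = engine.record()
    strain = [0.0]
    stress = [-rec0.pressure_tensor[axis]]
    l_perp = [float(np.sqrt(np.prod(rec0.box[tr_axes])))]
    frames = []
    if frame_every:
        frames.append(engine.config.copy())
    failed = False
    records = [rec0]
    n_rec = 0
    try:
        while (engine.config.box[axis] - l0) / l0 < max_strain:
            acc_stress = 0.0
            acc_strain = 0.0
            acc_lperp = 0.0
            for _ in range(record_every):
                # impose the pulling schedule, then integrate
                scale = np.ones(3)
                scale[axis] = (
                    engine.config.box[axis] + rate * settings.dt
                ) / engine.config.box[axis]
                engine.config.box = engine.config.box * scale
                engine.config.positions[:, axis] *= scale[axis]
                if engine._pairs_pos is not None:
                    engine._pairs_pos[:, axis] *= scale[axis]
                engine.step()
                p = engine.pressure_tensor()
                acc_stress += -p[axis]
                acc_strain += (engine.config.box[axis] - l0) / l0
                acc_lperp += float(
                    np.sqrt(np.prod(engine.config.box[tr_axes]))
                )
            rec = engine.record()
            records.append(rec)
            strain.append(acc_strain / record_every)
            stress.append(acc_stress / record_every)
            l_perp.append(acc_lperp / record_every)
            n_rec += 1
            if frame_every and n_rec % frame_every == 0:
                frames.append(engine.config.copy())
    except FloatingPointError:
        failed = True
    curve = StressStrainCurve(
        strain=np.array(strain),
        stress=np.array(stress),
        l_perp=np.array(l_perp),
        sampling_interval=record_every * settings.dt,
    )
    curve.metadata["failed"] = failed
    curve.metadata["axis"] = axis
    curve.metadata["rate"] = rate
    return curve, records, frames
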