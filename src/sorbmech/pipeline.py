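"""Desk-scale end-to-end studies on the coarse cross-linked network.

These drive the full chain — build network, add solvent, anneal and
quench, then measure — at sizes that run in seconds to minutes.  They
are the package's stand-in for the cluster-scale humidity studies: the
absolute numbers are in reduced units and not comparable to laboratory
moduli, but the *trends* with solvent content (softening, delayed
void-driven failure, swelling) are the quantities of interest.

The toy conditions are fixed here in one place: a 288-bead network
(8 chains x 36 residues, 8 cross-linkable sites per chain, half of
them bridged), solvent beads of diameter 0.8 that cohere with each
other (eps 0.6) but wet the matrix only weakly (cross eps 0.35), a
quench from T = 0.8 through 0.3 to 0.2 at zero pressure, athermal
quasi-static stiffness readout, and a fast tensile pull with a sluggish
transverse barostat for the cavitation/failure readout.
"""

from __future__ import annotations

import numpy as np

from .forcefield import ForceField
from .md import (
    IntegratorSettings,
    athermal_axial_stiffness,
    deform_uniaxial,
    push_off,
    step_npt,
    step_nvt,
)
from .mechanics import VoidTrace, failure_point, largest_void
from .synthetic import NetworkSpec, build_network, insert_solvent
from .system import SystemConfiguration

__all__ = [
    "toy_forcefield",
    "prepare_toy_sample",
    "toy_tensile_study",
    "toy_swelling_series",
]

#: quench temperature of the toy glass (reduced units)
TOY_TEMPERATURE = 0.2
#: solvent contents (bead counts) of the dry / moderate / high states
TOY_CONTENTS = (0, 70, 150)


def toy_forcefield() -> ForceField:
    """Force field of the toy humidity study.

    Matrix beads are standard LJ (eps = sigma = 1); solvent beads are
    smaller (sigma 0.8) and mutually cohesive (eps 0.6) but only weakly
    attracted to the matrix (cross eps 0.35 < Lorentz-Berthelot), so at
    high content the solvent pools into pockets — the coarse analogue
    of multilayer water clustering in a swollen protein matrix.
    """
    return ForceField(
        epsilon={"backbone": 1.0, "cys": 1.0, "solvent": 0.6},
        sigma={"backbone": 1.0, "cys": 1.0, "solvent": 0.8},
        pair_overrides={
            ("backbone", "solvent"): (0.35, 0.9),
            ("cys", "solvent"): (0.35, 0.9),
        },
        bond_k=500.0,
        r_cut=1.5,
        r_list=1.8,
    )


def prepare_toy_sample(
    n_solvent: int,
    seed: int,
    n_chains: int = 8,
    chain_length: int = 36,
) -> tuple[SystemConfiguration, ForceField]:
    """Build, solvate, anneal and quench one toy glass sample.

    Anneal at T = 0.8 (NVT), then cool under zero pressure through
    T = 0.3 to the working temperature 0.2.
    """
    spec = NetworkSpec(
        n_chains=n_chains, chain_length=chain_length, n_cys_per_chain=8,
        crosslink_fraction=0.5, seed=seed, reduced_density=1.0,
    )
    cfg = build_network(spec)
    ff = toy_forcefield()
    if n_solvent:
        cfg = insert_solvent(cfg, n_solvent, seed=seed + 1, min_distance=0.7)
    push_off(cfg, ff, 300)
    st = IntegratorSettings(dt=0.004, t_target=0.8, thermostat=True, seed=seed)
    step_nvt(cfg, ff, st, 4000, record_every=0)
    for t_stage in (0.3, TOY_TEMPERATURE):
        cfg.velocities *= np.sqrt(t_stage / st.t_target)
        st = IntegratorSettings(
            dt=0.004, t_target=t_stage, thermostat=True,
            barostat="isotropic", p_target=0.0, compressibility=0.05,
            seed=seed,
        )
        step_npt(cfg, ff, st, 4000, record_every=0)
    return cfg, ff


def _polymer_only(cfg: SystemConfiguration) -> SystemConfiguration:
    keep = cfg.species != "solvent"
    return SystemConfiguration(
        positions=cfg.positions[keep],
        species=cfg.species[keep],
        bonds=np.empty((0, 2), dtype=np.intp),
        crosslinks=np.empty((0, 2), dtype=np.intp),
        box=cfg.box.copy(),
    )


def toy_tensile_study(
    seed: int,
    contents: tuple[int, ...] = TOY_CONTENTS,
    max_strain: float = 1.25,
    void_grid: float = 0.15,
    void_probe: float = 0.45,
) -> list[dict]:
    """Stiffness and void-based failure vs solvent content.

    For each content: the sample's axial stiffness (athermal
    quasi-static, averaged over the three axes) and the failure strain
    from the ten-fold largest-void criterion during a fast tensile pull
    (rate 0.06, sluggish transverse barostat).  Voids are measured on
    the polymer matrix only — a solvent-filled pocket counts as a
    cavity, as sorbed solvent lines cavity surfaces rather than closing
    them.  The unstrained void volume is floored at one probe-sphere
    volume (the detection resolution).  A run whose void never reaches
    ten times its unstrained value within ``max_strain`` reports
    ``failure_strain = None`` (no failure within the pull).
    """
    results = []
    for n_solv in contents:
        cfg, ff = prepare_toy_sample(n_solv, seed)
        stiff = float(
            np.mean([
                athermal_axial_stiffness(cfg, ff, axis=ax) for ax in range(3)
            ])
        )
        st = IntegratorSettings(
            dt=0.004, t_target=TOY_TEMPERATURE, thermostat=True,
            p_target=0.0, compressibility=0.002, seed=seed + 4,
        )
        curve, _, frames = deform_uniaxial(
            cfg.copy(), ff, st, rate=0.06, max_strain=max_strain,
            record_every=100, frame_every=5,
        )
        vols = np.array([
            largest_void(_polymer_only(fr), void_grid, void_probe)[0]
            for fr in frames
        ])
        fr_strain = curve.strain[::5][: len(frames)]
        v0 = max(float(vols[0]), 4.0 / 3.0 * np.pi * void_probe**3)
        trace = VoidTrace(
            strain=fr_strain, volume=vols, v0=v0,
            grid_spacing=void_grid, probe_radius=void_probe,
        )
        hit = failure_point(trace, curve)
        results.append(
            {
                "n_solvent": n_solv,
                "content_fraction": n_solv / (cfg.n_particles - n_solv)
                if cfg.n_particles > n_solv
                else 0.0,
                "stiffness": stiff,
                "v0": v0,
                "failure_strain": None if hit is None else hit[0],
                "failure_stress": None if hit is None else hit[1],
                "curve": curve,
                "void_trace": trace,
            }
        )
    return results


def toy_swelling_series(
    seed: int,
    contents: tuple[int, ...] = (0, 30, 60, 90, 120),
    n_chains: int = 6,
    chain_length: int = 24,
    temperature: float = 0.3,
) -> list[dict]:
    """Equilibrium NPT volume vs solvent content for the swelling check.

    Smaller and warmer than the tensile toy: volumes equilibrate fast
    at T = 0.3 and zero pressure.  Returns per-content dry-referenced
    swelling ratios.
    """
    vols = []
    for n_solv in contents:
        spec = NetworkSpec(
            n_chains=n_chains, chain_length=chain_length,
            n_cys_per_chain=6, crosslink_fraction=0.5, seed=seed,
            reduced_density=1.0,
        )
        cfg = build_network(spec)
        ff = toy_forcefield()
        if n_solv:
            cfg = insert_solvent(cfg, n_solv, seed=seed + 1, min_distance=0.7)
        push_off(cfg, ff, 300)
        st = IntegratorSettings(
            dt=0.004, t_target=0.8, thermostat=True, seed=seed
        )
        step_nvt(cfg, ff, st, 2000, record_every=0)
        cfg.velocities *= np.sqrt(temperature / 0.8)
        st = IntegratorSettings(
            dt=0.004, t_target=temperature, thermostat=True,
            barostat="isotropic", p_target=0.0, compressibility=0.05,
            seed=seed,
        )
        recs = step_npt(cfg, ff, st, 6000, record_every=10)
        v = float(np.mean([np.prod(r.box) for r in recs[len(recs) // 2:]]))
        vols.append({"n_solvent": n_solv, "volume": v})
    v_dry = vols[0]["volume"]
    from .sorption import swelling_ratio

    for rec in vols:
        rec["swelling_percent"] = swelling_ratio(rec["volume"], v_dry)
    return vols
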