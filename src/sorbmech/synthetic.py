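"""Coarse-grained network builder and ground-truth analysis fixtures.

The builder emulates the amorphous, disulfide-cross-linked part of a
structural protein as a bead-spring network: linear chains of backbone
beads with cysteine-like cross-linkable sites evenly interspersed, a
prescribed fraction of which are bridged pairwise.  The reference
topology (18 chains x 96 residues, 22 cys-like sites per chain, 33% of
them bridged) gives ~7.5% cross-linked residues and a mean strand of
~13 residues between consecutive bridges.

The remaining generators produce analysis fixtures with known ground
truth: piecewise-linear stress-strain curves, planted spherical
cavities, and largest-void traces with a known ten-fold crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mechanics import StressStrainCurve, VoidTrace
from .system import SystemConfiguration, minimum_image

__all__ = [
    "NetworkSpec",
    "SynthCurveSpec",
    "build_network",
    "insert_solvent",
    "plant_cavity",
    "synth_stress_strain",
    "synth_void_trace",
]

#: reduced bond length between consecutive backbone beads
BOND_LENGTH = 1.0
#: minimum insertion distance for solvent, in units of the bead diameter;
#: chosen below contact to avoid force blow-ups at start-up
MIN_INSERT_FACTOR = 0.85


@dataclass(frozen=True)
class NetworkSpec:
    """Topology specification of the coarse cross-linked network.

    ``crosslink_fraction`` is the fraction of cross-linkable (cys-like)
    sites that participate in a bridge — each bridge consumes two sites.
    ``reduced_density`` is beads per unit volume in reduced units.
    """

    n_chains: int = 18
    chain_length: int = 96
    n_cys_per_chain: int = 22
    crosslink_fraction: float = 0.33
    seed: int = 0
    reduced_density: float = 0.85
    bridge_mode: str = "inter"  # 'inter' (preferred), 'any', 'intra'

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0.0 <= self.crosslink_fraction <= 1.0:
            raise ValueError("crosslink_fraction must be in [0, 1]")
        if self.n_cys_per_chain > self.chain_length:
            raise ValueError("n_cys_per_chain cannot exceed chain_length")
        if self.reduced_density <= 0:
            raise ValueError("reduced_density must be positive")
        if self.bridge_mode not in ("inter", "any", "intra"):
            raise ValueError("bridge_mode must be 'inter', 'any' or 'intra'")

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.chain_length


def _cys_indices(chain_length: int, n_cys: int) -> np.ndarray:
    """Evenly interspersed cross-linkable site indices along one chain."""
    return np.floor((np.arange(n_cys) + 0.5) * chain_length / n_cys).astype(int)


def build_network(spec: NetworkSpec) -> SystemConfiguration:
    """Build the bead-spring cross-linked network.

    Chains are grown as fixed-bond-length random walks inside a cubic box
    whose volume matches ``reduced_density``.  Bridges are placed greedily
    between spatially proximate unbridged cys sites (minimum-image
    distance), inter-chain pairs preferred by default; each site joins at
    most one bridge.  The number of bridged sites is
    round(crosslink_fraction * n_cys_per_chain * n_chains) floored to an
    even number, so the cross-linked residue fraction matches the
    bookkeeping fraction within rounding.

    Build statistics (cross-linked residue fraction, mean strand length)
    are stored in ``config.metadata['topology_stats']``.
    """
    rng = np.random.default_rng(spec.seed)
    L = (spec.n_beads / spec.reduced_density) ** (1.0 / 3.0)
    box = np.full(3, L)

    positions = np.empty((spec.n_beads, 3))
    bonds = []
    species = np.array(["backbone"] * spec.n_beads, dtype=object)
    cys_sites = []
    site_chain = []
    cys_local = _cys_indices(spec.chain_length, spec.n_cys_per_chain)

    for c in range(spec.n_chains):
        start = c * spec.chain_length
        pos = rng.uniform(0, L, size=3)
        positions[start] = pos
        for i in range(1, spec.chain_length):
            step = rng.normal(size=3)
            step *= BOND_LENGTH / np.linalg.norm(step)
            pos = pos + step
            positions[start + i] = pos
            bonds.append((start + i - 1, start + i))
        for loc in cys_local:
            gid = start + int(loc)
            species[gid] = "cys"
            cys_sites.append(gid)
            site_chain.append(c)

    cys_sites = np.array(cys_sites, dtype=np.intp)
    site_chain = np.array(site_chain, dtype=np.intp)

    n_sites_target = int(
        round(spec.crosslink_fraction * spec.n_cys_per_chain * spec.n_chains)
    )
    if n_sites_target < 1:
        if spec.crosslink_fraction > 0:
            warnings.warn(
                "crosslink_fraction too small for a single bridge; "
                "building an uncross-linked network",
                stacklevel=2,
            )
        n_bridges = 0
    else:
        n_bridges = n_sites_target // 2

    crosslinks = _place_bridges(
        positions, box, cys_sites, site_chain, n_bridges, spec.bridge_mode,
        seed=spec.seed,
    )

    config = SystemConfiguration(
        positions=positions,
        species=species,
        bonds=np.array(bonds, dtype=np.intp).reshape(-1, 2),
        crosslinks=crosslinks,
        box=box,
    )
    config.wrap()

    n_linked = 2 * len(crosslinks)
    stats = {
        "n_bridges": int(len(crosslinks)),
        "n_crosslinked_residues": n_linked,
        "crosslinked_residue_fraction": n_linked / spec.n_beads,
        "crosslinked_residue_percent": 100.0 * n_linked / spec.n_beads,
        "mean_strand_length": (
            spec.chain_length / (n_linked / spec.n_chains)
            if n_linked
            else float("inf")
        ),
    }
    config.metadata["topology_stats"] = stats
    config.metadata["cys_indices"] = cys_sites.tolist()
    config.metadata["network_spec"] = spec
    return config


def _place_bridges(
    positions: np.ndarray,
    box: np.ndarray,
    sites: np.ndarray,
    site_chain: np.ndarray,
    n_bridges: int,
    mode: str,
    seed: int,
) -> np.ndarray:
    """Greedy proximity pairing of cys sites, each in at most one bridge."""
    if n_bridges == 0:
        return np.empty((0, 2), dtype=np.intp)
    if 2 * n_bridges > len(sites):
        raise RuntimeError(
            f"infeasible bridge placement: {n_bridges} bridges requested for "
            f"{len(sites)} sites (seed {seed})"
        )
    dr = minimum_image(positions[sites][:, None] - positions[sites][None, :], box)
    dist = np.linalg.norm(dr, axis=-1)
    iu, ju = np.triu_indices(len(sites), k=1)
    same_chain = site_chain[iu] == site_chain[ju]
    if mode == "inter":
        # inter-chain pairs considered first, each group by distance
        order = np.lexsort((dist[iu, ju], same_chain))
    elif mode == "intra":
        order = np.lexsort((dist[iu, ju], ~same_chain))
    else:
        order = np.argsort(dist[iu, ju])

    used = np.zeros(len(sites), dtype=bool)
    bridges = []
    for k in order:
        a, b = iu[k], ju[k]
        if used[a] or used[b]:
            continue
        used[a] = used[b] = True
        bridges.append((sites[a], sites[b]))
        if len(bridges) == n_bridges:
            break
    if len(bridges) < n_bridges:
        raise RuntimeError(
            f"infeasible bridge placement after exhausting candidate pairs "
            f"(seed {seed})"
        )
    return np.array(bridges, dtype=np.intp)


# ----------------------------------------------------------------------
def insert_solvent(
    config: SystemConfiguration,
    n_solvent: int,
    seed: int = 0,
    min_distance: float | None = None,
    max_tries_per_particle: int = 2000,
) -> SystemConfiguration:
    """Insert single-bead solvent particles, rejecting close overlaps.

    Candidate positions are drawn uniformly in the box and accepted when
    no existing particle (network or previously inserted solvent) lies
    within ``min_distance`` (default 0.85 x bead diameter).
    """
    if n_solvent < 0:
        raise ValueError("n_solvent must be non-negative")
    if n_solvent == 0:
        return config.copy()
    if min_distance is None:
        min_distance = MIN_INSERT_FACTOR * BOND_LENGTH

    rng = np.random.default_rng(seed)
    out = config.copy()
    out.wrap()
    existing = [out.positions]
    tree = cKDTree(out.positions % out.box, boxsize=out.box)
    placed: list[np.ndarray] = []
    ptree: cKDTree | None = None
    for i in range(n_solvent):
        for attempt in range(max_tries_per_particle):
            cand = rng.uniform(0, 1, size=3) * out.box
            d, _ = tree.query(cand, k=1)
            if d < min_distance:
                continue
            if placed:
                if ptree is None:
                    ptree = cKDTree(np.array(placed), boxsize=out.box)
                dp, _ = ptree.query(cand, k=1)
                if dp < min_distance:
                    continue
            placed.append(cand)
            ptree = None  # rebuilt lazily; n_solvent is modest
            break
        else:
            raise RuntimeError(
                f"solvent insertion failed for particle {i} after "
                f"{max_tries_per_particle} tries (box too dense)"
            )
    placed_arr = np.array(placed)
    out.positions = np.vstack([out.positions, placed_arr])
    out.species = np.concatenate(
        [out.species, np.array(["solvent"] * n_solvent, dtype=object)]
    )
    if out.velocities is not None:
        out.velocities = np.vstack([out.velocities, np.zeros((n_solvent, 3))])
    out.validate()
    return out


def plant_cavity(
    config: SystemConfiguration, centre, radius: float
) -> SystemConfiguration:
    """Remove every particle within ``radius`` of ``centre``.

    The cavity sphere must fit inside the box.  Cavity metadata (centre,
    radius, number removed) is recorded on the returned configuration.
    Topology indices are remapped; bonds touching removed particles drop.
    """
    if radius <= 0:
        raise ValueError("cavity radius must be positive")
    centre = np.asarray(centre, dtype=float)
    if 2 * radius > np.min(config.box):
        raise ValueError("cavity sphere does not fit in the box")
    dr = minimum_image(config.positions - centre, config.box)
    keep = np.linalg.norm(dr, axis=1) >= radius
    remap = -np.ones(config.n_particles, dtype=np.intp)
    remap[keep] = np.arange(keep.sum())

    def _remap_pairs(pairs: np.ndarray) -> np.ndarray:
        if pairs.size == 0:
            return pairs
        ok = keep[pairs[:, 0]] & keep[pairs[:, 1]]
        return remap[pairs[ok]]

    out = SystemConfiguration(
        positions=config.positions[keep],
        species=config.species[keep],
        bonds=_remap_pairs(config.bonds),
        crosslinks=_remap_pairs(config.crosslinks),
        box=config.box.copy(),
        periodic=config.periodic.copy(),
        velocities=None if config.velocities is None else config.velocities[keep],
        metadata=dict(config.metadata),
    )
    out.metadata["cavity"] = {
        "centre": centre.tolist(),
        "radius": float(radius),
        "n_removed": int((~keep).sum()),
    }
    return out


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SynthCurveSpec:
    """Ground-truth parameters of a synthetic piecewise-linear tensile curve.

    The elastic branch has slope ``elastic_modulus`` through the origin;
    the hardening branch is ``hardening_intercept + hardening_modulus *
    strain``.  If ``yield_strain`` is None the generator switches branches
    at their intersection (continuous curve); if ``hardening_intercept``
    is None it is chosen for continuity at ``yield_strain``.  Optional
    ``poisson_ratio`` plants a transverse response L_perp = L0*(1 - nu*eps).
    """

    elastic_modulus: float
    hardening_modulus: float = 0.0
    hardening_intercept: float | None = None
    yield_strain: float | None = None
    noise_sd: float = 0.0
    seed: int = 0
    poisson_ratio: float | None = None

    def __post_init__(self) -> None:
        if not self.elastic_modulus > self.hardening_modulus >= 0:
            raise ValueError("require elastic_modulus > hardening_modulus >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.hardening_intercept is None and self.yield_strain is None:
            raise ValueError("give yield_strain or hardening_intercept")

    @property
    def switch_strain(self) -> float:
        if self.yield_strain is not None:
            return self.yield_strain
        return self.hardening_intercept / (
            self.elastic_modulus - self.hardening_modulus
        )

    @property
    def intercept(self) -> float:
        if self.hardening_intercept is not None:
            return self.hardening_intercept
        return (self.elastic_modulus - self.hardening_modulus) * self.yield_strain

    @property
    def analytic_yield(self) -> tuple[float, float]:
        """Intersection of the two branch lines (strain, stress)."""
        eps = self.intercept / (self.elastic_modulus - self.hardening_modulus)
        return eps, self.elastic_modulus * eps


def synth_stress_strain(
    spec: SynthCurveSpec, strain_grid: np.ndarray
) -> StressStrainCurve:
    """Piecewise-linear stress-strain fixture with optional Gaussian noise."""
    eps = np.asarray(strain_grid, dtype=float)
    if eps.size == 0 or eps[0] != 0.0 or np.any(np.diff(eps) <= 0):
        raise ValueError("strain grid must increase strictly from 0")
    stress = np.where(
        eps < spec.switch_strain,
        spec.elastic_modulus * eps,
        spec.intercept + spec.hardening_modulus * eps,
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_sd, size=eps.shape)
    l_perp = None
    if spec.poisson_ratio is not None:
        l_perp = 1.0 - spec.poisson_ratio * eps
    curve = StressStrainCurve(strain=eps, stress=stress, l_perp=l_perp)
    curve.metadata["ground_truth"] = spec
    return curve


def synth_void_trace(
    v0: float,
    growth_profile,
    strain_grid: np.ndarray,
) -> VoidTrace:
    """Largest-void-volume fixture with a known ten-fold crossing.

    ``growth_profile`` maps strain to absolute largest-void volume; it is
    evaluated on ``strain_grid``.  The first grid point at or above
    10*v0 (if any) is stored as ``metadata['crossing_strain']``.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    eps = np.asarray(strain_grid, dtype=float)
    vol = np.asarray([growth_profile(e) for e in eps], dtype=float)
    trace = VoidTrace(strain=eps, volume=vol, v0=v0)
    hit = np.flatnonzero(vol >= 10.0 * v0)
    trace.metadata["crossing_strain"] = (
        float(eps[hit[0]]) if hit.size else None
    )
    return trace
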