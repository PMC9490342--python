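"""Particle-system container shared by every simulation stage.

A :class:`SystemConfiguration` holds positions, per-particle species labels,
the bonded topology (chain bonds and disulfide-like cross-links), and an
orthorhombic periodic box.  All coordinates are in reduced length units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: species labels used by the coarse network
SPECIES = ("backbone", "cys", "solvent")


def minimum_image(dr: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Valid for orthorhombic boxes with all edges at least twice the largest
    interaction range.
    """
    return dr - box * np.round(dr / box)


@dataclass
class SystemConfiguration:
    """Positions, species, topology and periodic box of one configuration.

    Attributes
    ----------
    positions : (N, 3) float array, reduced length units, wrapped into box
    species : (N,) array of str, one of :data:`SPECIES`
    bonds : (Nb, 2) int array of chain bonds, each pair sorted, no duplicates
    crosslinks : (Nx, 2) int array of cys–cys bridges, same conventions
    box : (3,) float array of edge lengths
    periodic : (3,) bool array, per-axis periodicity flag
    velocities : optional (N, 3) float array
    metadata : free-form dict (cavity records, build statistics, ...)
    """

    positions: np.ndarray
    species: np.ndarray
    bonds: np.ndarray
    crosslinks: np.ndarray
    box: np.ndarray
    periodic: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=bool))
    velocities: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.species = np.asarray(self.species, dtype=object)
        self.bonds = np.asarray(self.bonds, dtype=np.intp).reshape(-1, 2)
        self.crosslinks = np.asarray(self.crosslinks, dtype=np.intp).reshape(-1, 2)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.periodic = np.asarray(self.periodic, dtype=bool).reshape(3)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def all_bonds(self) -> np.ndarray:
        """Chain bonds and cross-links as one (M, 2) array."""
        if self.crosslinks.size == 0:
            return self.bonds
        if self.bonds.size == 0:
            return self.crosslinks
        return np.vstack([self.bonds, self.crosslinks])

    def species_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.species == name)

    # ------------------------------------------------------------------
    def wrap(self) -> None:
        """Wrap all positions into [0, box) on periodic axes."""
        for ax in range(3):
            if self.periodic[ax]:
                self.positions[:, ax] %= self.box[ax]

    def validate(self) -> None:
        n = self.n_particles
        if self.species.shape[0] != n:
            raise ValueError("species length does not match positions")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        for pairs, what in ((self.bonds, "bond"), (self.crosslinks, "crosslink")):
            if pairs.size == 0:
                continue
            if np.any(pairs[:, 0] == pairs[:, 1]):
                raise ValueError(f"self-{what} detected")
            if np.any(pairs < 0) or np.any(pairs >= n):
                raise ValueError(f"{what} index out of range")
            canon = np.sort(pairs, axis=1)
            if len(np.unique(canon, axis=0)) != len(canon):
                raise ValueError(f"duplicate {what} detected")

    def copy(self) -> "SystemConfiguration":
        return SystemConfiguration(
            positions=self.positions.copy(),
            species=self.species.copy(),
            bonds=self.bonds.copy(),
            crosslinks=self.crosslinks.copy(),
            box=self.box.copy(),
            periodic=self.periodic.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            metadata=dict(self.metadata),
        )
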