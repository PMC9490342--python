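"""Uniaxial-deformation protocol and mechanical observables.

This module turns tensile simulations (or synthetic fixtures) into the
standard humidity-mechanics observables for glassy polymer networks:

* engineering strain  eps(t) = (L_par(t) - L_par(0)) / L_par(0),
* axial stress, taken as the negative axial diagonal component of the
  pressure tensor (tension positive),
* Young's modulus E from the linear elastic regime (strain < 0.02),
* the yield point as the intersection of tangents to the elastic and
  strain-hardening branches,
* Poisson's ratio  nu = -(transverse strain)/(axial strain) over the
  elastic window, with L_perp = sqrt(A),
* grid-based largest-void tracking and the ten-fold-void failure
  criterion, and
* radial density profiles around a cavity centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .system import SystemConfiguration, minimum_image

__all__ = [
    "StressStrainCurve",
    "MechanicalSummary",
    "VoidTrace",
    "DensityProfile",
    "youngs_modulus",
    "yield_point",
    "poisson_ratio",
    "largest_void",
    "failure_point",
    "cavity_density_profile",
    "deform_uniaxial",
]


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class StressStrainCurve:
    """Strain, axial stress and transverse box length of a tensile run.

    ``strain`` starts at 0 and is non-decreasing; ``l_perp`` is the
    geometric transverse length sqrt(A) with A the cross-section area.
    All series share one length; units are whatever the producer used
    (reduced units for the simulator, arbitrary for fixtures).
    """

    strain: np.ndarray
    stress: np.ndarray
    l_perp: np.ndarray | None = None
    sampling_interval: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must have equal length")
        if self.strain.size and self.strain[0] != 0.0:
            raise ValueError("strain series must start at 0")
        if np.any(np.diff(self.strain) < 0):
            raise ValueError("strain series must be non-decreasing")
        if self.l_perp is not None:
            self.l_perp = np.asarray(self.l_perp, dtype=float)
            if self.l_perp.shape != self.strain.shape:
                raise ValueError("l_perp length mismatch")


@dataclass
class MechanicalSummary:
    """Scalar mechanical characterization of one tensile run."""

    youngs_modulus: float
    yield_stress: float | None = None
    yield_strain: float | None = None
    failure_stress: float | None = None
    failure_strain: float | None = None
    poisson_ratio: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        nu = self.poisson_ratio
        if nu is not None and not (0.0 <= nu <= 0.5):
            warnings.warn(
                f"Poisson's ratio {nu:.3f} outside the expected [0, 0.5] range",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {
            "youngs_modulus": self.youngs_modulus,
            "yield_stress": self.yield_stress,
            "yield_strain": self.yield_strain,
            "failure_stress": self.failure_stress,
            "failure_strain": self.failure_strain,
            "poisson_ratio": self.poisson_ratio,
            **self.extra,
        }


@dataclass
class VoidTrace:
    """Largest-cavity volume as a function of strain."""

    strain: np.ndarray
    volume: np.ndarray
    v0: float
    grid_spacing: float | None = None
    probe_radius: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.strain.shape != self.volume.shape:
            raise ValueError("strain and volume must have equal length")
        if np.any(self.volume < 0):
            raise ValueError("void volumes must be non-negative")
        if self.v0 <= 0:
            raise ValueError("unstrained void volume v0 must be positive")


@dataclass
class DensityProfile:
    """Normalized radial number densities around a cavity centre."""

    bin_centers: np.ndarray
    profiles: dict[str, np.ndarray]
    raw_counts: dict[str, np.ndarray] = field(default_factory=dict)
    bulk_density: dict[str, float] = field(default_factory=dict)


# ----------------------------------------------------------------------
# elastic constants
# ----------------------------------------------------------------------
def youngs_modulus(
    curve: StressStrainCurve, strain_cap: float = 0.02
) -> tuple[float, float, tuple[int, int]]:
    """Young's modulus from the low-strain linear regime.

    Fits an unconstrained least-squares line (free intercept) to all
    samples with strain < ``strain_cap``; stress varies linearly with
    strain in this window for a glassy network.

    Returns
    -------
    (slope, stderr, window) where window = (first index, one past last).
    """
    mask = curve.strain < strain_cap
    n = int(mask.sum())
    if n < 5:
        raise ValueError(
            f"need at least 5 samples below strain {strain_cap}, got {n}"
        )
    x = curve.strain[mask]
    y = curve.stress[mask]
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    dof = max(n - 2, 1)
    sse = float(res[0]) if res.size else float(np.sum((A @ coef - y) ** 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    stderr = np.sqrt(sse / dof / sxx) if sxx > 0 else np.inf
    return slope, float(stderr), (0, n)


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def yield_point(
    curve: StressStrainCurve,
    strain_cap: float = 0.02,
    hardening_window: tuple[float, float] | None = None,
    parallel_tol: float = 1e-9,
) -> tuple[float, float, dict]:
    """Yield point as the intersection of elastic and hardening tangents.

    The elastic tangent is the Young's-modulus fit below ``strain_cap``.
    The hardening tangent is a least-squares line over
    ``hardening_window`` (strain interval); by default the final third of
    the recorded curve.  Returns (yield_strain, yield_stress, info).
    """
    e_slope, _, _ = youngs_modulus(curve, strain_cap)
    mask = curve.strain < strain_cap
    e_inter = _fit_line(curve.strain[mask], curve.stress[mask])[1]

    if hardening_window is None:
        lo = curve.strain[0] + (curve.strain[-1] - curve.strain[0]) * 2.0 / 3.0
        hardening_window = (lo, curve.strain[-1])
    hmask = (curve.strain >= hardening_window[0]) & (
        curve.strain <= hardening_window[1]
    )
    if hmask.sum() < 2:
        raise ValueError("hardening window contains fewer than 2 samples")
    h_slope, h_inter = _fit_line(curve.strain[hmask], curve.stress[hmask])

    if abs(e_slope - h_slope) <= parallel_tol * max(abs(e_slope), 1.0):
        raise ValueError("no intersection: tangents are parallel")
    eps_y = (h_inter - e_inter) / (e_slope - h_slope)
    sig_y = e_slope * eps_y + e_inter
    info = {
        "elastic_slope": e_slope,
        "elastic_intercept": e_inter,
        "hardening_slope": h_slope,
        "hardening_intercept": h_inter,
        "hardening_window": hardening_window,
        "elastic_cap": strain_cap,
    }
    return float(eps_y), float(sig_y), info


def poisson_ratio(curve: StressStrainCurve, strain_cap: float = 0.02) -> float:
    """Poisson's ratio from the elastic window.

    Slope of the transverse contraction -(L_perp(t) - L_perp(0))/L_perp(0)
    against the axial strain, fitted over strains below ``strain_cap``
    (intercept fixed at 0 through the origin of both strains).
    """
    if curve.l_perp is None:
        raise ValueError("curve carries no transverse box lengths")
    mask = curve.strain <= strain_cap
    eps_par = curve.strain[mask]
    if not np.any(eps_par > 0):
        raise ValueError("zero axial strain throughout the elastic window")
    lp0 = curve.l_perp[0]
    eps_perp = -(curve.l_perp[mask] - lp0) / lp0
    # least squares through the origin: both strains vanish at t = 0
    denom = float(np.dot(eps_par, eps_par))
    return float(np.dot(eps_par, eps_perp) / denom)


# ----------------------------------------------------------------------
# voids and failure
# ----------------------------------------------------------------------
#: LJ radius (sigma/2) assumed when a configuration has no per-species table
_DEFAULT_PARTICLE_RADIUS = 0.5


def _occupancy_grid(
    config: SystemConfiguration,
    grid_spacing: float,
    probe_radius: float,
    particle_radii: dict[str, float] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    box = config.box
    shape = np.maximum(np.floor(box / grid_spacing).astype(int), 1)
    if int(np.prod(shape)) < 1000:
        raise ValueError(
            f"grid too coarse: {int(np.prod(shape))} voxels < 1000; "
            "decrease grid_spacing"
        )
    spacing = box / shape
    centers = [
        (np.arange(shape[ax]) + 0.5) * spacing[ax] for ax in range(3)
    ]
    mesh = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1).reshape(-1, 3)

    empty = np.ones(mesh.shape[0], dtype=bool)
    pos = config.positions % box
    for name in np.unique(config.species):
        idx = config.species_indices(str(name))
        if idx.size == 0:
            continue
        r_part = (
            particle_radii.get(str(name), _DEFAULT_PARTICLE_RADIUS)
            if particle_radii
            else _DEFAULT_PARTICLE_RADIUS
        )
        tree = cKDTree(pos[idx], boxsize=box)
        d, _ = tree.query(mesh, k=1)
        empty &= d >= (probe_radius + r_part)
    return empty.reshape(tuple(shape)), spacing, mesh.reshape(*shape, 3)


def _label_periodic(empty: np.ndarray) -> tuple[np.ndarray, int]:
    """6-connected labelling of empty voxels with periodic wrapping."""
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(empty, structure=structure)
    if n == 0:
        return labels, 0
    # merge labels across each periodic face with union-find
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for ax in range(3):
        lo = np.take(labels, 0, axis=ax).ravel()
        hi = np.take(labels, -1, axis=ax).ravel()
        both = (lo > 0) & (hi > 0)
        for a, b in zip(lo[both], hi[both]):
            union(int(a), int(b))

    remap = np.array([find(i) for i in range(n + 1)])
    labels = remap[labels]
    return labels, len(np.unique(labels[labels > 0]))


def largest_void(
    config: SystemConfiguration,
    grid_spacing: float = 0.1,
    probe_radius: float = 0.5,
    particle_radii: dict[str, float] | None = None,
    reexpand: bool = True,
) -> tuple[float, np.ndarray]:
    """Volume and centre of the largest cavity in a periodic configuration.

    The box is voxelized at ``grid_spacing``; a voxel belongs to the
    eroded cavity space when no particle centre lies within
    (probe_radius + particle radius) of its centre — i.e. a probe
    sphere centred there fits.  Eroded voxels are clustered by
    6-connectivity with periodic wrapping; the largest cluster is then
    dilated back by the probe radius (morphological opening), so a
    planted spherical cavity of radius R reports (4/3) pi R^3 rather
    than the probe-eroded core.  Volume = voxel count x voxel volume;
    the centre is the eroded cluster's minimum-image centroid.  An
    empty box returns the full box volume; ``reexpand=False`` returns
    the eroded volume.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if config.n_particles == 0:
        return config.volume, config.box / 2.0
    empty, spacing, mesh = _occupancy_grid(
        config, grid_spacing, probe_radius, particle_radii
    )
    labels, n = _label_periodic(empty)
    if n == 0:
        return 0.0, config.box / 2.0
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    best = ids[np.argmax(counts)]
    voxel_vol = float(np.prod(spacing))
    cluster = labels == best
    # minimum-image centroid via circular means per axis
    sel = mesh[cluster]
    centre = np.empty(3)
    for ax in range(3):
        theta = sel[:, ax] / config.box[ax] * 2 * np.pi
        mean = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
        centre[ax] = (mean % (2 * np.pi)) / (2 * np.pi) * config.box[ax]
    if not reexpand:
        return float(counts.max()) * voxel_vol, centre
    # dilate the winning cluster by the probe radius (periodic)
    tree = cKDTree(sel.reshape(-1, 3) % config.box, boxsize=config.box)
    d, _ = tree.query(mesh.reshape(-1, 3), k=1)
    vol = float(np.count_nonzero(d <= probe_radius)) * voxel_vol
    return vol, centre


def failure_point(
    void_trace: VoidTrace,
    curve: StressStrainCurve | None = None,
    threshold_factor: float = 10.0,
) -> tuple[float, float | None] | None:
    """Failure by the ten-fold largest-void criterion.

    Failure is the first recorded strain at which the largest-void volume
    reaches ``threshold_factor`` times its unstrained value (no
    interpolation between frames).  The paired stress is linearly
    interpolated from ``curve`` at that strain.  Returns None when the
    threshold is never crossed within the trace.
    """
    thresh = threshold_factor * void_trace.v0
    crossed = np.flatnonzero(void_trace.volume >= thresh)
    if crossed.size == 0:
        return None
    eps_f = float(void_trace.strain[crossed[0]])
    sigma_f = None
    if curve is not None:
        sigma_f = float(np.interp(eps_f, curve.strain, curve.stress))
    return eps_f, sigma_f


def cavity_density_profile(
    frames: list[SystemConfiguration] | SystemConfiguration,
    centre: np.ndarray,
    bin_width: float,
    selections: dict[str, np.ndarray] | None = None,
    r_max: float | None = None,
    bulk_fraction: float = 0.25,
) -> DensityProfile:
    """Radial number-density profiles about a cavity centre.

    For each named selection (boolean or index array over particles) the
    minimum-image radial number density is histogrammed and normalized by
    that selection's bulk density, estimated as the average over the
    outermost ``bulk_fraction`` of the radial range.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if isinstance(frames, SystemConfiguration):
        frames = [frames]
    box = frames[0].box
    if r_max is None:
        r_max = float(np.min(box)) / 2.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    centers = 0.5 * (edges[:-1] + edges[1:])

    if selections is None:
        selections = {"all": np.arange(frames[0].n_particles)}

    profiles: dict[str, np.ndarray] = {}
    raw: dict[str, np.ndarray] = {}
    bulk: dict[str, float] = {}
    for name, sel in selections.items():
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        if sel.size == 0:
            raise ValueError(f"selection '{name}' is empty")
        counts = np.zeros(len(centers))
        for conf in frames:
            dr = minimum_image(conf.positions[sel] - np.asarray(centre), box)
            r = np.linalg.norm(dr, axis=1)
            h, _ = np.histogram(r, bins=edges)
            counts += h
        counts /= len(frames)
        dens = counts / shell_vol
        n_bulk = max(int(len(centers) * bulk_fraction), 1)
        rho_bulk = float(dens[-n_bulk:].mean())
        if rho_bulk <= 0:
            rho_bulk = float(sel.size) / frames[0].volume
        profiles[name] = dens / rho_bulk
        raw[name] = counts
        bulk[name] = rho_bulk
    return DensityProfile(
        bin_centers=centers, profiles=profiles, raw_counts=raw, bulk_density=bulk
    )


# ----------------------------------------------------------------------
# deformation protocol (implementation lives with the engine)
# ----------------------------------------------------------------------
def deform_uniaxial(*args, **kwargs):
    """Uniaxial tensile run; see :func:`sorbmech.md.deform_uniaxial`."""
    from .md import deform_uniaxial as _impl

    return _impl(*args, **kwargs)


def summarize_curve(
    curve: StressStrainCurve,
    void_trace: VoidTrace | None = None,
    strain_cap: float = 0.02,
    hardening_window: tuple[float, float] | None = None,
) -> MechanicalSummary:
    """All scalar observables of one tensile run in one record."""
    e, e_err, _ = youngs_modulus(curve, strain_cap)
    extra = {"youngs_modulus_stderr": e_err}
    try:
        eps_y, sig_y, _ = yield_point(curve, strain_cap, hardening_window)
    except ValueError:
        eps_y = sig_y = None
    nu = None
    if curve.l_perp is not None:
        nu = poisson_ratio(curve, strain_cap)
    eps_f = sig_f = None
    if void_trace is not None:
        hit = failure_point(void_trace, curve)
        if hit is not None:
            eps_f, sig_f = hit
    return MechanicalSummary(
        youngs_modulus=e,
        yield_stress=sig_y,
        yield_strain=eps_y,
        failure_stress=sig_f,
        failure_strain=eps_f,
        poisson_ratio=nu,
        extra=extra,
    )
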