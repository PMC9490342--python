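# Methods

`sorbmech` implements, at desk scale, the full computational chain used
to study water uptake by an amorphous, disulfide-cross-linked protein
matrix and its mechanical consequences: a coarse-grained network
builder, a molecular-dynamics core, grand-canonical solvent exchange by
fractional-particle λ-dynamics, sorption-isotherm construction with GAB
fitting, and tensile/void analysis.  This note records the models, the
parameters that matter, the numerical choices, and what the desk-scale
tests do and do not demonstrate.

## The coarse network model

The sorbent is a bead–spring network: linear chains of unit-diameter
beads (reduced units: lengths in σ, energies in ε, masses in m), with
cross-linkable ("cys-like") sites evenly interspersed along each chain
and a prescribed fraction of those sites bridged pairwise, preferring
spatially proximate inter-chain pairs.  The reference topology — 18
chains of 96 residues, 22 sites per chain, 33% of sites bridged — gives
65 bridges, 7.5% cross-linked residues and a mean strand of ≈13
residues between bridges.  The bridged-site count is
round(fraction × sites) floored to an even number; each site joins at
most one bridge.

Everything else about real protein chemistry (side chains, hydrogen
bonds, atomistic water) is deliberately absent.  A single
`UnitSystem` (σ in nm, ε in kJ/mol, m in g/mol) converts reduced
results to physical units for report tables; defaults are σ = 0.47 nm,
ε = 2.5 kJ/mol, m = 96.23 g/mol (one mean residue).

## Molecular-dynamics core

Velocity-Verlet integration; truncated (unshifted) Lennard-Jones
interactions over species-pair tables (Lorentz–Berthelot combination,
with optional per-pair overrides); harmonic bonds k(r−r0)²; Verlet
neighbour list rebuilt every 15 steps *and* whenever any displacement
exceeds half the list skin.  Temperature control is a Nosé–Hoover
thermostat (differential form; identical stationary distribution to the
Nosé formulation, simpler to integrate) with inertial parameter
Q = 5.0 in reduced analogy to the 5.0 kJ mol⁻¹ ps² used at atomistic
scale.  Pressure control is a Berendsen barostat, isotropic or
semi-isotropic; in semi-isotropic mode the frozen axis is never touched
by the barostat (bit-exact), and the coupling time defaults to 100·dt.
Default dt = 0.005 reduced time (0.004 in most studies here), the
standard LJ-stability analogue of a 1.5 fs atomistic step.

An optional mean-field tail correction is available for homogeneous
phases (applied to the fractional particle's energy when enabled); it
is off by default because most analyses here involve cavities.

Two athermal utilities support sample preparation and measurement:
displacement-capped push-off (removes builder overlaps) and FIRE
minimization (inherent structures for quasi-static elasticity).

## Grand-canonical solvent exchange

One solvent particle is *fractional*: its pair energies are scaled by
f(λ) = λ⁵ with a soft-core separation s² = r² + α(1−λ)²σ², α = 0.5, so
energy and dU/dλ are finite at any overlap while λ < 1 and the plain
potential is recovered exactly at λ = 1.  The coupling function is a
pluggable choice; any smooth monotone f with f(0)=0, f(1)=1 satisfies
the contract.

λ evolves under

    W λ̈ = −∂U/∂λ + μ_ex,target − k_B T ln( N_eff / (ρ_ref V) ),

with N_eff the full solvent count plus λ.  The last term is the
ideal-gas part of the chemical-potential difference against a reference
density ρ_ref; it is required for the stationary density to be defined
at all for a weakly/non-interacting solvent (the bare equation has no
restoring force in that limit), and it makes the effective target a
full chemical potential μ = μ_ex,target + k_B T ln(ρ_ref Λ³).

Two design points matter and were established empirically:

* **Events conserve λ-momentum.**  When λ reaches 1 the fractional
  particle becomes a full one and a fresh fractional particle is
  inserted at a uniform random position, continuing at λ−1; when λ
  reaches 0 it is deleted and a randomly designated full solvent
  particle continues at λ+1.  Both events keep N_eff *and* the total
  potential energy continuous (the fractional identity merely relabels
  which interactions carry the λ scaling), so the λ velocity is carried
  through.  Zeroing it instead ("inelastic capping") either re-inserts
  a just-designated bound particle on the next step (the boundary force
  points outward) or, with parked-state workarounds, breaks detailed
  balance and biases the stationary density by O(0.1 k_BT) in μ.
* **λ is thermostatted by Langevin friction + noise** (γ default 1.0,
  seeded).  The insertion path has a coupling-work barrier (repulsive
  work at mid-λ, a binding well near λ = 1 of order the particle's pair
  energy); a purely deterministic λ gets trapped.  Thermal noise at the
  run temperature restores ergodic barrier crossing.

The λ inertial mass W defaults to 5.0 (the reduced analogue of the
published inertial parameter); the desk-scale studies here use lighter
masses (0.2–2.0) to reach many exchange events in 10⁴–10⁵ steps.

Validation: (i) a non-interacting solvent at μ_ex = 0 holds the
reference density within a few per mille with Poissonian number
fluctuations; (ii) on a moderate-density LJ fluid (ρ ≈ 0.2, T = 1.5),
a run targeted at the Widom-insertion μ_ex of a pre-equilibrated
density holds that density within combined error bars.  *Known
limitation:* if ρ_ref is deliberately set far from the equilibrium
density, the finite-rate λ dynamics at liquid-like density carry a
residual bias of order 0.1–0.2 k_BT in the delivered chemical
potential (dissipative, non-adiabatic traversals).  The production
regime of the method — heavy W, long runs, ρ_ref pre-equilibrated close
to equilibrium, exactly as in the cluster-scale protocol — is the
regime where this bias vanishes; desk-scale tests stay in it.

The Widom test-particle estimator (the independent oracle used in
tests) averages exp(−ΔU/k_BT) over uniform insertions spread across
20–30 decorrelated frames; a single-snapshot estimate is biased and its
nominal standard error meaningless.  It reproduces 2B₂ρk_BT for a
dilute gas to within its error.

## Chemical-potential bookkeeping

Phase equilibrium equates excess chemical potentials up to the
ideal-gas difference k_BT ln(Cρ_k/(100 ρ_w,g)); the internal-degrees
term B(T) is a temperature-only common factor and is fixed to zero.
Vapour states are ideal-gas at P = (RH/100)·P_sat with
P_sat(300 K) = 3.55 kPa.  The pressure expansion
μ(P) = μ(P′) + v_w,k(P−P′) + k_BT ln(P′/P) converts between phase
pressures (v_w,k in nm³/molecule; at saturation the printed data imply
v_w,k ≈ 0.0203 nm³).  Concentration conversions (g/100 g ↔ number
density ↔ per-residue ↔ volume-%) close exactly and round-trip to
1e−9; the mean residue mass implied by the packaged table is
96.2 g/mol.  The effective dielectric constant of the mixture is the
volume-fraction-weighted linear mix of 72 (water) and 4 (dry matrix).

## GAB fitting

The sorption isotherm C(a) = C_m b K a / ((1−ba)(1−ba+bKa)) is fitted
by multi-start nonlinear least squares (coarse grid over
C_m ∈ [0.5,10], K ∈ [1,50], b ∈ [0.1,0.95]; best SSE kept; bounds keep
b < 1 so the pole stays outside the domain).

The default objective minimizes *relative* residuals (equivalently,
errors proportional to C).  Two reasons.  First, sorption-point
uncertainties derived from particle-number fluctuations grow roughly
with the uptake itself, so a constant-relative-error model is the
natural one when no explicit error bars accompany the data.  Second,
the objective is decisive for reproducing published coefficient sets:
on the packaged ten-point table, constraining K to the reference value
13.51 and optimizing the rest gives (C_m, b) = (3.18, 0.809) under
relative weighting — the reference values to printed precision — but
(3.00, 0.828) under absolute weighting.  Absolute-residual
(`weights='none'`) and explicit-error (`weights='errors'`) modes are
provided.

A caution that the tests surface deliberately: the GAB objective has a
flat valley trading K against C_m and b.  On the ten-point reference
table the relative SSE changes by <15% for K anywhere in [12, 20]
(with C_m and b re-optimized each time), so C_m (±4%) and b (±1%) are
well identified while K is reproducible only to tens of percent;
fitted K values should be quoted with that caveat, and the derived
enthalpy ΔH = RT ln K inherits it logarithmically.

## Mechanics

Uniaxial tension imposes L∥(t) = L∥(0) + rate·t with affine coordinate
rescaling each step; the transverse axes couple semi-isotropically to
the barostat.  Strain is engineering strain; stress is the negative
axial diagonal pressure-tensor component (tension positive).  Each
recorded sample averages stress, strain and L⊥ = √A over its recording
interval — instantaneous stress in a few-hundred-particle box is
noise-dominated.

* **Young's modulus**: free-intercept least squares over the
  strain < 0.02 window (window size configurable).
* **Yield point**: intersection of the elastic tangent with a
  least-squares hardening tangent (default window: final third of the
  recorded curve; configurable).  Exact on piecewise-linear fixtures.
* **Poisson's ratio**: through-origin regression of −ΔL⊥/L⊥(0) on
  axial strain over the elastic window.
* **Largest void**: morphological opening on a voxel grid (default
  spacing 0.1, probe radius half the solvent diameter): voxels whose
  probe sphere fits (no particle centre within probe + particle
  radius), 6-connected clustering with periodic wrapping and union-find
  label merging across faces, then dilation of the winning cluster
  back by the probe radius.  The re-expansion is what lets a planted
  spherical cavity of radius R report (4/3)πR³ rather than the eroded
  core.  Volume is voxel count × voxel volume; the centre is the
  eroded cluster's circular-mean centroid.
* **Failure**: first recorded strain at which the largest void reaches
  10× its unstrained volume (no interpolation between frames); the
  paired stress is linearly interpolated from the curve.  A trace that
  never crosses reports "no failure within max strain".
* **Cavity density profiles**: minimum-image radial number densities
  about the void centre, normalized per selection by the outer-shell
  bulk average.

## The desk-scale toy studies

`sorbmech.pipeline` fixes the toy conditions in one place.  The sample
is a 288-bead network (8 chains × 36 residues, 8 sites per chain, half
bridged) at reduced density 1.0, annealed at T = 0.8 and quenched
through 0.3 to a working temperature of 0.2 under zero pressure.
Solvent beads (diameter 0.8) are mutually cohesive (ε = 0.6) but wet
the matrix only weakly (cross ε = 0.35, overriding Lorentz–Berthelot):
at high content the solvent pools into pockets, the coarse analogue of
multilayer water clustering in a swollen matrix.  Dry / moderate /
high states use 0, 70 and 150 solvent beads.

Stiffness is measured in the athermal quasi-static limit — FIRE
minimization, ±0.4% affine axial strain, re-minimization,
central-difference virial-stress slope, averaged over the three axes.
Finite-temperature tensile slopes at this system size are
avalanche-dominated (the same sample can return slopes differing by
tens of units between axes); the AQS readout is reproducible to a few
units and is the standard elasticity probe for small glasses.  The
failure readout uses the fast tensile pull (rate 0.06, sluggish
transverse compressibility 0.002 so that dilatational stress can
cavitate the sample) with voids measured on the polymer matrix only —
a solvent-filled pocket counts as a cavity, consistent with sorbed
solvent lining cavity surfaces rather than closing them — and the
unstrained void volume floored at one probe-sphere volume, the
detection resolution.

What these toys show: the *trends* — monotone softening with solvent
content, rising void-criterion failure strain, swelling linear in
content (R² > 0.99) — at reduced scale.  What they cannot show:
absolute moduli or stresses in GPa/MPa (the model has no chemistry and
operates ~10⁶ times faster strain rates), hydrogen-bond-specific
mechanisms, or quantitative humidity mapping; those require the
atomistic, cluster-scale counterpart of this pipeline.

## Synthetic-data generators and what passing tests mean

Analysis operators are validated against generators with known ground
truth: piecewise-linear stress–strain curves (optionally noisy, with a
planted Poisson ratio), largest-void traces with a known 10× crossing,
planted spherical cavities, and solvent insertion with a minimum
distance of 0.85 bead diameters (below-contact placements destabilize
the first integration steps).  These fixtures exercise the estimators'
correctness, not the realism of the simulator: a passing fixture test
says the operator implements its definition exactly, and nothing about
whether a real material's curve satisfies the fixture's assumptions
(e.g. clean two-branch linearity).

## Determinism

Every stochastic stage takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical
topologies, traces and CSV/JSON outputs.  Stationarity of
grand-canonical traces is flagged (two-halves block-mean comparison at
one combined standard error) rather than silently assumed.
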