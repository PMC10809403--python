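# Methods

## Scope and model

`finsize` quantifies and corrects finite-size electrostatic artifacts in
cubic periodic simulation boxes. Its physical model is continuum
electrostatics on two routes:

* **Lattice-sum route** (`finsize.lattice`): point charges in vacuum-like
  surroundings. The periodic energy is the standard Ewald decomposition —
  erfc-screened real-space sum under the minimum-image convention within
  a cutoff r_cut ≤ L/2, exact reciprocal-space sum over k = 2πn/L,
  Gaussian self term −fα/√π Σq², and, for net-charged systems, the
  uniform-background term −πf q_tot²/(2α²V). The default boundary is
  tinfoil (conducting surroundings, no surface-dipole term); `vacuum`
  adds 2πf|M|²/(3V). The nonperiodic reference is the exact pairwise
  Coulomb sum with no cutoff.
* **Poisson route** (`finsize.poisson`): a dielectric cavity model. Atom
  spheres of user-supplied radius carry ε_in (default 1); everything else
  is solvent with ε_out (default 66.6, the SPC-like water model value;
  78, closer to experiment, is an option — switching adds a
  box-size-independent offset to the corrections, so the value in use is
  echoed in every report). The electrostatic solvation free energy is
  ΔG_solv = ½ Σᵢ qᵢ[φ_het(rᵢ) − φ_vac(rᵢ)], where φ_het solves
  ∇·(ε∇φ) = −4πf ρ with the cavity dielectric and φ_vac solves the
  identical grid with ε ≡ ε_in. Because both solves share the grid,
  charge assignment and operator, the (divergent in the continuum limit)
  grid self-energy cancels exactly by construction rather than by
  analytic subtraction.

The two correction terms follow one convention: corrected
ΔG = ΔG_raw + ΔG_pol + ΔG_dir, with each term a B-minus-A average over
end-state snapshots (default expectation: 20 snapshots per end state;
any positive number is accepted and the standard error over snapshots is
reported). Per-snapshot values are retained so the average can be
re-assembled either before or after the B−A subtraction — identical for
means, by linearity. ΔG_dsm is identically zero for net-charge-conserving
perturbations in neutral boxes and is reported as an explicit zero, not
computed.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `EwaldParams.r_cut` | 1.0 (≤ L/2 enforced) | nm | real-space cutoff |
| `EwaldParams.alpha` | erfcinv(rel_tol)/r_cut, ≥ 3/r_cut | nm⁻¹ | splitting; auto-choice ties the real-space truncation error to the requested accuracy |
| `EwaldParams.rel_tol` | 1e-5 | — | target relative accuracy; the reciprocal sum raises k_max until the outermost shells contribute less than this |
| `GridSpec.spacing` | 0.05 | nm | grid resolution; periodic grids round the node count (to even) so L is an integer number of cells and a box-centered solute sits on a node |
| `GridSpec.eps_in` / `eps_out` | 1 / 66.6 | — | cavity / solvent permittivity |
| `GridSpec.kappa` | 0 | nm⁻¹ | optional linearized ionic screening in the solvent region; salt corrections beyond this linear term are out of scope |
| `GridSpec.sor_tol` | 1e-6 | — | relative residual of the linear solve |
| `GridSpec.pad_factor` / `min_extent` | 3.0 / 1.6 | — / nm | nonperiodic grid: at least pad_factor × solute extent, at least min_extent |
| `GridSpec.eps_edge_samples` | 4 | — | midpoint samples for edge permittivities (below) |
| restraint r₀ / k | 2.25 / 1000 | nm / kJ mol⁻¹ nm⁻² | harmonic co-ion–anchor restraint (harmonic form assumed; only r₀ and k are prescribed) |
| λ windows | 11, equidistant on [0,1] | — | linear charge interpolation |
| temperature | 300 | K | k_BT in all ensemble statistics |
| equilibration discard | 0.1 | fraction | initial fraction of each replica dropped in `analyze peptide` |

## Numerical choices

**Plain Ewald, not mesh-interpolated.** At the problem sizes this package
handles (tens to hundreds of charges), the exact reciprocal sum costs
nothing and removes interpolation error as a confounder; it also serves
as the oracle for any future mesh implementation. The net-charge
background term is included so legacy constant-charge topologies are
computable.

**Brute-force lattice oracle.** The independent check on the Ewald
machinery is a direct real-space sum over image cells in an expanding
cube, with Evjen weights ((1/2) per axis at the cube surface) keeping
partial outer shells charge-neutral. Cube-ordered summation converges to
the vacuum-boundary energy; the shape-dependent dipole term 2πf|M|²/(3V)
is subtracted to land on the tinfoil value. The truncated sum retains
1/n² and 1/n³ shape terms; a three-point Richardson fit (n, n−3, n−6)
removes both. The oracle refuses net-charged systems, whose sum is
conditionally convergent with no shape-independent answer.

**Poisson discretization.** 7-point finite-difference stencil with
node-centered fields. Charges are spread trilinearly (cloud-in-cell), so
the grid charge equals the net charge exactly. The sharp dielectric
boundary enters through edge permittivities: the harmonic mean of ε
sampled at `eps_edge_samples` midpoints along each edge — the
distance-weighted harmonic average that preserves normal flux across the
interface (two samples reduce to the plain harmonic mean of the adjacent
nodes, which at 0.05 nm spacing leaves a noticeably larger Born-ion
error). Potentials at atom centers are trilinear interpolations.

**Linear solves.** The variable-coefficient systems are solved by
matrix-free preconditioned conjugate gradients: the preconditioner is
the exact inverse of the constant-coefficient Laplacian applied
spectrally (FFT on periodic grids with the k=0 mode projected out, DST-I
on Dirichlet interiors), so uniform-permittivity problems converge in
one iteration and the iterative and spectral paths agree to solver
tolerance by construction. The returned potential satisfies the
`sor_tol` relative-residual contract; non-convergence raises with the
final residual. Periodic solves subtract the mean source (uniform
neutralizing background) when the grid is net-charged and gauge-fix the
potential to zero mean; no reported energy depends on the gauge
constant.

**Boundary conditions.** The nonperiodic reference solves on a padded
grid with Dirichlet values from the Coulomb potential f Σqᵢ/(ε·r) of the
sources in the exterior dielectric (ε_out for the heterogeneous solve,
ε_in for the vacuum solve). Padding is a configuration knob with a
convergence test, not a hidden constant.

**Error cancellation in ΔG_pol.** Within one boundary condition the grid
self-energy cancels between the heterogeneous and vacuum solves. Across
boundary conditions the remaining cavity-discretization error cancels
only if both grids share the same spacing, so the nonperiodic reference
adopts the spacing actually resolved for the periodic grid (L/dims).
Without this, box edges that are not integer multiples of the requested
spacing corrupt the 1/L scaling of the correction.

**ΔG_dir pair set.** All pairs within the perturbed group (host + solute
+ co-ion) are included; whether the original scheme excludes bonded
(1-2/1-3) pairs is not specified anywhere we could follow, and the
choice cancels in B−A differences whenever the excluded pairs' geometry
is state-independent.

**Degenerate inputs.** Coincident atoms raise a singularity error naming
the pair; molecules whose extent reaches L return a wall distance of 0
with a warning; replicas with an empty basin window are excluded with a
warning; empty histograms, empty snapshot lists and non-cubic boxes are
errors, not silent fallbacks.

## Synthetic data: what it does and does not emulate

The fixtures module generates every input the tests use:

* **Born ion, rock-salt cell, random neutral clouds** are exact oracle
  geometries (closed-form solvation energy, Madelung constant,
  Ewald-vs-direct agreement). They contain no solvent structure at all —
  the solvent exists only as a continuum ε.
* **Ideal helical alanine octapeptide**: backbone built by
  natural-extension placement with φ=−57°, ψ=−47°, ω=180° and standard
  bond lengths/angles, united-atom methyls, protonated N-terminus
  (staggered NH₃⁺), deprotonated C-terminus (OXT at the
  chain-continuation position). This is the *starting* structure of a
  simulation, not an ensemble member; terminal-atom torsions are
  conventions, and starting structures prepared through
  solvation/minimization pipelines can differ by ~0.1 nm in overall
  extent, which is the table precision of the wall-distance comparisons.
* **Two-state distance sampler**: a Gaussian mixture (compact basin at
  0.65 nm, extended at 2.1 nm, σ = 0.12 nm, default p_compact = 0.2,
  10 replicas × 2000 frames) emulating a peptide's end-to-end
  distribution. It has no autocorrelation, so replica standard errors
  are exact; real trajectories correlate in time and their effective
  sample size is smaller. Passing the recovery tests demonstrates the
  estimator machinery, not the convergence of any real simulation.
* **Orientation sampler**: uniform-sphere or six-face von Mises–Fisher
  mixture. Face-locking in real small boxes comes coupled with
  conformational change; the fixture isolates the orientational
  signature only.

All generators are deterministic under a fixed seed.

## Design choices made where the design was open

* Units fixed globally (nm, e, kJ/mol, f = 138.935458); only cubic boxes
  are supported and anything else is rejected rather than truncated.
* Cavity radii are a required user input (charge table column); no
  force-field parser is implemented, and no claim of numerical agreement
  with any particular Poisson–Boltzmann package's radius set is made —
  correctness is argued against analytic oracles.
* The co-ion species is metadata; all energetics see only charges.
* The counter-ion complement needed to neutralize state A is reported as
  a to-add quantity, never silently inserted into coordinates.
* Basin windows default to A = [0.4, 0.9) nm (salt-bridge contact) and
  B = [1.8, 2.6) nm (extended) — implementation defaults, configurable.
* "Average" wall distance means the mean of per-frame values pooled over
  replicas; per-replica minima are also emitted since box-size plots can
  reasonably use either.
* Equal-area sphere binning (uniform cos θ bands × uniform φ slices) so
  the isotropic uniformity test is exact per bin.

## Problem sizes used in validation

Lattice checks run on 8-atom clouds and the 8-ion rock-salt cell with
n_shells = 12 (extrapolated); Poisson checks use 0.1–0.025 nm spacings
(grids up to ~90³ for the 9 nm box at 0.1 nm); the box-size scaling
study uses L ∈ {3, 4.5, 6, 9} nm at 0.1 nm spacing; ensemble statistics
use 10 replicas × 2000 frames across 20 seeds. These sizes were chosen
so every oracle comparison resolves its tolerance with margin.

## Known limitations

* No mesh (PME) implementation, forces, virials or dispersion terms.
* The Poisson route is linear-response continuum theory: no nonlinear
  Poisson–Boltzmann, no explicit solvent granularity, no
  vacuum–liquid-interface (Galvani) potential — hence ΔG_dsm = 0 only
  for net-charge-conserving neutral-box setups, which is the supported
  regime.
* Ionic screening is the linearized κ² term only; production-quality
  salt corrections are out of scope.
* No trajectory superpositioning, secondary-structure assignment or
  plotting; binary trajectory formats are not read — snapshot series are
  directories of GRO/PDB files or plain-text distance tables.
* The corrections assume the perturbed group is compact relative to the
  box; the leading artifact is the 1/L Wigner term and the package's
  scaling tests probe exactly that regime.
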