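# Methods

`npmem` analyses coarse-grained (CG) configurations of a ligand-coated
nanoparticle (NP) interacting with DPPC/cholesterol bilayers.  Every
estimator in the package is validated by *recovery*: a synthetic
generator plants known structure (an order-parameter field, a
cholesterol distribution, a thickness profile, a free-energy curve, a
diffusion coefficient) and the corresponding analysis must reproduce the
planted value.  This note documents the models, the tunable parameters,
the numerical choices, and what the synthetic data do and do not
represent.

Units throughout: lengths nm, times ns, energies kJ/mol, charges e,
temperatures K.  k_B = 0.0083145 kJ/mol/K; the default temperature is
323 K (above the DPPC main transition, the standard choice for fluid
DPPC membranes).

## The system

The bilayer is a two-leaflet DPPC membrane with a cholesterol mole
fraction between 0 and 50%.  Each DPPC molecule is 12 beads (choline,
phosphate PO4, two glycerols, two 4-bead tails); cholesterol is 8 beads
(hydroxyl + compact sterol body).  The NP is a spherical core (default
diameter 4.3 nm) coated with flexible ligand chains at a fixed 2:1 ratio
of anionic MUS (terminal charge −1 e, so 134 MUS ligands give a total
charge of −134) to hydrophobic OT.  The bilayer normal is z; the
reaction coordinate ξ for partitioning is the distance between the NP
centre of mass and the bilayer centre.

## Synthetic configurations

`synth.gen_bilayer` places lipids at uniform random lateral anchors,
split between leaflets so per-species counts differ by at most one
molecule (well inside the ≤10-molecule symmetry the analyses assume).
Head groups sit at ±half the PO4–PO4 separation (default 4.0 nm) with
0.03 nm vertical jitter; tails grow bond by bond (bond length 0.47 nm)
with orientations drawn at a prescribed mean P2.  Frames of a generated
trajectory are *independent statistical snapshots*, not time-correlated
dynamics — the generator produces ensembles, not trajectories of a
thermostat.  The one exception is `gen_brownian2d`, which integrates
genuine 2D Gaussian random walks (per-axis step variance 2·D·dt, with
1 cm²/s = 10⁵ nm²/ns) for the diffusion machinery.

### Planting a target P2

To plant a mean order parameter t = ⟨P2(cos α)⟩, bond polar angles are
drawn from the maximum-entropy distribution on the sphere consistent
with that constraint, p(u) ∝ exp(λ·P2(u)) with u = cos α.  ⟨P2⟩(λ) is
strictly increasing, so λ is unique for any t ∈ (−0.5, 1) and is found
by bracketing root search; the endpoints are planted exactly (bond along
the normal / in the plane).  Sampling uses an inverse-CDF table on a
4001-point u-grid, precomputed per target level on a grid of 601 levels
(snapping a requested target to this grid biases the planted mean by
< 0.002, an order of magnitude below the ±0.02 recovery tolerance).
Because P2 is even in u, forcing chains to grow toward the bilayer core
does not alter the planted value.  For spatially varying fields the
target is evaluated at the growing chain's current end point, keeping
each bond midpoint within half a bond length of where its target
applies; planted radial steps are therefore blurred by at most ~0.2 nm.

### Planting wells, snorkeling, and PMFs

Cholesterol depletion c(d)/c_bulk is planted by rejection sampling of
lateral anchors against the target field; thickness wells move the four
head-group beads of each lipid so the local PO4–PO4 separation matches
the target at the lipid's lateral distance d from the NP.  Default well
shapes are Gaussian with σ = 2 nm, the scale of the structural
perturbation a membrane-embedded NP of a few nm induces.  The snorkeled
fraction is planted exactly per frame: the rounded fraction of MUS
termini is placed in the head-group slabs, the rest in the hydrophobic
core band.

Planted free-energy profiles are analytic functions on [0, span]
referenced to zero at the span end (the water phase).  The double-well
factory superposes a Gaussian barrier (default at ξ = 1.5 nm) and a
Gaussian interface minimum (default at 4.5 nm) and rescales both so the
barrier − minimum difference equals the requested barrier (28 kJ/mol by
default) exactly.  Umbrella samples are i.i.d. draws from
exp(−[G(ξ) + (k/2)(ξ−c)²]/k_BT) by inverse-CDF on a 20001-point grid —
far finer than the harmonic width √(k_BT/k) ≈ 0.06 nm at the standard
k = 750 kJ/mol/nm².

All generators are pure functions of (spec, seed); sub-streams derive
from the single seed by fixed per-generator offsets, so outputs are
bitwise reproducible.

### What the synthetic data are not

The generator performs no dynamics, no energy minimisation and no
self-assembly: bead overlaps occur, tails may cross the midplane, and
the NP is held static when combined with a bilayer.  Umbrella samples
are uncorrelated, whereas real restrained MD series are autocorrelated
(the block-bootstrap machinery exists for the real case but is exercised
on i.i.d. data).  Passing recovery tests therefore demonstrates the
*estimators* are correct and unbiased at known ground truth — not that
real membranes behave like the synthetic ones.

## Structural observables

**P2 order parameter.**  Per bond, P2 = (3cos²α − 1)/2 with α the angle
between the bond (minimum image) and the bilayer normal; +1 is perfect
alignment, −0.5 perpendicular, 0 isotropic.  The DPPC bond set is the
eight tail bonds per lipid (glycerol→first tail bead plus consecutive
tail beads), equally weighted — the standard CG tail-order convention.
Maps average per-bond values in (lateral distance × z) or (x × z) cells
binned by bond midpoint, both leaflets jointly; empty cells are NaN,
never zero.  Phase labels: liquid-disordered (Ld) for P2 ∈ [0.2, 0.5],
liquid-ordered (Lo) for [0.7, 1], everything else in [−0.5, 1]
"intermediate" (including the 0.5–0.7 gap).

**Profiles around the NP.**  Radial profiles use the lateral (x, y)
minimum-image distance from the NP centre of mass (core beads only by
default; a flag includes ligands).  Radial concentration counts molecule
centres of mass per annulus (bead-count mode available), normalised by a
bulk reference c_bulk taken from annuli in [6 nm, min(lx,ly)/2 − 1 nm]
by default — outside the NP's sphere of influence — with a fallback to
the outer half of the profile for small boxes.  Thickness is
⟨z_PO4,upper⟩ − ⟨z_PO4,lower⟩ per annulus with leaflets ordered
canonically (upper = larger mean z), so the value is positive whatever
the labels.  The 2D RDF normalises lateral pair counts by the ideal-gas
expectation from the mean planar density of the partner group, so
uncorrelated uniform beads give g(r) ≡ 1.

**Snorkeling.**  The snorkeled fraction is the share of MUS terminal
beads *outside* the hydrophobic core band |z − z_mid| < 1 nm (half-width
configurable), with z_mid the PO4 midplane per frame; termini in the
head-group slabs or the water phase both count as snorkeled.

**Errors.**  Profile standard errors use block averaging over 5 equal
time blocks, because frames of a real trajectory are autocorrelated and
a naive per-frame SE is optimistic.

**Well recovery.**  Planted Gaussian wells are recovered by weighted
least squares with per-bin Poisson errors.  The two-parameter
(depth, width) fit is degenerate when inner annuli are sparse — the
measured depth spread across seeds is ±0.05 even at 8×10⁵ samples — so
recovery of a well of known width fits depth alone (spread ±0.02,
unbiased); both variants are exposed.

## Energetics

The nonbonded kernels implement the cut-and-shift scheme of CG membrane
simulations: for each inverse-power term r⁻ᵖ the force gains
A(r−r₁)² + B(r−r₁)³ between the shift onset r₁ and the cutoff r_c, with
A and B solved (2×2 linear system) from zero force and zero force
derivative at r_c, and an integration constant zeroing the potential
there.  Defaults: r₁ = 0.9 nm and r_c = 1.2 nm for the 12-6
Lennard-Jones terms; the Coulomb term (prefactor 138.935 kJ·mol⁻¹·nm·e⁻²,
uniform relative dielectric ε_r = 15) is shifted over its whole range
(r₁ = 0).  Both kernels are C¹ at the cutoff; the suite verifies each
potential equals the numerical quadrature of its force.

Bead–bead interaction parameters are force-field specific, so the
package ships a small documented per-role σ/ε set in the MARTINI value
range (σ = 0.47 nm, ε between 2.0 and 5.6 kJ/mol) as a working default,
overridable per pair via TSV.  Group–group energies sum shifted LJ + Coulomb over
minimum-image pairs within 1.2 nm; the normalisation counts partner
molecules with *any* bead within the cutoff (the conservative superset
of a COM criterion).  Reports compute the per-frame normalised energy
first and then average over time; components absent from the system
(cholesterol in a cholesterol-free membrane) print N/A rather than
zero.

## Umbrella sampling and WHAM

`make_windows` lays an inclusive-endpoint ladder over [0, span]:
round(span/spacing) + 1 centres, so the 7 nm span at 0.2 nm spacing
gives 36 windows; with 200 ns equilibration plus 400 ns production per
window that is a 21.6 µs campaign (18 µs at 300 ns production).

WHAM iterates the standard self-consistency equations on a uniform
histogram grid (200 bins by default, spanning the sampled range; the
bias is evaluated at bin centres — a bin-averaged Boltzmann bias was
tested and gave *larger* systematic error).  All exponentials go through
log-sum-exp, so far-apart windows (bias energies of 10³–10⁴ kJ/mol) stay
in range.  The fixed point is solved by Anderson-accelerated iteration
(memory 20, plain damped update as fallback), converging when the true
self-consistency residual max|ΔF| < tolerance·k_BT (default 10⁻⁷);
acceleration cuts ~15 000 plain iterations to under 100 without changing
the solution, which the suite pins against an independent generic
root-finder on a 2-window/10-bin problem (agreement to 10⁻⁸).
Windows are checked for connectivity: groups of windows sharing no
sampled bin cannot be joined and raise an error, while interior empty
bins simply come out unsampled (NaN).

Profiles are referenced to zero over the outermost 0.5 nm of sampled ξ
(the flat water phase).  Because a PMF is defined only up to an additive
constant, *recovery comparisons* minimise over that gauge (subtract the
mean difference) before computing RMSE — the analogue of superposition
before an RMSD.  At the study conditions (36 windows, k = 750, 10⁴
samples/window) the reconstruction is information-limited by inter-window
coupling noise: the gauge-aligned RMSE against the planted curve is
typically 0.2–0.3 kJ/mol and the barrier error well under 1 kJ/mol,
while the systematic floor (measured with exact expected histograms) is
only 0.04 kJ/mol.

Bootstrap errors resample each window's series in contiguous blocks
(default block = 1/20 of the series, i.e. ~10 ns of a typical production
span) with replacement, re-run WHAM on the frozen bin grid, re-reference,
and report the per-bin SD across replicates; non-converged replicates
are discarded with a warning, and more than 50% failures is an error.
`pmf_features` extracts the interface minimum (argmin over a stated
region, ties to the smallest ξ) and the barrier (max over [0, minimum]
minus the minimum).  `convergence_scan` truncates each window to growing
sampling times and tracks the barrier, mirroring the convergence
protocol of umbrella campaigns.

## Lateral diffusion

MSD uses every frame as a time origin over a logarithmic lag grid
(xy components by default); wrapped trajectories (frame-to-frame jump
above half a box edge) are rejected unless unwrapped first, and
`unwrap` reconstructs continuous paths by accumulating minimum-image
displacements.  D is the least-squares MSD slope over a fit window
(default 10–50% of the longest lag, skipping the short-lag region)
divided by 2·dim, converted as 1 nm²/ns = 10⁻⁵ cm²/s.  The formal OLS
slope error understates uncertainty because MSD values at different
lags share displacements; `fit_diffusion_ensemble` instead fits D per
particle and uses the spread across independent walkers, giving a 95%
CI with honest coverage (93–97% measured over 100 seeded replicates).
A negative fitted slope reports D = 0 with a warning.

## Problem sizes used in the shipped checks

Recovery runs use: P2 levels on 1300-lipid bilayers × 2 snapshots
(≥10⁴ bonds per map cell after corner clipping); the Ld/Lo step on
1000 lipids × 4 snapshots at 0.5 nm bins; cholesterol depletion on
2000 lipids (40% CHOL) × 40 snapshots; thinning on 800 lipids × 8;
WHAM on 36 windows × 10⁴ samples; diffusion on 500 walkers × 2000 steps
with coverage over 100 replicates of 200 × 400.  These sizes put each
estimator's statistical error several times below its stated recovery
tolerance.

## Known limitations

* Orthorhombic boxes only; triclinic GRO box lines are rejected.
* The energetics path is a dense vectorised pair sum — fine for the
  ≤10⁵-bead systems targeted here, but no cell lists for very large
  frames.
* The synthetic bilayer has no explicit water in any analysis (a flag
  adds inert W beads for file realism only), no area-per-lipid
  tessellation, and no physical correlation between planted fields
  (e.g. planting disorder does not thin the membrane by itself).
* Bootstrap and block-averaging defaults assume series long enough to
  contain ≥20 blocks; shorter records fall back to cruder estimates.
* `plant_structure` assumes the generator's bead templates (12-bead
  DPPC, 8-bead CHOL) when rebuilding chains.
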