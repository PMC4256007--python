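# npmem

Analysis toolkit for coarse-grained simulations of ligand-coated
nanoparticles (NPs) partitioning into lipid membranes.

When an anionic, ligand-decorated NP embeds in a DPPC/cholesterol
bilayer, it reorganises its surroundings: charged ligand termini
"snorkel" up to the head-group region, lipid tails disorder locally
(liquid-ordered → liquid-disordered), cholesterol is depleted near the
particle, and the membrane thins.  Quantifying these effects — and the
free-energy barrier the NP must cross to translocate — requires a stack
of trajectory analyses.  `npmem` implements that stack for
coarse-grained bead models, aimed at simulators who have (or want to
prototype against) GRO-format configurations of bilayer + NP systems:

* **Order parameters** — per-bond P2 = ⟨(3cos²α − 1)/2⟩ against the
  bilayer normal, spatial maps, and Ld/Lo phase classification
  (Ld: P2 ∈ [0.2, 0.5], Lo: [0.7, 1]).
* **Structure around the NP** — number-density maps, lateral radial
  concentration profiles c(d)/c_bulk, 2D radial distribution functions,
  PO4–PO4 thickness profiles, and the snorkeled fraction of charged
  termini.
* **Energetics** — shifted Lennard-Jones and Coulomb kernels (potential
  and force exactly zero at the 1.2 nm cutoff) and per-molecule
  normalised NP–component interaction energies.
* **Free energies** — umbrella-sampling window layout, WHAM
  reconstruction of the potential of mean force G(ξ) along the
  NP–bilayer-centre distance, block-bootstrap error bars, and
  barrier/minimum extraction.
* **Dynamics** — mean-square displacement with multiple time origins
  and lateral self-diffusion coefficients from MSD = 4Dτ.

Everything is verifiable without running molecular dynamics: the
`synth` module generates bilayer/NP configurations, biased
reaction-coordinate samples, and Brownian trajectories with *planted,
analytically known* structure, so each estimator is tested by parameter
recovery.

## Worked example

Reconstruct a planted 28 kJ/mol translocation barrier from synthetic
umbrella sampling, then map planted local disorder around an NP:

```python
import numpy as np
from npmem import pmf, structure, synth

# 1. plant a double-well PMF and reconstruct it from biased samples
planted = synth.double_well_pmf(barrier=28.0)          # kJ/mol, exact
layout = pmf.make_windows(span=7.0, spacing=0.2, k=750.0)
windows = synth.gen_umbrella_samples(
    planted, layout.centers, k=750.0, n_per_window=10000, seed=1)
profile = pmf.bootstrap_pmf(windows, pmf.WHAMSettings(), n_boot=20, seed=1)
feats = pmf.pmf_features(profile, interface_region=(3.5, 6.0))
print(f"windows: {layout.n_windows}")
print(f"barrier: {feats['barrier_height']:.2f} kJ/mol (planted 28.00)")
print(f"minimum: {feats['minimum_location']:.2f} nm from the bilayer centre")
print(f"median bootstrap SD: {np.nanmedian(profile.sd):.2f} kJ/mol")

# 2. plant local disorder around the NP and map it
spec = synth.BilayerSpec(n_lipids=1000, chol_fraction=0.3)
traj, top = synth.gen_bilayer(spec, seed=2, n_frames=4)
field = synth.PlantedStructure(p2_field=synth.radial_step(0.4, 0.8, 3.0))
disordered = synth.plant_structure(traj, top, field, seed=3)
p2map = structure.p2_map(disordered, top, mode="dz", bin_width=0.5)
w = np.where(np.isfinite(p2map.values), p2map.counts, 0.0)
v = np.where(np.isfinite(p2map.values), p2map.values, 0.0)
radial_p2 = (v * w).sum(axis=1) / np.maximum(w.sum(axis=1), 1)
near, far = radial_p2[2], radial_p2[-3]
print(f"P2 near the NP: {near:.2f} ({structure.classify_phase(near)})  "
      f"far: {far:.2f} ({structure.classify_phase(far)})")
```

Output:

```
windows: 36
barrier: 27.53 kJ/mol (planted 28.00)
minimum: 4.53 nm from the bilayer centre
median bootstrap SD: 0.43 kJ/mol
P2 near the NP: 0.38 (Ld)  far: 0.80 (Lo)
```

The 7 nm reaction-coordinate span at 0.2 nm spacing yields 36 umbrella
windows; WHAM rebuilds the planted barrier to within half a kJ/mol, the
interface minimum lands at its planted 4.5 nm, and the order-parameter
map separates the planted liquid-disordered region near the particle
(P2 ≈ 0.4) from the ordered bulk (P2 ≈ 0.8) at the planted 3 nm
boundary.

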