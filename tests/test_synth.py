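"""Generator tests: composition, determinism, and planted-target fidelity."""

import numpy as np
import pytest
from scipy import stats

from npmem import structure, synth
from npmem._orient import SAMPLER, p2
from npmem.traj_io import Box


class TestBilayerComposition:
    def test_composition_arithmetic_and_leaflet_symmetry(self):
        spec = synth.BilayerSpec(n_lipids=100, chol_fraction=0.30)
        traj, top = synth.gen_bilayer(spec, seed=1)
        dppc = np.unique(top.molecule_ids[top.species == "DPPC"])
        chol = np.unique(top.molecule_ids[top.species == "CHOL"])
        assert dppc.size == 70
        assert chol.size == 30
        leaf = top.df["leaflet"].to_numpy(dtype=object)
        for mols, sp in ((dppc, "DPPC"), (chol, "CHOL")):
            per_leaf = [
                np.unique(
                    top.molecule_ids[(top.species == sp) & (leaf == side)]
                ).size
                for side in ("upper", "lower")
            ]
            assert abs(per_leaf[0] - per_leaf[1]) <= 10  # symmetric to within 10

    def test_zero_cholesterol_means_no_chol_beads(self):
        spec = synth.BilayerSpec(n_lipids=50, chol_fraction=0.0)
        _, top = synth.gen_bilayer(spec, seed=1)
        assert top.select(species="CHOL").size == 0

    def test_same_seed_bitwise_identical(self):
        spec = synth.BilayerSpec(n_lipids=40, chol_fraction=0.1)
        t1, _ = synth.gen_bilayer(spec, seed=9, n_frames=2)
        t2, _ = synth.gen_bilayer(spec, seed=9, n_frames=2)
        assert np.array_equal(t1.positions, t2.positions)
        t3, _ = synth.gen_bilayer(spec, seed=10, n_frames=2)
        assert not np.array_equal(t1.positions, t3.positions)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            synth.BilayerSpec(n_lipids=10, chol_fraction=1.5)
        with pytest.raises(ValueError):
            synth.BilayerSpec(n_lipids=0)

    def test_head_groups_sit_at_planted_separation(self):
        spec = synth.BilayerSpec(n_lipids=200, leaflet_separation_bulk=4.0)
        traj, top = synth.gen_bilayer(spec, seed=3)
        leaf = top.df["leaflet"].to_numpy(dtype=object)
        po4 = top.select(role="PO4")
        up = traj.positions[0, po4[leaf[po4] == "upper"], 2].mean()
        lo = traj.positions[0, po4[leaf[po4] == "lower"], 2].mean()
        assert up - lo == pytest.approx(4.0, abs=0.05)

    def test_water_flag_adds_inert_beads(self):
        spec = synth.BilayerSpec(n_lipids=20, chol_fraction=0.0)
        traj, top = synth.gen_bilayer(
            spec, seed=4, with_water=True, waters_per_lipid=28.0
        )
        w = top.select(species="W")
        assert w.size == round(28 * 20 / 4)
        # water stays outside the hydrophobic core slab
        z = traj.positions[0, w, 2]
        z_mid = traj.box.lz / 2
        assert np.all(np.abs(z - z_mid) > 2.0)


class TestNanoparticle:
    def test_study_particle_total_charge(self):
        spec = synth.NPSpec(n_mus=134, n_ot=67)
        _, top = synth.gen_np(spec, seed=1)
        assert top.charges.sum() == pytest.approx(-134.0)
        assert spec.total_charge == -134

    def test_minimal_particle(self):
        spec = synth.NPSpec(core_diameter=1.0, n_mus=2, n_ot=1)
        _, top = synth.gen_np(spec, seed=1)
        n_ligands = np.unique(
            top.df.index[np.isin(top.species, ["MUS", "OT"])].size
        )
        assert top.charges.sum() == pytest.approx(-2.0)
        assert top.select(species="MUS", role="terminal").size == 2
        assert top.select(species="OT").size == spec.ot_length_beads

    def test_ratio_violation_rejected(self):
        with pytest.raises(ValueError, match="2:1"):
            synth.NPSpec(n_mus=10, n_ot=7)

    def test_termini_within_ligand_reach(self):
        spec = synth.NPSpec(core_diameter=3.0, n_mus=30, n_ot=15)
        pos, top = synth.gen_np(spec, seed=2, center=(1.0, 2.0, 3.0))
        term = top.select(species="MUS", role="terminal")
        r = np.linalg.norm(pos[term] - np.array([1.0, 2.0, 3.0]), axis=1)
        reach = 1.5 + synth.BOND_LENGTH * spec.mus_length_beads + 0.3
        assert np.all(r <= reach)

    def test_same_seed_bitwise_identical(self):
        spec = synth.NPSpec(n_mus=8, n_ot=4)
        p1, _ = synth.gen_np(spec, seed=5)
        p2_, _ = synth.gen_np(spec, seed=5)
        assert np.array_equal(p1, p2_)


class TestOrientationSampler:
    def test_extreme_targets_are_exact(self):
        rng = np.random.default_rng(0)
        u_top = SAMPLER.sample(rng, np.full(100, 1.0))
        assert np.all(np.abs(u_top) == 1.0)
        u_flat = SAMPLER.sample(rng, np.full(100, -0.5))
        assert np.all(u_flat == 0.0)

    def test_isotropic_target_zero(self):
        # Monte-Carlo oracle: for target 0 the distribution is uniform on
        # the sphere; the mean P2 of 1e5 draws is 0 within 3 sigma
        rng = np.random.default_rng(1)
        u = SAMPLER.sample(rng, np.zeros(100000))
        sigma = np.sqrt(0.2 / 100000)  # Var[P2] = 1/5 under isotropy
        assert abs(p2(u).mean()) < 3 * sigma

    def test_out_of_range_target_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            SAMPLER.sample(rng, np.array([1.2]))
        with pytest.raises(ValueError):
            SAMPLER.sample(rng, np.array([-0.6]))


class TestPlantedStructure:
    def test_constant_p2_one_means_tails_parallel_to_normal(self, small_bilayer):
        traj, top = small_bilayer
        planted = synth.plant_structure(
            traj, top, synth.PlantedStructure(p2_field=1.0), seed=21
        )
        bonds = structure.tail_bonds(top)
        vals = structure.p2_of_bonds(planted.frame(0), bonds)
        assert np.allclose(vals, 1.0, atol=1e-9)

    def test_constant_p2_zero_recovered_within_monte_carlo_error(self):
        spec = synth.BilayerSpec(n_lipids=800, chol_fraction=0.0)
        traj, top = synth.gen_bilayer(spec, seed=22, n_frames=2)
        planted = synth.plant_structure(
            traj, top, synth.PlantedStructure(p2_field=0.0), seed=23
        )
        bonds = structure.tail_bonds(top)
        vals = np.concatenate(
            [structure.p2_of_bonds(planted.frame(i), bonds) for i in range(2)]
        )
        assert vals.size >= 10000
        sigma = np.sqrt(0.2 / vals.size)
        assert abs(vals.mean()) < 3 * sigma

    def test_uniform_depletion_passes_chi2_uniformity(self):
        spec = synth.BilayerSpec(n_lipids=600, chol_fraction=0.5)
        traj, top = synth.gen_bilayer(spec, seed=24, n_frames=2)
        planted = synth.plant_structure(
            traj, top, synth.PlantedStructure(chol_depletion=1.0), seed=25
        )
        roh = top.select(role="hydroxyl")
        xy = planted.positions[:, roh, :2].reshape(-1, 2)
        L = traj.box.lx
        counts, *_ = np.histogram2d(
            xy[:, 0] % L, xy[:, 1] % L, bins=[4, 4], range=[[0, L], [0, L]]
        )
        _, pval = stats.chisquare(counts.ravel())
        assert pval > 0.01

    def test_snorkel_target_fraction_planted_exactly(self, bilayer_with_np):
        traj, top = bilayer_with_np
        planted = synth.plant_structure(
            traj, top, synth.PlantedStructure(snorkel_fraction_target=0.75), seed=26
        )
        frac, _ = structure.snorkel_fraction(planted, top)
        assert frac == pytest.approx(0.75, abs=0.01)

    def test_out_of_range_p2_target_rejected(self, small_bilayer):
        traj, top = small_bilayer
        with pytest.raises(ValueError):
            synth.plant_structure(
                traj, top, synth.PlantedStructure(p2_field=1.5), seed=27
            )


class TestUmbrellaSamples:
    def test_flat_pmf_gives_gaussian_at_center(self):
        ppmf = synth.flat_pmf(span=7.0)
        ws = synth.gen_umbrella_samples(ppmf, [3.0], k=750.0, n_per_window=20000, seed=31)
        s = ws.windows[0].samples
        kBT = synth.KB * ppmf.temperature
        assert s.mean() == pytest.approx(3.0, abs=3 * np.sqrt(kBT / 750.0 / 20000))
        assert s.var() == pytest.approx(kBT / 750.0, rel=0.05)

    def test_harmonic_pmf_variance_closed_form(self):
        a, c, k = 40.0, 3.5, 750.0
        ppmf = synth.harmonic_pmf(a, c, span=7.0)
        ws = synth.gen_umbrella_samples(ppmf, [c], k=k, n_per_window=20000, seed=32)
        kBT = synth.KB * ppmf.temperature
        expected = kBT / (2 * a + k)
        assert ws.windows[0].samples.var() == pytest.approx(expected, rel=0.05)

    def test_double_well_window_matches_quadrature(self):
        # KS oracle: empirical window CDF vs numerical quadrature of the
        # biased density
        ppmf = synth.double_well_pmf()
        c, k = 2.0, 750.0
        ws = synth.gen_umbrella_samples(ppmf, [c], k=k, n_per_window=5000, seed=33)
        grid = np.linspace(0, 7, 50001)
        kBT = ppmf.kBT
        dens = np.exp(-(ppmf.values(grid) + 0.5 * k * (grid - c) ** 2) / kBT)
        cdf_grid = np.concatenate(
            [[0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))]
        )
        cdf_grid /= cdf_grid[-1]
        res = stats.kstest(ws.windows[0].samples, lambda x: np.interp(x, grid, cdf_grid))
        assert res.pvalue > 0.01

    def test_center_outside_span_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_umbrella_samples(synth.flat_pmf(span=7.0), [8.0], 750.0, 10, seed=1)

    def test_determinism(self):
        ppmf = synth.double_well_pmf()
        w1 = synth.gen_umbrella_samples(ppmf, [1.0, 2.0], 750.0, 100, seed=34)
        w2 = synth.gen_umbrella_samples(ppmf, [1.0, 2.0], 750.0, 100, seed=34)
        for a, b in zip(w1.windows, w2.windows):
            assert np.array_equal(a.samples, b.samples)


class TestBrownian:
    def test_zero_diffusion_is_stationary(self):
        traj = synth.gen_brownian2d(0.0, 1.0, 50, 10, seed=41)
        assert np.all(traj.positions == traj.positions[0])

    def test_single_step_variance(self):
        D, dt = 5e-7, 1.0
        traj = synth.gen_brownian2d(D, dt, 2, 50000, seed=42)
        step = traj.positions[1, :, :2] - traj.positions[0, :, :2]
        msd1 = np.sum(step**2, axis=1).mean()
        expected = 4 * D * 1e5 * dt  # nm^2
        assert msd1 == pytest.approx(expected, rel=0.03)

    def test_z_fixed_and_deterministic(self):
        t1 = synth.gen_brownian2d(1e-7, 0.5, 20, 5, seed=43)
        t2 = synth.gen_brownian2d(1e-7, 0.5, 20, 5, seed=43)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.all(t1.positions[:, :, 2] == t1.positions[0, 0, 2])

    def test_negative_diffusion_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_brownian2d(-1e-7, 1.0, 10, 10, seed=44)


class TestPlantedPMFFactories:
    def test_double_well_barrier_is_exact(self):
        ppmf = synth.double_well_pmf(barrier=28.0)
        grid = np.linspace(0, 7, 20001)
        g = ppmf.values(grid)
        assert g.max() - g.min() == pytest.approx(28.0, abs=1e-3)
        # referenced to zero in the water phase
        assert abs(g[-1]) < 1e-9

    def test_minimum_and_barrier_locations(self):
        ppmf = synth.double_well_pmf(barrier_loc=1.5, min_loc=4.5)
        grid = np.linspace(0, 7, 20001)
        g = ppmf.values(grid)
        assert grid[np.argmin(g)] == pytest.approx(4.5, abs=0.1)
        assert grid[np.argmax(g)] == pytest.approx(1.5, abs=0.1)
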