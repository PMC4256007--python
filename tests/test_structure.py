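"""Structural-observable tests: P2 machinery, maps, profiles, snorkeling."""

import numpy as np
import pytest
from scipy import stats

from npmem import structure, synth
from npmem.traj_io import Box, Frame, Topology, Trajectory


def _single_bond_system(vec):
    """One DPPC-like molecule with one tail bond along ``vec``."""
    pos = np.zeros((12, 3))
    pos[:, :] = 5.0
    pos[5] = pos[4] + np.asarray(vec)
    box = Box(10, 10, 10)
    beads = [
        ("choline", 1.0), ("PO4", -1.0), ("glycerol", 0.0), ("glycerol", 0.0),
    ] + [("tail", 0.0)] * 8
    top = Topology.from_arrays(
        molecule_id=[0] * 12,
        species=["DPPC"] * 12,
        role=[r for r, _ in beads],
        charge=[q for _, q in beads],
        leaflet=["upper"] * 12,
    )
    return Frame(0.0, pos, box), top


class TestP2:
    def test_bond_along_normal_is_one(self):
        frame, top = _single_bond_system([0, 0, 0.47])
        bonds = np.array([[4, 5]])
        assert structure.p2_of_bonds(frame, bonds)[0] == pytest.approx(1.0)

    def test_bond_in_plane_is_minus_half(self):
        frame, top = _single_bond_system([0.3, 0.2, 0.0])
        bonds = np.array([[4, 5]])
        assert structure.p2_of_bonds(frame, bonds)[0] == pytest.approx(-0.5)

    def test_random_orientations_average_to_zero(self):
        # Monte-Carlo oracle: isotropic bonds have mean P2 = 0
        rng = np.random.default_rng(7)
        n = 100000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = np.zeros((2 * n, 3))
        pos[1::2] = v * 0.47
        pos += 20.0
        frame = Frame(0.0, pos, Box(60, 60, 60))
        bonds = np.column_stack([np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)])
        vals = structure.p2_of_bonds(frame, bonds)
        assert np.all((vals >= -0.5 - 1e-12) & (vals <= 1.0 + 1e-12))
        assert abs(vals.mean()) < 0.005

    def test_zero_length_bond_rejected(self):
        frame, _ = _single_bond_system([0, 0, 0.47])
        with pytest.raises(ValueError):
            structure.p2_of_bonds(frame, np.array([[0, 1]]))  # coincident beads


class TestPhaseClassification:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.4, "Ld"),       # disordered mid-range
            (0.2, "Ld"),
            (0.5, "Ld"),
            (0.85, "Lo"),      # ordered
            (0.7, "Lo"),
            (1.0, "Lo"),
            (0.6, "intermediate"),   # gap between the two ranges
            (0.0, "intermediate"),
            (-0.5, "intermediate"),
        ],
    )
    def test_ranges(self, value, label):
        assert structure.classify_phase(value) == label

    def test_total_over_domain(self):
        for v in np.linspace(-0.5, 1.0, 301):
            assert structure.classify_phase(v) in ("Ld", "intermediate", "Lo")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            structure.classify_phase(1.2)


class TestP2Map:
    def test_single_bond_cell_matches_per_bond_value(self):
        frame, top = _single_bond_system([0.2, 0.0, 0.4])
        traj = Trajectory(np.array([0.0]), frame.positions[None], frame.box)
        bonds = np.array([[4, 5]])
        field = structure.p2_map(
            traj, top, bonds=bonds, mode="xz", bin_width=1.0,
            np_com_xy=(5.0, 5.0),
        )
        expected = structure.p2_of_bonds(frame, bonds)[0]
        filled = field.values[np.isfinite(field.values)]
        assert filled.size == 1
        assert filled[0] == pytest.approx(expected)

    def test_planted_constant_field_recovered_per_cell(self):
        spec = synth.BilayerSpec(n_lipids=800, chol_fraction=0.0)
        traj, top = synth.gen_bilayer(spec, seed=51, n_frames=8)
        planted = synth.plant_structure(
            traj, top, synth.PlantedStructure(p2_field=0.4), seed=52
        )
        field = structure.p2_map(planted, top, mode="dz", bin_width=4.0)
        cells = field.values[field.counts >= 10000]
        assert cells.size > 0
        assert np.all(np.abs(cells - 0.4) < 0.02)

    def test_planted_radial_step_located_within_one_bin(self):
        spec = synth.BilayerSpec(n_lipids=1000, chol_fraction=0.0)
        traj, top = synth.gen_bilayer(spec, seed=53, n_frames=4)
        step_at = 3.0
        planted = synth.plant_structure(
            traj, top,
            synth.PlantedStructure(p2_field=synth.radial_step(0.4, 0.8, step_at)),
            seed=54,
        )
        bin_width = 0.5
        field = structure.p2_map(planted, top, mode="dz", bin_width=bin_width)
        # collapse z: per-d mean weighted by counts
        w = np.where(np.isfinite(field.values), field.counts, 0.0)
        v = np.where(np.isfinite(field.values), field.values, 0.0)
        prof = (v * w).sum(axis=1) / np.maximum(w.sum(axis=1), 1)
        d = field.centers1
        crossing = d[np.nonzero(prof > 0.6)[0][0]]
        assert abs(crossing - step_at) <= bin_width

    def test_empty_bond_selection_rejected(self, small_bilayer):
        traj, top = small_bilayer
        with pytest.raises(ValueError):
            structure.p2_map(traj, top, bonds=np.empty((0, 2), dtype=int))


class TestNumberDensityMap:
    def test_single_static_bead_occupies_one_cell(self):
        pos = np.full((1, 3), 2.5)
        traj = Trajectory(
            np.arange(100.0), np.repeat(pos[None], 100, axis=0), Box(10, 10, 10)
        )
        field = structure.number_density_map(traj, np.array([0]), bin_width=1.0)
        nz = np.nonzero(field.values)
        assert len(nz[0]) == 1
        assert field.values[nz][0] == pytest.approx(1.0)  # 1 bead / 1 nm^2 cell

    def test_mass_conservation_exact(self, bilayer_with_np):
        traj, top = bilayer_with_np
        sel = top.select(species="DPPC")
        field = structure.number_density_map(traj, sel, bin_width=0.7)
        total = (field.values * field.cell_areas).sum()
        assert total == pytest.approx(sel.size, rel=1e-12)

    def test_uniform_beads_give_flat_map(self):
        rng = np.random.default_rng(55)
        pos = rng.uniform(0, 8, size=(6, 2000, 3))
        traj = Trajectory(np.arange(6.0), pos, Box(8, 8, 8))
        field = structure.number_density_map(
            traj, np.arange(2000), bin_width=2.0
        )
        _, pval = stats.chisquare(field.counts.ravel())
        assert pval > 0.01

    def test_planted_snorkeling_empties_core_band(self, bilayer_with_np):
        traj, top = bilayer_with_np
        planted = synth.plant_structure(
            traj, top, synth.PlantedStructure(snorkel_fraction_target=1.0), seed=56
        )
        term = top.select(species="MUS", role="terminal")
        field = structure.number_density_map(planted, term, bin_width=0.5)
        z_mid = traj.box.lz / 2
        z_centers = field.centers2
        core_cols = np.abs(z_centers - z_mid) < 0.75
        assert field.values[:, core_cols].sum() == 0.0

    def test_empty_selection_rejected(self, bilayer_with_np):
        traj, _ = bilayer_with_np
        with pytest.raises(ValueError):
            structure.number_density_map(traj, np.array([], dtype=int))


class TestRadialConcentration:
    def test_uniform_cholesterol_gives_unity_profile(self):
        spec = synth.BilayerSpec(n_lipids=800, chol_fraction=0.4)
        traj, top = synth.gen_bilayer(spec, seed=57, n_frames=6)
        planted = synth.plant_structure(
            traj, top, synth.PlantedStructure(chol_depletion=1.0), seed=58
        )
        prof = structure.radial_concentration(
            planted, top, "CHOL", bin_width=1.0,
            bulk_range=(4.0, traj.box.lx / 2 - 0.5),
        )
        ok = np.isfinite(prof.value) & (prof.n > 0)
        dev = np.abs(prof.value[ok] - 1.0)
        # each annulus within 3 SE of unity (Poisson SE floor for sparse bins)
        se = np.maximum(prof.stderr[ok], 1.0 / np.sqrt(np.maximum(prof.n[ok], 1)))
        assert np.all(dev <= 3.5 * se)

    def test_planted_gaussian_depletion_depth_recovered(self):
        # box must extend well past the well so c_bulk is clean; the
        # depth of the known-width well is the recovered parameter
        spec = synth.BilayerSpec(n_lipids=2000, chol_fraction=0.4)
        traj, top = synth.gen_bilayer(spec, seed=59, n_frames=40)
        planted = synth.plant_structure(
            traj, top,
            synth.PlantedStructure(chol_depletion=synth.gaussian_depletion(0.5, 2.0)),
            seed=60,
        )
        prof = structure.radial_concentration(
            planted, top, "CHOL", bin_width=0.5,
            bulk_range=(7.0, traj.box.lx / 2 - 0.5),
        )
        depth, _ = structure.fit_gaussian_well(prof, bulk=1.0, sigma=2.0)
        assert depth == pytest.approx(0.5, abs=0.05)
        # the free two-parameter fit still locates a well of about the
        # right width
        _, width = structure.fit_gaussian_well(prof, bulk=1.0)
        assert width == pytest.approx(2.0, abs=0.8)

    def test_missing_species_rejected(self):
        spec = synth.BilayerSpec(n_lipids=40, chol_fraction=0.0)
        traj, top = synth.gen_bilayer(spec, seed=61)
        with pytest.raises(ValueError, match="CHOL"):
            structure.radial_concentration(traj, top, "CHOL")


class TestRdf2D:
    @staticmethod
    def _uniform_system(n, seed, frames=4, L=12.0):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, L, size=(frames, n, 3))
        return Trajectory(np.arange(float(frames)), pos, Box(L, L, 8.0))

    def test_uniform_uncorrelated_gives_unity(self):
        traj = self._uniform_system(800, 62)
        a = np.arange(400)
        b = np.arange(400, 800)
        prof = structure.rdf_2d(traj, a, b, bin_width=0.5, r_max=5.0)
        se = np.maximum(prof.stderr, 1e-3)
        assert np.all(np.abs(prof.value - 1.0) <= 4 * se)

    def test_hard_exclusion_zero_below_contact(self):
        rng = np.random.default_rng(63)
        L = 20.0
        a_pos = np.array([[10.0, 10.0, 4.0]])
        theta = rng.uniform(0, 2 * np.pi, 500)
        r = rng.uniform(1.0, 8.0, 500)  # nothing closer than 1 nm
        b_pos = np.column_stack(
            [10 + r * np.cos(theta), 10 + r * np.sin(theta), np.full(500, 4.0)]
        )
        pos = np.concatenate([a_pos, b_pos])[None]
        traj = Trajectory(np.array([0.0]), pos, Box(L, L, 8.0))
        prof = structure.rdf_2d(traj, np.array([0]), np.arange(1, 501),
                                bin_width=0.25, r_max=9.0)
        assert np.all(prof.value[prof.d < 0.95] == 0.0)
        assert prof.value[(prof.d > 2) & (prof.d < 7)].mean() > 0

    def test_matches_bruteforce_pair_histogram(self):
        traj = self._uniform_system(200, 64, frames=2)
        a = np.arange(80)
        b = np.arange(80, 200)
        bw, rmax = 0.4, 4.8
        prof = structure.rdf_2d(traj, a, b, bin_width=bw, r_max=rmax)
        # explicit python double loop
        edges = prof.d - bw / 2
        edges = np.append(edges, prof.d[-1] + bw / 2)
        hist = np.zeros(len(prof.d))
        L = np.array([traj.box.lx, traj.box.ly])
        for f in range(traj.n_frames):
            for i in a:
                for j in b:
                    d2 = traj.positions[f, j, :2] - traj.positions[f, i, :2]
                    d2 -= L * np.round(d2 / L)
                    r = np.hypot(*d2)
                    if r < rmax:
                        k = int(r // bw)
                        if k < len(hist):
                            hist[k] += 1
        areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        rho = b.size / traj.box.area_xy
        expected = hist / (traj.n_frames * a.size * rho * areas)
        assert np.allclose(prof.value, expected, rtol=1e-10)

    def test_rmax_beyond_half_box_rejected(self):
        traj = self._uniform_system(10, 65)
        with pytest.raises(ValueError):
            structure.rdf_2d(traj, np.array([0]), np.array([1]), r_max=7.0)


class TestThicknessProfile:
    def test_flat_bilayer_recovers_planted_separation(self):
        spec = synth.BilayerSpec(n_lipids=800, leaflet_separation_bulk=4.0)
        traj, top = synth.gen_bilayer(spec, seed=66, n_frames=6)
        prof = structure.thickness_profile(traj, top, bin_width=1.0)
        ok = np.isfinite(prof.value)
        assert np.all(np.abs(prof.value[ok] - 4.0) < 0.02)

    def test_planted_thinning_well_recovered(self):
        spec = synth.BilayerSpec(n_lipids=800, leaflet_separation_bulk=4.0)
        traj, top = synth.gen_bilayer(spec, seed=67, n_frames=8)
        planted = synth.plant_structure(
            traj, top,
            synth.PlantedStructure(thinning=synth.gaussian_thinning(4.0, 1.0, 2.0)),
            seed=68,
        )
        prof = structure.thickness_profile(planted, top, bin_width=0.5)
        depth, _ = structure.fit_gaussian_well(prof, bulk=4.0)
        assert depth == pytest.approx(1.0, abs=0.1)
        # plateau at bulk once the planted well has decayed (< 0.02 nm)
        far = prof.value[(prof.d > 6.0) & np.isfinite(prof.value)]
        assert far.size > 0
        assert np.all(np.abs(far - 4.0) < 0.05)

    def test_value_positive_regardless_of_label_order(self, small_bilayer):
        traj, top = small_bilayer
        swapped = top.df.copy()
        swapped["leaflet"] = swapped["leaflet"].map(
            {"upper": "lower", "lower": "upper", "none": "none"}
        )
        prof1 = structure.thickness_profile(traj, top, bin_width=2.0)
        prof2 = structure.thickness_profile(traj, Topology(swapped), bin_width=2.0)
        ok = np.isfinite(prof1.value)
        assert np.allclose(prof1.value[ok], prof2.value[ok])
        assert np.all(prof1.value[ok] > 0)

    def test_invariant_under_global_z_translation(self, small_bilayer):
        traj, top = small_bilayer
        shifted = Trajectory(traj.times, traj.positions + [0, 0, 1.7], traj.box)
        p1 = structure.thickness_profile(traj, top, bin_width=2.0)
        p2_ = structure.thickness_profile(shifted, top, bin_width=2.0)
        ok = np.isfinite(p1.value)
        assert np.allclose(p1.value[ok], p2_.value[ok], atol=1e-12)

    def test_missing_leaflet_labels_rejected(self, small_bilayer):
        traj, top = small_bilayer
        broken = top.df.copy()
        broken["leaflet"] = "none"
        with pytest.raises(ValueError, match="leaflet"):
            structure.thickness_profile(traj, Topology(broken))


class TestSnorkelFraction:
    def test_all_termini_in_head_slabs_gives_one(self, bilayer_with_np):
        traj, top = bilayer_with_np
        planted = synth.plant_structure(
            traj, top, synth.PlantedStructure(snorkel_fraction_target=1.0), seed=69
        )
        frac, series = structure.snorkel_fraction(planted, top)
        assert frac == pytest.approx(1.0)
        assert np.all(series == 1.0)

    def test_half_in_core_gives_half(self, bilayer_with_np):
        traj, top = bilayer_with_np
        planted = synth.plant_structure(
            traj, top, synth.PlantedStructure(snorkel_fraction_target=0.5), seed=70
        )
        frac, _ = structure.snorkel_fraction(planted, top)
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_uniform_termini_match_geometric_fraction(self):
        # geometric oracle: uniformly placed termini fall outside the core
        # band in proportion to 1 - band volume fraction
        rng = np.random.default_rng(71)
        lz = 10.0
        n_term, n_po4 = 4000, 100
        z_term = rng.uniform(0, lz, n_term)
        pos = np.zeros((n_term + n_po4, 3))
        pos[:n_term, 2] = z_term
        pos[n_term:, 2] = np.concatenate([np.full(50, 7.0), np.full(50, 3.0)])
        traj = Trajectory(np.array([0.0]), pos[None], Box(10, 10, lz))
        top = Topology.from_arrays(
            molecule_id=np.arange(n_term + n_po4),
            species=["MUS"] * n_term + ["DPPC"] * n_po4,
            role=["terminal"] * n_term + ["PO4"] * n_po4,
            charge=[-1.0] * n_term + [0.0] * n_po4,
        )
        half = 1.0
        frac, _ = structure.snorkel_fraction(traj, top, core_half_width=half)
        expected = 1.0 - 2 * half / lz
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(0.2 * 0.8 / n_term))

    def test_nonpositive_half_width_rejected(self, bilayer_with_np):
        traj, top = bilayer_with_np
        with pytest.raises(ValueError):
            structure.snorkel_fraction(traj, top, core_half_width=0.0)
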