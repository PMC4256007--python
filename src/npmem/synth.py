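"""Synthetic bilayer/nanoparticle configurations with planted structure.

Every analysis in this package is validated by recovery: the generators
here produce configurations whose order-parameter field, cholesterol
distribution, bilayer thickness, snorkeling fraction, free-energy
profile, or diffusion coefficient is known analytically, so the
estimators can be tested without running molecular dynamics.  The
generated structures are statistical stand-ins emulating a MARTINI-style
coarse-grained DPPC/cholesterol bilayer with an embedded ligand-coated
nanoparticle; they are not physical MD states (no integrator, no forces).

Geometry conventions: the bilayer is normal to z, centred at half the
box height; head groups sit at +/- half the phosphate-to-phosphate
separation.  Lipid tails are bead chains whose bond orientations are
drawn from a maximum-entropy distribution with a prescribed mean P2
(see :mod:`npmem._orient`).  Frames of a generated trajectory are
independent statistical snapshots, not time-correlated dynamics (the
Brownian generator is the exception: it produces genuine random-walk
dynamics for the diffusion machinery).

All generators are pure functions of (spec, seed): two calls with the
same arguments return bitwise-identical output.  Sub-streams are derived
from the single seed with fixed per-generator offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._orient import SAMPLER, p2
from .traj_io import Box, Topology, Trajectory, UmbrellaWindowSet, Window, lateral_distance

__all__ = [
    "KB",
    "DEFAULT_TEMPERATURE",
    "BOND_LENGTH",
    "BilayerSpec",
    "NPSpec",
    "PlantedStructure",
    "PlantedPMF",
    "gen_bilayer",
    "gen_np",
    "combine",
    "plant_structure",
    "gen_umbrella_samples",
    "gen_brownian2d",
    "gaussian_depletion",
    "gaussian_thinning",
    "radial_step",
    "double_well_pmf",
    "harmonic_pmf",
    "flat_pmf",
]

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083145

#: Simulation temperature of the study conditions, K.
DEFAULT_TEMPERATURE = 323.0

#: Coarse-grained bond length, nm.
BOND_LENGTH = 0.47

# per-molecule bead templates: (name, role, charge)
_DPPC_BEADS = [
    ("NC3", "choline", 1.0),
    ("PO4", "PO4", -1.0),
    ("GL1", "glycerol", 0.0),
    ("GL2", "glycerol", 0.0),
    ("C1A", "tail", 0.0),
    ("C2A", "tail", 0.0),
    ("C3A", "tail", 0.0),
    ("C4A", "tail", 0.0),
    ("C1B", "tail", 0.0),
    ("C2B", "tail", 0.0),
    ("C3B", "tail", 0.0),
    ("C4B", "tail", 0.0),
]
_CHOL_BEADS = [("ROH", "hydroxyl", 0.0)] + [(f"R{i}", "sterol", 0.0) for i in range(1, 8)]

#: z-jitter of planted head-group beads, nm.
_HEAD_Z_NOISE = 0.03


@dataclass
class BilayerSpec:
    """Composition and geometry of a two-leaflet DPPC/cholesterol bilayer.

    ``chol_fraction`` is the cholesterol mole fraction (the study spans
    0-50% mol.); ``leaflet_separation_bulk`` is the unperturbed
    PO4-to-PO4 distance.  If ``box_xy`` is None it is derived from the
    per-leaflet molecule count and ``area_per_lipid``.
    """

    n_lipids: int = 1250
    chol_fraction: float = 0.0
    box_xy: float | None = None
    leaflet_separation_bulk: float = 4.0  # nm, PO4-to-PO4
    area_per_lipid: float = 0.64  # nm^2
    temperature: float = DEFAULT_TEMPERATURE  # K

    def __post_init__(self) -> None:
        if not 0.0 <= self.chol_fraction <= 1.0:
            raise ValueError("chol_fraction must lie in [0, 1]")
        if self.n_lipids <= 0:
            raise ValueError("n_lipids must be positive")
        if self.box_xy is not None and self.box_xy <= 0:
            raise ValueError("box_xy must be positive")

    @property
    def n_chol(self) -> int:
        return int(round(self.n_lipids * self.chol_fraction))

    @property
    def n_dppc(self) -> int:
        return self.n_lipids - self.n_chol

    def resolved_box_xy(self) -> float:
        if self.box_xy is not None:
            return self.box_xy
        per_leaflet = (self.n_lipids + 1) // 2
        return float(np.sqrt(per_leaflet * self.area_per_lipid))


@dataclass
class NPSpec:
    """Ligand-coated nanoparticle: core sphere plus MUS/OT bead chains.

    The study particle has a 4.3 nm core coated at a 2:1 MUS:OT ratio
    with each anionic MUS terminus carrying -1 e, giving a total charge
    of -n_mus.
    """

    core_diameter: float = 4.3  # nm
    n_mus: int = 134
    n_ot: int = 67
    mus_charge: float = -1.0  # e per MUS terminal
    mus_length_beads: int = 4  # chain beads incl. terminal
    ot_length_beads: int = 2

    def __post_init__(self) -> None:
        if self.n_mus != 2 * self.n_ot:
            raise ValueError(
                f"MUS:OT ratio must be 2:1, got {self.n_mus}:{self.n_ot}"
            )
        if self.core_diameter <= 0:
            raise ValueError("core_diameter must be positive")

    @property
    def total_charge(self) -> float:
        return self.mus_charge * self.n_mus


FieldFn = Callable[[np.ndarray], np.ndarray]


def _as_field(f: FieldFn | float | None) -> FieldFn | None:
    if f is None or callable(f):
        return f
    val = float(f)
    return lambda d: np.full_like(np.asarray(d, dtype=float), val)


@dataclass
class PlantedStructure:
    """Radial targets planted around the nanoparticle.

    Each field maps lateral distance d (nm, from the NP centre of mass)
    to a target: ``p2_field`` the local mean P2 of tail bonds,
    ``chol_depletion`` the normalised cholesterol concentration
    c(d)/c_bulk, ``thinning`` the local PO4-PO4 thickness (nm).
    Fields may be callables, constants, or None (aspect left untouched).
    Depletion and thickness fields should tend to their bulk values as
    d grows; the Gaussian-well factories in this module do.
    """

    p2_field: FieldFn | float | None = None
    chol_depletion: FieldFn | float | None = None
    thinning: FieldFn | float | None = None
    snorkel_fraction_target: float | None = None

    def __post_init__(self) -> None:
        self.p2_field = _as_field(self.p2_field)
        self.chol_depletion = _as_field(self.chol_depletion)
        self.thinning = _as_field(self.thinning)
        if self.snorkel_fraction_target is not None and not (
            0.0 <= self.snorkel_fraction_target <= 1.0
        ):
            raise ValueError("snorkel_fraction_target must lie in [0, 1]")


def gaussian_depletion(depth: float = 0.5, sigma: float = 2.0) -> FieldFn:
    """Normalised concentration well 1 - depth*exp(-d^2/2sigma^2) -> 1."""
    return lambda d: 1.0 - depth * np.exp(-np.asarray(d, dtype=float) ** 2 / (2 * sigma**2))


def gaussian_thinning(bulk: float = 4.0, depth: float = 1.0, sigma: float = 2.0) -> FieldFn:
    """Thickness well bulk - depth*exp(-d^2/2sigma^2) -> bulk (nm)."""
    return lambda d: bulk - depth * np.exp(-np.asarray(d, dtype=float) ** 2 / (2 * sigma**2))


def radial_step(inner: float, outer: float, d0: float) -> FieldFn:
    """Step field: ``inner`` for d < d0, ``outer`` beyond."""
    return lambda d: np.where(np.asarray(d, dtype=float) < d0, inner, outer)


# ---------------------------------------------------------------------------
# bilayer generator
# ---------------------------------------------------------------------------


def _chain_orientations(
    rng: np.random.Generator, targets: np.ndarray, sign: np.ndarray
) -> np.ndarray:
    """Unit bond vectors with planted P2; z-component directed by ``sign``.

    P2 depends only on cos^2(alpha), so forcing the chain to head into
    the bilayer core (sign of the z-component) leaves the planted value
    unchanged.
    """
    u = SAMPLER.sample(rng, targets)
    uz = -np.asarray(sign, dtype=float) * np.abs(u)
    phi = rng.uniform(0.0, 2 * np.pi, size=uz.shape)
    s = np.sqrt(np.clip(1.0 - uz * uz, 0.0, None))
    return np.stack([s * np.cos(phi), s * np.sin(phi), uz], axis=-1)


def _build_bilayer_topology(spec: BilayerSpec) -> tuple[Topology, dict]:
    """Bead table plus per-molecule layout metadata (leaflet, kind)."""
    n_dppc_u = spec.n_dppc // 2 + spec.n_dppc % 2
    n_dppc_l = spec.n_dppc // 2
    n_chol_u = spec.n_chol // 2 + spec.n_chol % 2
    n_chol_l = spec.n_chol // 2

    mol_kind: list[str] = []
    mol_leaflet: list[str] = []
    for leaf, nd, nc in (("upper", n_dppc_u, n_chol_u), ("lower", n_dppc_l, n_chol_l)):
        mol_kind += ["DPPC"] * nd + ["CHOL"] * nc
        mol_leaflet += [leaf] * (nd + nc)

    molecule_id: list[int] = []
    species: list[str] = []
    role: list[str] = []
    charge: list[float] = []
    leaflet: list[str] = []
    names: list[str] = []
    for mid, (kind, leaf) in enumerate(zip(mol_kind, mol_leaflet)):
        beads = _DPPC_BEADS if kind == "DPPC" else _CHOL_BEADS
        for name, r, q in beads:
            molecule_id.append(mid)
            species.append(kind)
            role.append(r)
            charge.append(q)
            leaflet.append(leaf)
            names.append(name)
    top = Topology.from_arrays(molecule_id, species, role, charge, leaflet)
    layout = {
        "mol_kind": np.array(mol_kind, dtype=object),
        "mol_leaflet": np.array(mol_leaflet, dtype=object),
        "names": names,
    }
    return top, layout


def _grow_chains(
    rng: np.random.Generator,
    start: np.ndarray,
    signs: np.ndarray,
    n_bonds: int,
    bond_length: float,
    box: Box,
    p2_fn: FieldFn | None,
    np_com_xy: np.ndarray | None,
    const_target: float,
) -> np.ndarray:
    """Grow bead chains bond by bond, vectorised over molecules.

    Returns positions of shape (n_chains, n_bonds, 3).  For a spatially
    varying target the P2 level of each bond is evaluated at the chain's
    current end point, so the bond midpoint sits within half a bond
    length of where its target applies.
    """
    n = start.shape[0]
    out = np.empty((n, n_bonds, 3))
    cur = start.copy()
    for j in range(n_bonds):
        if p2_fn is not None and np_com_xy is not None:
            targets = np.asarray(p2_fn(lateral_distance(cur, np_com_xy, box)))
        else:
            targets = np.full(n, const_target)
        vec = _chain_orientations(rng, targets, signs)
        cur = cur + bond_length * vec
        out[:, j, :] = cur
    return out


def _place_lipids(
    rng: np.random.Generator,
    spec: BilayerSpec,
    layout: dict,
    box: Box,
    anchors_xy: np.ndarray,
    thickness_fn: FieldFn | None,
    p2_fn: FieldFn | None,
    np_com_xy: np.ndarray | None,
    tail_p2: float,
) -> np.ndarray:
    """Build one frame's bead positions from per-molecule xy anchors."""
    z_mid = box.lz / 2.0
    kinds = layout["mol_kind"]
    leafs = layout["mol_leaflet"]
    is_dppc = kinds == "DPPC"
    signs = np.where(leafs == "upper", 1.0, -1.0)

    if thickness_fn is not None and np_com_xy is not None:
        d_anchor = lateral_distance(
            np.column_stack([anchors_xy, np.zeros(len(anchors_xy))]), np_com_xy, box
        )
        local_sep = np.asarray(thickness_fn(d_anchor), dtype=float)
    else:
        local_sep = np.full(len(kinds), spec.leaflet_separation_bulk)
    z_head = (
        z_mid
        + signs * local_sep / 2.0
        + rng.normal(0.0, _HEAD_Z_NOISE, size=len(kinds))
    )

    sizes = np.where(is_dppc, 12, 8)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    pos = np.empty((offsets[-1], 3))

    # --- DPPC head groups and glycerol backbone ---
    dp = np.nonzero(is_dppc)[0]
    if dp.size:
        s = signs[dp]
        xy = anchors_xy[dp]
        zh = z_head[dp]
        base = offsets[dp]
        head = np.empty((dp.size, 4, 3))
        head[:, 0] = np.column_stack([xy, zh + s * 0.30])  # NC3 toward water
        head[:, 1] = np.column_stack([xy, zh])  # PO4
        gl_z = zh - s * 0.30
        head[:, 2] = np.column_stack([xy, gl_z])  # GL1
        head[:, 3] = np.column_stack([xy[:, 0] + 0.25, xy[:, 1], gl_z])  # GL2
        for k in range(4):
            pos[base + k] = head[:, k]
        for start_k, off_k in ((2, 4), (3, 8)):  # two tails of 4 beads each
            chains = _grow_chains(
                rng, head[:, start_k], s, 4, BOND_LENGTH, box,
                p2_fn, np_com_xy, tail_p2,
            )
            for j in range(4):
                pos[base + off_k + j] = chains[:, j]

    # --- cholesterol: hydroxyl plus a compact ordered sterol body ---
    ch = np.nonzero(~is_dppc)[0]
    if ch.size:
        s = signs[ch]
        roh = np.column_stack([anchors_xy[ch], z_head[ch] - s * 0.35])
        base = offsets[ch]
        pos[base] = roh
        chains = _grow_chains(
            rng, roh, s, 7, BOND_LENGTH * 0.6, box, None, None, 0.9
        )
        for j in range(7):
            pos[base + 1 + j] = chains[:, j]

    # wrap laterally into the box
    pos[:, 0] %= box.lx
    pos[:, 1] %= box.ly
    return pos


def gen_bilayer(
    spec: BilayerSpec,
    seed: int,
    n_frames: int = 1,
    frame_spacing: float = 1.0,
    tail_p2: float = 0.7,
    with_water: bool = False,
    waters_per_lipid: float = 28.0,
) -> tuple[Trajectory, Topology]:
    """Generate a two-leaflet DPPC/cholesterol bilayer.

    Molecule counts follow the spec exactly (cholesterol count rounded
    from the mole fraction); the two leaflets are symmetric to within one
    molecule per species.  Frames are independent snapshots spaced
    ``frame_spacing`` ns apart; ``tail_p2`` sets the uniform default tail
    order (override spatial structure with :func:`plant_structure`).

    ``with_water`` adds inert W beads in the water slabs for file-format
    realism only; no analysis in this package consumes them.  The number
    of CG water beads per lipid is exposed as a free parameter.
    """
    top, layout = _build_bilayer_topology(spec)
    lxy = spec.resolved_box_xy()
    box = Box(lxy, lxy, spec.leaflet_separation_bulk + 6.0)
    rng = np.random.default_rng([int(seed), 1])
    n_mol = len(layout["mol_kind"])
    frames = []
    for _ in range(n_frames):
        anchors = rng.uniform(0.0, lxy, size=(n_mol, 2))
        frames.append(
            _place_lipids(rng, spec, layout, box, anchors, None, None, None, tail_p2)
        )
    positions = np.stack(frames)

    if with_water:
        n_w = int(round(waters_per_lipid * spec.n_lipids / 4.0))  # 4:1 CG mapping
        half = spec.leaflet_separation_bulk / 2.0 + 0.8
        z_mid = box.lz / 2.0
        w_frames = []
        for _ in range(n_frames):
            w = rng.uniform(0.0, 1.0, size=(n_w, 3))
            w[:, 0] *= box.lx
            w[:, 1] *= box.ly
            slab = box.lz / 2.0 - half
            upper = w[:, 2] < 0.5
            w[:, 2] = np.where(
                upper,
                z_mid + half + (w[:, 2] / 0.5) * slab,
                z_mid - half - ((w[:, 2] - 0.5) / 0.5) * slab,
            )
            w_frames.append(w)
        positions = np.concatenate([positions, np.stack(w_frames)], axis=1)
        w_top = Topology.from_arrays(
            np.arange(n_w) + n_mol, ["W"] * n_w, ["chain"] * n_w
        )
        top = top.concat(w_top)

    times = np.arange(n_frames, dtype=float) * frame_spacing
    return Trajectory(times, positions, box), top


# ---------------------------------------------------------------------------
# nanoparticle generator
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def gen_np(
    spec: NPSpec, seed: int, center: Sequence[float] = (0.0, 0.0, 0.0)
) -> tuple[np.ndarray, Topology]:
    """Generate nanoparticle bead coordinates and topology fragment.

    Core beads tile the sphere of ``core_diameter``; ligands are radial
    bead chains anchored at uniformly distributed surface sites, MUS and
    OT interleaved at the fixed 2:1 ratio.  Each MUS terminal bead
    carries ``mus_charge`` (-1 e), so the particle's total charge equals
    -n_mus.  The whole particle is one molecule.
    """
    rng = np.random.default_rng([int(seed), 2])
    r_core = spec.core_diameter / 2.0
    n_core = max(1, int(round(4 * np.pi * r_core**2 / 0.21)))
    core = _fibonacci_sphere(n_core) * r_core

    n_lig = spec.n_mus + spec.n_ot
    sites = _fibonacci_sphere(n_lig)
    lig_kind = np.array(["MUS"] * spec.n_mus + ["OT"] * spec.n_ot, dtype=object)
    rng.shuffle(lig_kind)

    pos = [core]
    species = ["NP_core"] * n_core
    role = ["core"] * n_core
    charge = [0.0] * n_core
    names = [f"AU{i}" for i in range(n_core)]
    for u, kind in zip(sites, lig_kind):
        length = spec.mus_length_beads if kind == "MUS" else spec.ot_length_beads
        for j in range(length):
            radial = r_core + BOND_LENGTH * (j + 1)
            jitter = rng.normal(0.0, 0.05, size=3)
            pos.append((u * radial + jitter)[None, :])
            species.append(kind)
            terminal = j == length - 1
            role.append("terminal" if terminal else "chain")
            charge.append(spec.mus_charge if (terminal and kind == "MUS") else 0.0)
            names.append(f"{kind[0]}{j}")
    positions = np.concatenate(pos, axis=0) + np.asarray(center, dtype=float)
    top = Topology.from_arrays(
        np.zeros(len(species), dtype=int), species, role, charge
    )
    return positions, top


def combine(
    traj: Trajectory, top: Topology, extra_positions: np.ndarray, extra_top: Topology
) -> tuple[Trajectory, Topology]:
    """Append a static bead set (e.g. the NP) to every frame."""
    extra = np.broadcast_to(
        extra_positions[None, :, :], (traj.n_frames, *extra_positions.shape)
    )
    positions = np.concatenate([traj.positions, extra], axis=1)
    return Trajectory(traj.times, positions, traj.box), top.concat(extra_top)


# ---------------------------------------------------------------------------
# structure planting
# ---------------------------------------------------------------------------


def plant_structure(
    traj: Trajectory,
    top: Topology,
    ps: PlantedStructure,
    seed: int,
    np_com_xy: Sequence[float] | None = None,
    core_half_width: float = 1.0,
    head_slab_half_width: float = 0.3,
) -> Trajectory:
    """Rewrite a bilayer trajectory so planted radial targets hold.

    For each frame: lipid-tail bond orientations are redrawn so the
    expected P2 at lateral distance d equals ``ps.p2_field(d)`` (targets
    evaluated at the growing chain's current position, so the bond
    midpoint sits within half a bond length of where its target was
    evaluated); cholesterol molecules are laterally redistributed by
    rejection sampling against ``ps.chol_depletion``; head-group heights
    follow ``ps.thinning``; and MUS terminal beads are split between the
    head-group slabs and the hydrophobic core band to match
    ``ps.snorkel_fraction_target`` exactly (count rounded per frame).
    """
    rng = np.random.default_rng([int(seed), 3])
    box = traj.box
    z_mid = box.lz / 2.0
    if np_com_xy is None:
        np_com_xy = np.array([box.lx / 2.0, box.ly / 2.0])
    np_com_xy = np.asarray(np_com_xy, dtype=float)

    mol = top.molecule_ids
    species = top.species
    leaflet = top.df["leaflet"].to_numpy(dtype=object)
    roles = top.roles

    def _mol_index_matrix(sp: str, width: int) -> np.ndarray:
        """(n_mol, width) bead indices per molecule, template order."""
        mols = np.unique(mol[species == sp])
        if mols.size == 0:
            return np.empty((0, width), dtype=int)
        rows = []
        for m in mols:
            idx = np.nonzero(mol == m)[0]
            if idx.size != width:
                raise ValueError(
                    f"{sp} molecule {m} has {idx.size} beads, expected {width}"
                )
            rows.append(idx)
        return np.stack(rows)

    dppc = _mol_index_matrix("DPPC", 12)
    chol = _mol_index_matrix("CHOL", 8)
    dppc_sign = (
        np.where(leaflet[dppc[:, 0]] == "upper", 1.0, -1.0) if dppc.size else None
    )

    # default bulk separation estimated from the current frame's PO4 planes
    po4 = top.select(role="PO4")
    spec_like_sep = None
    if po4.size:
        up = po4[leaflet[po4] == "upper"]
        lo = po4[leaflet[po4] == "lower"]
        if up.size and lo.size:
            spec_like_sep = float(
                traj.positions[0, up, 2].mean() - traj.positions[0, lo, 2].mean()
            )

    positions = traj.positions.copy()
    max_dep = None
    if ps.chol_depletion is not None:
        d_grid = np.linspace(0.0, np.hypot(box.lx, box.ly), 512)
        max_dep = float(np.max(ps.chol_depletion(d_grid)))
        if max_dep <= 0:
            raise ValueError("chol_depletion must be positive somewhere")

    for f in range(traj.n_frames):
        pos = positions[f]

        if ps.chol_depletion is not None and chol.size:
            # batched rejection sampling of new lateral anchors
            n = chol.shape[0]
            new_xy = np.empty((n, 2))
            pending = np.arange(n)
            while pending.size:
                cand = np.column_stack(
                    [
                        rng.uniform(0, box.lx, pending.size),
                        rng.uniform(0, box.ly, pending.size),
                        np.zeros(pending.size),
                    ]
                )
                d = lateral_distance(cand, np_com_xy, box)
                accept = rng.random(pending.size) < (
                    np.asarray(ps.chol_depletion(d), dtype=float) / max_dep
                )
                new_xy[pending[accept]] = cand[accept, :2]
                pending = pending[~accept]
            shift = new_xy - pos[chol[:, 0], :2]
            pos[chol, 0] += shift[:, 0:1]
            pos[chol, 1] += shift[:, 1:2]

        if dppc.size:
            s = dppc_sign
            if ps.thinning is not None:
                d = lateral_distance(pos[dppc[:, 1]], np_com_xy, box)
                local = np.asarray(ps.thinning(d), dtype=float)
                z_head = (
                    z_mid
                    + s * local / 2.0
                    + rng.normal(0.0, _HEAD_Z_NOISE, size=d.size)
                )
                dz = z_head - pos[dppc[:, 1], 2]
                pos[dppc[:, :4], 2] += dz[:, None]
            if ps.p2_field is not None:
                for start_col, tail_cols in ((2, slice(4, 8)), (3, slice(8, 12))):
                    chains = _grow_chains(
                        rng, pos[dppc[:, start_col]], s, 4, BOND_LENGTH, box,
                        ps.p2_field, np_com_xy, 0.0,
                    )
                    pos[dppc[:, tail_cols]] = chains

        if ps.snorkel_fraction_target is not None:
            term = np.nonzero((species == "MUS") & (roles == "terminal"))[0]
            if term.size:
                if po4.size == 0 or spec_like_sep is None:
                    raise ValueError("snorkel planting needs PO4 beads in both leaflets")
                k = int(round(ps.snorkel_fraction_target * term.size))
                order = rng.permutation(term.size)
                snork = term[order[:k]]
                buried = term[order[k:]]
                half_sep = spec_like_sep / 2.0
                leaf_sign = np.where(rng.random(snork.size) < 0.5, 1.0, -1.0)
                pos[snork, 2] = (
                    z_mid
                    + leaf_sign * half_sep
                    + rng.uniform(-head_slab_half_width, head_slab_half_width, snork.size)
                    * 0.9
                )
                pos[buried, 2] = z_mid + rng.uniform(
                    -core_half_width * 0.9, core_half_width * 0.9, buried.size
                )
    return Trajectory(traj.times.copy(), positions, box)


# ---------------------------------------------------------------------------
# planted free-energy profiles and umbrella samples
# ---------------------------------------------------------------------------


@dataclass
class PlantedPMF:
    """A known 1D free-energy profile along the NP-bilayer-centre distance.

    ``pmf`` maps xi (nm, on [0, span]) to kJ/mol; evaluation through
    :meth:`values` re-references the curve to zero at xi = span (the
    water phase), the convention used for reconstructed profiles.
    """

    pmf: Callable[[np.ndarray], np.ndarray]
    span: float = 7.0
    temperature: float = DEFAULT_TEMPERATURE

    def values(self, xi: np.ndarray) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        v = np.asarray(self.pmf(xi), dtype=float) - float(self.pmf(np.array([self.span]))[0])
        if not np.all(np.isfinite(v)):
            raise ValueError("planted PMF is not finite on its domain")
        return v

    @property
    def kBT(self) -> float:
        return KB * self.temperature


def flat_pmf(span: float = 7.0, temperature: float = DEFAULT_TEMPERATURE) -> PlantedPMF:
    return PlantedPMF(lambda xi: np.zeros_like(np.asarray(xi, dtype=float)), span, temperature)


def harmonic_pmf(
    a: float, c: float, span: float = 7.0, temperature: float = DEFAULT_TEMPERATURE
) -> PlantedPMF:
    """G(xi) = a (xi - c)^2."""
    return PlantedPMF(lambda xi: a * (np.asarray(xi, dtype=float) - c) ** 2, span, temperature)


def double_well_pmf(
    barrier: float = 28.0,
    barrier_loc: float = 1.5,
    min_loc: float = 4.5,
    min_depth: float = 8.0,
    barrier_width: float = 0.7,
    min_width: float = 0.8,
    span: float = 7.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> PlantedPMF:
    """Interface-minimum / core-barrier profile with an exact barrier.

    A Gaussian peak at ``barrier_loc`` and a Gaussian well at ``min_loc``
    are scaled so that max(G) - G(minimum) equals ``barrier`` exactly
    (to grid precision), emulating the shape of an NP-translocation
    profile: minimum at the bilayer-water interface, barrier toward the
    core, flat in the water phase.
    """

    def raw(xi: np.ndarray, amp: float) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        return amp * np.exp(
            -((xi - barrier_loc) ** 2) / (2 * barrier_width**2)
        ) - min_depth * np.exp(-((xi - min_loc) ** 2) / (2 * min_width**2))

    grid = np.linspace(0.0, span, 4001)
    amp0 = barrier - min_depth if barrier > min_depth else barrier / 2.0
    g0 = raw(grid, amp0)
    scale = barrier / (g0.max() - g0.min())
    # rescale both features jointly so the planted barrier is exact
    final_amp = amp0 * scale
    final_depth = min_depth * scale

    def f(xi: np.ndarray) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        return final_amp * np.exp(
            -((xi - barrier_loc) ** 2) / (2 * barrier_width**2)
        ) - final_depth * np.exp(-((xi - min_loc) ** 2) / (2 * min_width**2))

    return PlantedPMF(f, span, temperature)


def gen_umbrella_samples(
    ppmf: PlantedPMF,
    centers: Sequence[float],
    k: float,
    n_per_window: int,
    seed: int,
    dt: float = 0.1,
) -> UmbrellaWindowSet:
    """Draw i.i.d. biased samples from a planted PMF, window by window.

    For window i the sample density is proportional to
    exp(-[G(xi) + (k/2)(xi - c_i)^2] / kBT) on [0, span], realised by
    inverse-CDF sampling on a fine grid (20001 points; discretisation is
    far below the harmonic width sqrt(kBT/k)).  Sample times are spaced
    ``dt`` ns for use by the convergence-scan machinery.
    """
    centers = np.asarray(centers, dtype=float)
    if k <= 0:
        raise ValueError("force constant must be positive")
    if n_per_window < 1:
        raise ValueError("need at least one sample per window")
    if np.any(centers < 0) or np.any(centers > ppmf.span):
        raise ValueError("window centers must lie within [0, span]")
    grid = np.linspace(0.0, ppmf.span, 20001)
    g = ppmf.values(grid)
    kBT = ppmf.kBT
    rng = np.random.default_rng([int(seed), 4])
    windows = []
    times = np.arange(n_per_window, dtype=float) * dt
    for c in centers:
        logw = -(g + 0.5 * k * (grid - c) ** 2) / kBT
        logw -= logw.max()
        dens = np.exp(logw)
        norm = np.trapezoid(dens, grid)
        if not np.isfinite(norm) or norm <= 0:
            raise ValueError("biased density is not normalizable")
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(grid))])
        cdf /= cdf[-1]
        samples = np.interp(rng.random(n_per_window), cdf, grid)
        windows.append(Window(center=float(c), k=float(k), samples=samples, times=times.copy()))
    return UmbrellaWindowSet(windows, ppmf.temperature)


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------

#: 1 cm^2/s expressed in nm^2/ns.
CM2_PER_S_TO_NM2_PER_NS = 1.0e5


def gen_brownian2d(
    D: float,
    dt: float,
    n_steps: int,
    n_particles: int,
    seed: int,
    box: Box | None = None,
) -> Trajectory:
    """Independent 2D Brownian walkers with known diffusion coefficient.

    ``D`` is in cm^2/s (the unit diffusion tables are printed in); each
    Cartesian increment has variance 2*D*dt after conversion to
    nm^2/ns.  Positions are returned unwrapped (no periodic jumps), with
    z fixed at mid-box; D = 0 yields stationary particles.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if box is None:
        box = Box(50.0, 50.0, 10.0)
    rng = np.random.default_rng([int(seed), 5])
    d_nm = D * CM2_PER_S_TO_NM2_PER_NS
    sigma = np.sqrt(2.0 * d_nm * dt)
    start = np.empty((n_particles, 3))
    start[:, 0] = rng.uniform(0.0, box.lx, n_particles)
    start[:, 1] = rng.uniform(0.0, box.ly, n_particles)
    start[:, 2] = box.lz / 2.0
    steps = np.zeros((n_steps, n_particles, 3))
    if sigma > 0:
        steps[1:, :, :2] = rng.normal(0.0, sigma, size=(n_steps - 1, n_particles, 2))
    positions = start[None, :, :] + np.cumsum(steps, axis=0)
    times = np.arange(n_steps, dtype=float) * dt
    return Trajectory(times, positions, box)
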