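"""Structural observables of the NP-membrane system.

Implements the order-parameter machinery (per-bond P2, spatial maps,
liquid-ordered/disordered phase classification), number-density maps,
radial concentration profiles around the nanoparticle, lateral (2D)
radial distribution functions, PO4-PO4 thickness profiles, and the
snorkeling fraction of charged ligand termini.

All radial quantities are measured against the lateral (in-plane)
minimum-image distance from the nanoparticle centre of mass; the NP COM
is computed from the core beads by default (ligands optional).  Profile
standard errors come from block averaging over equal time blocks, since
consecutive frames of a real trajectory are autocorrelated and a naive
per-frame standard error would be optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .traj_io import Box, Frame, Topology, Trajectory, lateral_distance, min_image_disp

__all__ = [
    "ScalarField2D",
    "RadialProfile",
    "np_com",
    "tail_bonds",
    "p2_of_bonds",
    "p2_map",
    "classify_phase",
    "number_density_map",
    "radial_concentration",
    "rdf_2d",
    "thickness_profile",
    "snorkel_fraction",
    "block_stderr",
    "fit_gaussian_well",
]

PhaseLabel = Literal["Ld", "intermediate", "Lo"]


@dataclass
class ScalarField2D:
    """A binned 2D field: per-cell value, per-cell sample count.

    Cells that received no samples hold NaN in ``values`` (empty, not
    zero) and 0 in ``counts``.  ``edges1``/``edges2`` are the bin edges
    of the two axes (nm).
    """

    edges1: np.ndarray
    edges2: np.ndarray
    values: np.ndarray  # (n1, n2)
    counts: np.ndarray  # (n1, n2)
    axis_labels: tuple[str, str] = ("axis1", "axis2")

    @property
    def centers1(self) -> np.ndarray:
        return 0.5 * (self.edges1[1:] + self.edges1[:-1])

    @property
    def centers2(self) -> np.ndarray:
        return 0.5 * (self.edges2[1:] + self.edges2[:-1])

    @property
    def cell_areas(self) -> np.ndarray:
        """Per-cell area matrix (nm^2); edge cells may be partial."""
        return np.outer(np.diff(self.edges1), np.diff(self.edges2))

    def to_tsv(self, path) -> None:
        """Matrix TSV with axis headers; empty cells written as nan."""
        with open(path, "w") as fh:
            fh.write(
                "# rows: %s centers; cols: %s centers\n" % self.axis_labels
            )
            fh.write("\t" + "\t".join(f"{c:.4f}" for c in self.centers2) + "\n")
            for c1, row in zip(self.centers1, self.values):
                fh.write(f"{c1:.4f}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


@dataclass
class RadialProfile:
    """Values vs lateral distance d from the NP centre of mass."""

    d: np.ndarray  # bin centres, nm, strictly increasing
    value: np.ndarray
    stderr: np.ndarray
    n: np.ndarray  # samples per bin
    bulk_value: float | None = None  # reference used for normalisation

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if np.any(np.diff(self.d) <= 0) or np.any(self.d < 0):
            raise ValueError("bin centres must be non-negative and strictly increasing")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("d_nm\tvalue\tstderr\tn\n")
            for d, v, e, n in zip(self.d, self.value, self.stderr, self.n):
                fh.write(f"{d:.4f}\t{v:.6g}\t{e:.6g}\t{n:.6g}\n")


def np_com(frame: Frame, top: Topology, include_ligands: bool = False) -> np.ndarray:
    """Nanoparticle centre of mass (equal bead weights).

    Core beads only by default; the profiles in this package are defined
    relative to this point.
    """
    sel = top.select(species=("NP_core", "MUS", "OT") if include_ligands else "NP_core")
    if sel.size == 0:
        raise ValueError("no nanoparticle beads in topology")
    return frame.positions[sel].mean(axis=0)


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------


def tail_bonds(top: Topology) -> np.ndarray:
    """DPPC tail bond pairs: consecutive tail beads plus glycerol-first-tail.

    The DPPC template is (NC3, PO4, GL1, GL2, C1A..C4A, C1B..C4B); each
    lipid contributes 8 bonds (GL1-C1A, C1A-C2A, ..., GL2-C1B, ...),
    the field convention for MARTINI-style tail order parameters.
    """
    pairs = []
    mol = top.molecule_ids
    species = top.species
    for m in np.unique(mol[species == "DPPC"]):
        idx = np.nonzero(mol == m)[0]
        if idx.size < 12:
            raise ValueError(f"DPPC molecule {m} has {idx.size} beads, expected 12")
        gl1, gl2 = idx[2], idx[3]
        a = idx[4:8]
        b = idx[8:12]
        pairs.append([gl1, a[0]])
        pairs.extend([[a[j], a[j + 1]] for j in range(3)])
        pairs.append([gl2, b[0]])
        pairs.extend([[b[j], b[j + 1]] for j in range(3)])
    if not pairs:
        raise ValueError("topology contains no DPPC molecules")
    return np.asarray(pairs, dtype=int)


def p2_of_bonds(frame: Frame, bonds: np.ndarray, normal_axis: int = 2) -> np.ndarray:
    """Per-bond P2 = (3 cos^2 a - 1)/2 against the bilayer normal.

    a is the angle between the bond vector (minimum image) and the
    normal axis (z by default).  Values lie in [-0.5, 1]; a bond along
    the normal gives 1, a bond in the bilayer plane gives -0.5.
    """
    bonds = np.asarray(bonds, dtype=int)
    vec = min_image_disp(frame.positions[bonds[:, 0]], frame.positions[bonds[:, 1]], frame.box)
    norm = np.linalg.norm(vec, axis=1)
    if np.any(norm == 0):
        raise ValueError("zero-length bond encountered")
    cos_a = vec[:, normal_axis] / norm
    return 0.5 * (3.0 * cos_a**2 - 1.0)


def classify_phase(p2_value: float) -> PhaseLabel:
    """Map a P2 value to a bilayer phase label.

    Liquid-disordered (Ld) spans 0.2-0.5 and liquid-ordered (Lo) spans
    0.7-1; everything else in [-0.5, 1] - including the 0.5-0.7 gap and
    values below 0.2 - is 'intermediate'.  The classification is total
    and piecewise constant.
    """
    if not -0.5 - 1e-12 <= p2_value <= 1.0 + 1e-12:
        raise ValueError(f"P2 value {p2_value} outside [-0.5, 1]")
    if 0.2 <= p2_value <= 0.5:
        return "Ld"
    if 0.7 <= p2_value <= 1.0:
        return "Lo"
    return "intermediate"


def _grid_edges(lo: float, hi: float, bin_width: float) -> np.ndarray:
    """Uniform edges of width ``bin_width`` covering [lo, hi] exactly.

    When the range is not an integer multiple of the width the final bin
    is truncated at ``hi`` (consumers use actual edge-derived areas, so
    normalisation stays exact).
    """
    n = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n + 1)
    edges[-1] = min(edges[-1], hi)
    return edges


def p2_map(
    traj: Trajectory,
    top: Topology,
    bonds: np.ndarray | None = None,
    mode: Literal["dz", "xz"] = "dz",
    bin_width: float = 0.2,
    np_com_xy: Sequence[float] | None = None,
    time_window: tuple[float | None, float | None] | None = None,
) -> ScalarField2D:
    """Spatially averaged P2 map, binned by bond midpoint.

    ``mode='dz'`` bins by (lateral distance from the NP COM, z);
    ``mode='xz'`` bins by (x, z), the style of published map panels.
    Cells with no samples are NaN.  The two leaflets are averaged
    jointly.
    """
    if time_window is not None:
        traj = traj.time_window(*time_window)
    if bonds is None:
        bonds = tail_bonds(top)
    if len(bonds) == 0:
        raise ValueError("empty bond selection")
    box = traj.box
    if mode == "dz":
        if np_com_xy is None:
            np_com_xy = _resolve_np_com_xy(traj, top)
        d_max = min(box.lx, box.ly) / 2.0
        e1 = _grid_edges(0.0, d_max, bin_width)
    else:
        e1 = _grid_edges(0.0, box.lx, bin_width)
    e2 = _grid_edges(0.0, box.lz, bin_width)
    sums = np.zeros((len(e1) - 1, len(e2) - 1))
    counts = np.zeros_like(sums)
    for f in traj:
        vals = p2_of_bonds(f, bonds)
        mid = 0.5 * (f.positions[bonds[:, 0]] + f.positions[bonds[:, 1]])
        if mode == "dz":
            c1 = lateral_distance(mid, np.asarray(np_com_xy, dtype=float), box)
        else:
            c1 = mid[:, 0] % box.lx
        c2 = mid[:, 2]
        h_cnt, _, _ = np.histogram2d(c1, c2, bins=[e1, e2])
        h_sum, _, _ = np.histogram2d(c1, c2, bins=[e1, e2], weights=vals)
        sums += h_sum
        counts += h_cnt
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    labels = ("lateral_distance_nm", "z_nm") if mode == "dz" else ("x_nm", "z_nm")
    return ScalarField2D(e1, e2, values, counts, labels)


def _resolve_np_com_xy(traj: Trajectory, top: Topology) -> np.ndarray:
    try:
        return np_com(traj.frame(0), top)[:2]
    except ValueError:
        return np.array([traj.box.lx / 2.0, traj.box.ly / 2.0])


# ---------------------------------------------------------------------------
# density maps and radial profiles
# ---------------------------------------------------------------------------


def number_density_map(
    traj: Trajectory,
    selection: np.ndarray,
    bin_width: float = 0.2,
    plane: Literal["xz", "xy"] = "xz",
    time_window: tuple[float | None, float | None] | None = None,
) -> ScalarField2D:
    """Mean per-frame bead count per unit cell area (beads/nm^2).

    Mass conservation holds exactly: sum(values) * cell_area equals the
    mean selected-bead count per frame.  Cells never visited report a
    density of 0 but a count of 0 (so "zero density" regions, the white
    cells of an occupancy map, are distinguishable from unsampled axes
    ranges only through ``counts``).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if time_window is not None:
        traj = traj.time_window(*time_window)
    box = traj.box
    i1, i2 = (0, 2) if plane == "xz" else (0, 1)
    L1 = box.lengths[i1]
    L2 = box.lengths[i2]
    e1 = _grid_edges(0.0, L1, bin_width)
    e2 = _grid_edges(0.0, L2, bin_width)
    counts = np.zeros((len(e1) - 1, len(e2) - 1))
    for f in traj:
        c1 = f.positions[selection, i1] % L1
        c2 = f.positions[selection, i2] % L2
        h, _, _ = np.histogram2d(c1, c2, bins=[e1, e2])
        counts += h
    cell_area = np.outer(np.diff(e1), np.diff(e2))  # exact, incl. partial edge cells
    values = counts / (traj.n_frames * cell_area)
    labels = ("x_nm", "z_nm") if plane == "xz" else ("x_nm", "y_nm")
    return ScalarField2D(e1, e2, values, counts, labels)


def _molecule_com_xy(frame: Frame, top: Topology, mols: np.ndarray) -> np.ndarray:
    """Lateral COM per molecule; minimum-image averaging around the first bead."""
    out = np.empty((mols.size, 2))
    mol = top.molecule_ids
    for i, m in enumerate(mols):
        idx = np.nonzero(mol == m)[0]
        ref = frame.positions[idx[0]]
        disp = min_image_disp(ref, frame.positions[idx], frame.box)
        out[i] = (ref + disp.mean(axis=0))[:2]
    return out


def radial_concentration(
    traj: Trajectory,
    top: Topology,
    species: str,
    bin_width: float = 0.5,
    r_max: float | None = None,
    np_com_xy: Sequence[float] | None = None,
    mode: Literal["com", "bead"] = "com",
    bulk_range: tuple[float, float] | None = None,
    time_window: tuple[float | None, float | None] | None = None,
    n_blocks: int = 5,
) -> RadialProfile:
    """Normalised 2D radial concentration c(d)/c_bulk around the NP.

    Counts molecule centres of mass (or beads with ``mode='bead'``) in
    lateral annuli around the NP COM, divides by annulus area and frame
    count, then normalises by the bulk concentration estimated from the
    annuli in ``bulk_range`` (default [6 nm, min(lx,ly)/2 - 1 nm],
    because the NP's influence extends well past its core; for small
    boxes the default falls back to the outer half of the profile).
    Standard errors are block averages over ``n_blocks`` time blocks.
    """
    if time_window is not None:
        traj = traj.time_window(*time_window)
    sel = top.select(species=species)
    if sel.size == 0:
        raise ValueError(f"no beads of species {species!r} present")
    box = traj.box
    if np_com_xy is None:
        np_com_xy = _resolve_np_com_xy(traj, top)
    np_com_xy = np.asarray(np_com_xy, dtype=float)
    if r_max is None:
        r_max = min(box.lx, box.ly) / 2.0
    edges = _grid_edges(0.0, r_max, bin_width)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    mols = np.unique(top.molecule_ids[sel])

    per_frame = np.empty((traj.n_frames, len(edges) - 1))
    for i, f in enumerate(traj):
        if mode == "com":
            xy = _molecule_com_xy(f, top, mols)
            pts = np.column_stack([xy, np.zeros(len(xy))])
        else:
            pts = f.positions[sel]
        d = lateral_distance(pts, np_com_xy, box)
        h, _ = np.histogram(d, bins=edges)
        per_frame[i] = h / areas

    conc = per_frame.mean(axis=0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    if bulk_range is None:
        hi = min(box.lx, box.ly) / 2.0 - 1.0
        lo = 6.0 if hi > 7.0 else r_max / 2.0
        bulk_range = (lo, hi)
    bulk_mask = (centers >= bulk_range[0]) & (centers <= bulk_range[1])
    if not bulk_mask.any():
        raise ValueError("bulk reference region contains no annuli")
    c_bulk = conc[bulk_mask].mean()
    if c_bulk <= 0:
        raise ValueError("bulk concentration is zero; cannot normalise")
    stderr = block_stderr(per_frame, n_blocks) / c_bulk
    counts = per_frame.sum(axis=0) * areas / max(traj.n_frames, 1) * traj.n_frames
    return RadialProfile(centers, conc / c_bulk, stderr, counts, bulk_value=float(c_bulk))


def rdf_2d(
    traj: Trajectory,
    groupA: np.ndarray,
    groupB: np.ndarray,
    bin_width: float = 0.1,
    r_max: float | None = None,
    time_window: tuple[float | None, float | None] | None = None,
) -> RadialProfile:
    """Lateral (in-plane) radial distribution function g(r) of B around A.

    Pair distances use the 2D minimum image; normalisation is against
    the ideal-gas expectation from the mean planar density of group B,
    so an uncorrelated uniform system gives g(r) = 1.  ``r_max`` must
    not exceed half the smaller lateral box edge.
    """
    groupA = np.asarray(groupA, dtype=int)
    groupB = np.asarray(groupB, dtype=int)
    if groupA.size == 0 or groupB.size == 0:
        raise ValueError("both groups must be nonempty")
    if time_window is not None:
        traj = traj.time_window(*time_window)
    box = traj.box
    half = min(box.lx, box.ly) / 2.0
    if r_max is None:
        r_max = half
    if r_max > half + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the lateral box ({half})")
    edges = _grid_edges(0.0, r_max, bin_width)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    rho_B = groupB.size / box.area_xy
    hist = np.zeros(len(edges) - 1)
    shared = np.intersect1d(groupA, groupB)
    for f in traj:
        a = f.positions[groupA]
        b = f.positions[groupB]
        diff = a[:, None, :2] - b[None, :, :2]
        L = np.array([box.lx, box.ly])
        diff -= L * np.round(diff / L)
        r = np.hypot(diff[..., 0], diff[..., 1]).ravel()
        if shared.size:  # self-pairs contribute r=0; drop them
            r = r[r > 1e-12]
        hist += np.histogram(r, bins=edges)[0]
    norm = traj.n_frames * groupA.size * rho_B * areas
    g = hist / norm
    centers = 0.5 * (edges[1:] + edges[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        stderr = np.where(hist > 0, g / np.sqrt(hist), 0.0)
    return RadialProfile(centers, g, stderr, hist, bulk_value=float(rho_B))


def thickness_profile(
    traj: Trajectory,
    top: Topology,
    bin_width: float = 0.5,
    r_max: float | None = None,
    np_com_xy: Sequence[float] | None = None,
    time_window: tuple[float | None, float | None] | None = None,
    n_blocks: int = 5,
) -> RadialProfile:
    """Radial bilayer thickness: <z_PO4,upper> - <z_PO4,lower> per annulus.

    Leaflets are ordered canonically (upper = larger mean z), so the
    value is positive for an intact bilayer regardless of labelling.
    Annuli missing PO4 beads in either leaflet are NaN with a count of 0.
    """
    if time_window is not None:
        traj = traj.time_window(*time_window)
    box = traj.box
    leaflets = top.df["leaflet"].to_numpy(dtype=object)
    po4 = top.select(role="PO4")
    if po4.size == 0:
        raise ValueError("no PO4 beads in topology")
    up = po4[leaflets[po4] == "upper"]
    lo = po4[leaflets[po4] == "lower"]
    if up.size == 0 or lo.size == 0:
        raise ValueError("leaflet labels missing: need PO4 beads in both leaflets")
    if np_com_xy is None:
        np_com_xy = _resolve_np_com_xy(traj, top)
    np_com_xy = np.asarray(np_com_xy, dtype=float)
    if r_max is None:
        r_max = min(box.lx, box.ly) / 2.0
    edges = _grid_edges(0.0, r_max, bin_width)
    nb = len(edges) - 1

    per_frame = np.full((traj.n_frames, nb), np.nan)
    counts = np.zeros(nb)
    for i, f in enumerate(traj):
        d_up = lateral_distance(f.positions[up], np_com_xy, box)
        d_lo = lateral_distance(f.positions[lo], np_com_xy, box)
        for bidx in range(nb):
            m_up = (d_up >= edges[bidx]) & (d_up < edges[bidx + 1])
            m_lo = (d_lo >= edges[bidx]) & (d_lo < edges[bidx + 1])
            if m_up.any() and m_lo.any():
                z_u = f.positions[up[m_up], 2].mean()
                z_l = f.positions[lo[m_lo], 2].mean()
                hi, low = max(z_u, z_l), min(z_u, z_l)
                per_frame[i, bidx] = hi - low
                counts[bidx] += m_up.sum() + m_lo.sum()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN annuli
        value = np.nanmean(per_frame, axis=0)
    stderr = block_stderr(per_frame, n_blocks)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RadialProfile(centers, value, stderr, counts)


def snorkel_fraction(
    traj: Trajectory,
    top: Topology,
    termini: np.ndarray | None = None,
    head_slab_half_width: float = 0.5,
    core_half_width: float = 1.0,
    time_window: tuple[float | None, float | None] | None = None,
) -> tuple[float, np.ndarray]:
    """Fraction of MUS termini outside the hydrophobic core band.

    A terminal bead counts as snorkeled when it is *not* in the core
    band |z - z_mid| < ``core_half_width`` (i.e. it sits in a head-group
    slab or the water phase).  z_mid is the PO4 midplane per frame.
    Returns the frame-averaged fraction and the per-frame series.
    """
    if head_slab_half_width <= 0 or core_half_width <= 0:
        raise ValueError("zone half-widths must be positive")
    if time_window is not None:
        traj = traj.time_window(*time_window)
    if termini is None:
        termini = top.select(species="MUS", role="terminal")
    termini = np.asarray(termini, dtype=int)
    if termini.size == 0:
        raise ValueError("no MUS terminal beads selected")
    po4 = top.select(role="PO4")
    if po4.size == 0:
        raise ValueError("no PO4 beads to define the midplane")
    series = np.empty(traj.n_frames)
    for i, f in enumerate(traj):
        z_mid = f.positions[po4, 2].mean()
        z = f.positions[termini, 2]
        in_core = np.abs(z - z_mid) < core_half_width
        series[i] = 1.0 - in_core.mean()
    return float(series.mean()), series


# ---------------------------------------------------------------------------
# statistics helpers
# ---------------------------------------------------------------------------


def block_stderr(per_frame: np.ndarray, n_blocks: int = 5) -> np.ndarray:
    """Standard error of the time mean from ``n_blocks`` equal blocks.

    ``per_frame`` is (n_frames, ...) and may contain NaN (ignored).
    With fewer frames than blocks, falls back to the naive SE.
    """
    import warnings as _warnings

    per_frame = np.asarray(per_frame, dtype=float)
    nf = per_frame.shape[0]
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        if nf >= n_blocks >= 2:
            bounds = np.linspace(0, nf, n_blocks + 1).astype(int)
            block_means = np.stack(
                [np.nanmean(per_frame[a:b], axis=0) for a, b in zip(bounds[:-1], bounds[1:])]
            )
            return np.nanstd(block_means, axis=0, ddof=1) / np.sqrt(n_blocks)
        if nf < 2:
            return np.zeros(per_frame.shape[1:])
        return np.nanstd(per_frame, axis=0, ddof=1) / np.sqrt(nf)


def fit_gaussian_well(
    profile: RadialProfile,
    bulk: float | None = None,
    sigma: float | None = None,
    weighted: bool = True,
) -> tuple[float, float]:
    """Fit value(d) = bulk - depth * exp(-d^2 / 2 sigma^2); return (depth, sigma).

    Used to recover planted Gaussian depletion/thinning wells.  ``bulk``
    defaults to the mean over the outer half of the profile.  With
    ``sigma`` given, only the depth is fitted (the one-parameter
    recovery of a well of known width; the free two-parameter fit is
    depth/width degenerate when inner annuli are sparse).  ``weighted``
    applies per-bin counting errors (Poisson for count-based profiles),
    which concentrates the fit where the data are informative.  NaN bins
    are ignored.
    """
    mask = np.isfinite(profile.value)
    d = profile.d[mask]
    v = profile.value[mask]
    if d.size < 4:
        raise ValueError("too few valid bins to fit a well")
    if bulk is None:
        bulk = float(v[d > d.max() / 2.0].mean())

    sig = None
    if weighted:
        n = np.maximum(profile.n[mask], 1.0)
        sig = np.where(v > 0, v, 1.0) / np.sqrt(n)
        sig = np.maximum(sig, 1e-6)

    depth0 = max(bulk - v.min(), 1e-3)
    if sigma is not None:

        def model1(x, depth):
            return bulk - depth * np.exp(-(x**2) / (2.0 * sigma**2))

        popt, _ = curve_fit(model1, d, v, p0=[depth0], sigma=sig, maxfev=10000)
        return float(popt[0]), float(sigma)

    def model(x, depth, width):
        return bulk - depth * np.exp(-(x**2) / (2.0 * width**2))

    popt, _ = curve_fit(
        model, d, v, p0=[depth0, 2.0], sigma=sig, maxfev=10000,
        bounds=([0.0, 0.1], [np.inf, np.inf]),
    )
    return float(popt[0]), float(popt[1])
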