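"""Coordinate, topology and umbrella-window I/O plus periodic geometry.

Conventions used throughout the package:

* lengths in nm, times in ns, energies in kJ/mol, charges in units of the
  elementary charge ``e``;
* orthorhombic periodic boxes only (the study membranes are rectangular);
* bead indices are 0-based in memory and 1-based in GRO files, as the
  format requires.

Coordinate files use the GRO fixed-column format (read and written through
MDAnalysis, converting its angstrom convention to nm).  Multi-frame
trajectories use a plain whitespace text format, one block per frame::

    # t <time_ns> box <lx> <ly> <lz> n <n_beads>
    <bead_index> <x> <y> <z>
    ...

The per-bead semantic map (species, role, charge, molecule id, leaflet) is
stored as a TSV "species table" with columns
``bead_index  molecule_id  species  role  charge  leaflet``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Box",
    "Frame",
    "Trajectory",
    "Topology",
    "Window",
    "UmbrellaWindowSet",
    "SPECIES",
    "ROLES",
    "min_image_disp",
    "min_image_dist",
    "lateral_distance",
    "read_gro",
    "write_gro",
    "read_traj",
    "write_traj",
    "read_window_records",
    "assign_leaflets",
]

#: Recognised bead species.
SPECIES = ("DPPC", "CHOL", "NP_core", "MUS", "OT", "W", "ION")

#: Recognised bead roles.
ROLES = (
    "PO4",
    "choline",
    "glycerol",
    "tail",
    "hydroxyl",
    "sterol",
    "terminal",
    "chain",
    "core",
)


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box with edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(f"box lengths must be positive, got {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def area_xy(self) -> float:
        return self.lx * self.ly


@dataclass
class Frame:
    """A single configuration: bead positions (nm) at one time (ns)."""

    time: float
    positions: np.ndarray  # (N, 3) nm
    box: Box

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """A stack of frames sharing one bead set and one box.

    ``positions`` has shape ``(n_frames, n_beads, 3)``; ``times`` is in ns.
    """

    times: np.ndarray
    positions: np.ndarray
    box: Box

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_beads, 3)")
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValueError("times and positions disagree on frame count")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.times[i], self.positions[i], self.box)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def time_window(self, begin: float | None = None, end: float | None = None) -> "Trajectory":
        """Frames with ``begin <= t <= end`` (either bound may be None)."""
        mask = np.ones(self.n_frames, dtype=bool)
        if begin is not None:
            mask &= self.times >= begin
        if end is not None:
            mask &= self.times <= end
        if not mask.any():
            raise ValueError("time window selects no frames")
        return Trajectory(self.times[mask], self.positions[mask], self.box)

    def last(self, span: float) -> "Trajectory":
        """The final ``span`` ns of the trajectory."""
        return self.time_window(begin=self.times[-1] - span)


class Topology:
    """Per-bead semantic map over raw coordinates.

    Wraps a :class:`pandas.DataFrame` with columns ``molecule_id``,
    ``species``, ``role``, ``charge`` and ``leaflet`` (one row per bead,
    in bead-index order).
    """

    COLUMNS = ("molecule_id", "species", "role", "charge", "leaflet")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"topology table lacks columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        bad = set(self.df["species"]) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species: {sorted(bad)}")
        bad = set(self.df["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        mus_term = (self.df["species"] == "MUS") & (self.df["role"] == "terminal")
        if mus_term.any() and not np.allclose(self.df.loc[mus_term, "charge"], -1.0):
            raise ValueError("every MUS terminal bead must carry charge -1 e")

    @classmethod
    def from_arrays(
        cls,
        molecule_id: Sequence[int],
        species: Sequence[str],
        role: Sequence[str],
        charge: Sequence[float] | None = None,
        leaflet: Sequence[str] | None = None,
    ) -> "Topology":
        n = len(molecule_id)
        df = pd.DataFrame(
            {
                "molecule_id": np.asarray(molecule_id, dtype=int),
                "species": list(species),
                "role": list(role),
                "charge": np.zeros(n) if charge is None else np.asarray(charge, dtype=float),
                "leaflet": ["none"] * n if leaflet is None else list(leaflet),
            }
        )
        return cls(df)

    @property
    def n_beads(self) -> int:
        return len(self.df)

    @property
    def charges(self) -> np.ndarray:
        return self.df["charge"].to_numpy(dtype=float)

    @property
    def molecule_ids(self) -> np.ndarray:
        return self.df["molecule_id"].to_numpy(dtype=int)

    @property
    def roles(self) -> np.ndarray:
        return self.df["role"].to_numpy(dtype=object)

    @property
    def species(self) -> np.ndarray:
        return self.df["species"].to_numpy(dtype=object)

    def select(
        self,
        species: str | Iterable[str] | None = None,
        role: str | Iterable[str] | None = None,
        leaflet: str | None = None,
    ) -> np.ndarray:
        """Bead indices matching all given criteria (may be empty)."""
        mask = np.ones(self.n_beads, dtype=bool)
        if species is not None:
            species = [species] if isinstance(species, str) else list(species)
            mask &= self.df["species"].isin(species).to_numpy()
        if role is not None:
            role = [role] if isinstance(role, str) else list(role)
            mask &= self.df["role"].isin(role).to_numpy()
        if leaflet is not None:
            mask &= (self.df["leaflet"] == leaflet).to_numpy()
        return np.nonzero(mask)[0]

    def concat(self, other: "Topology") -> "Topology":
        """Append another topology; molecule ids of ``other`` are shifted
        past the current maximum so they stay unique."""
        shift = self.df["molecule_id"].max() + 1 if self.n_beads else 0
        df2 = other.df.copy()
        df2["molecule_id"] = df2["molecule_id"] + shift
        return Topology(pd.concat([self.df, df2], ignore_index=True))

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(0, "bead_index", np.arange(self.n_beads))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Topology":
        df = pd.read_csv(path, sep="\t")
        if "bead_index" in df.columns:
            df = df.sort_values("bead_index").drop(columns="bead_index")
        return cls(df)


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------


def min_image_disp(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image displacement ``b - a``.

    Each component is wrapped into ``(-L/2, L/2]``.  Broadcasts over
    leading dimensions.
    """
    L = box.lengths
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d -= L * np.round(d / L)
    # np.round maps +L/2 to -L/2; fold back onto the half-open (-L/2, L/2]
    d = np.where(d <= -L / 2, d + L, d)
    return d


def min_image_dist(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Minimum-image Euclidean distance between points."""
    return np.linalg.norm(min_image_disp(a, b, box), axis=-1)


def lateral_distance(pos: np.ndarray, ref: np.ndarray, box: Box) -> np.ndarray:
    """In-plane (x, y) minimum-image distance from ``ref``.

    The bilayer lies in the xy-plane, so radial profiles around the
    nanoparticle centre of mass use this 2D distance.
    """
    pos = np.asarray(pos, dtype=float)
    ref = np.asarray(ref, dtype=float)
    L = np.array([box.lx, box.ly])
    d = pos[..., :2] - ref[..., :2]
    d -= L * np.round(d / L)
    d = np.where(d <= -L / 2, d + L, d)
    return np.hypot(d[..., 0], d[..., 1])


# ---------------------------------------------------------------------------
# GRO files (via MDAnalysis; nm <-> angstrom conversion at the boundary)
# ---------------------------------------------------------------------------


def read_gro(path: str | Path) -> tuple[Frame, list[str]]:
    """Read a single-frame GRO file.

    Returns the frame (positions in nm) and the per-bead atom names.
    Velocities, if present, are ignored.  Triclinic box lines with
    off-diagonal components are rejected: the toolkit supports
    orthorhombic boxes only.
    """
    import MDAnalysis as mda

    path = Path(path)
    text = path.read_text().splitlines()
    if len(text) < 2:
        raise ValueError(f"{path}: not a GRO file (fewer than 2 lines)")
    try:
        n_atoms = int(text[1].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed atom-count line") from exc
    if n_atoms == 0:
        raise ValueError(f"{path}: GRO file declares zero atoms")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # MDAnalysis raises OSError/EOFError variants
        raise ValueError(f"{path}: malformed GRO file ({exc})") from exc
    dims = u.dimensions
    if dims is None:
        raise ValueError(f"{path}: missing box line")
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ValueError(
            f"{path}: triclinic box (angles {dims[3:]}) not supported; "
            "orthorhombic boxes only"
        )
    box = Box(*(dims[:3] / 10.0))
    frame = Frame(0.0, u.atoms.positions.astype(float) / 10.0, box)
    return frame, [str(n) for n in u.atoms.names]


def write_gro(
    frame: Frame,
    names: Sequence[str],
    path: str | Path,
    resnames: Sequence[str] | None = None,
    resids: Sequence[int] | None = None,
) -> None:
    """Write a frame as a fixed-column GRO file (positions in nm).

    ``resnames``/``resids`` default to a single residue named SYS.
    """
    import MDAnalysis as mda

    n = frame.n_beads
    if len(names) != n:
        raise ValueError("names length does not match bead count")
    if resids is None:
        resids = np.ones(n, dtype=int)
    resids = np.asarray(resids, dtype=int)
    # map bead-level residue ids to MDAnalysis residue indices
    uniq, resindex = np.unique(resids, return_inverse=True)
    if resnames is None:
        res_names = ["SYS"] * len(uniq)
    else:
        res_names = [resnames[np.nonzero(resids == u)[0][0]] for u in uniq]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=len(uniq), atom_resindex=resindex, trajectory=True
        )
        u.add_TopologyAttr("names", list(names))
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("resids", uniq)
        u.atoms.positions = (frame.positions * 10.0).astype(np.float32)
        u.dimensions = [frame.box.lx * 10, frame.box.ly * 10, frame.box.lz * 10, 90, 90, 90]
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# plain-text trajectories
# ---------------------------------------------------------------------------


def write_traj(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-frame trajectory in the documented text format."""
    with open(path, "w") as fh:
        for f in traj:
            fh.write(
                f"# t {f.time:.6f} box {traj.box.lx:.6f} {traj.box.ly:.6f} "
                f"{traj.box.lz:.6f} n {f.n_beads}\n"
            )
            for i, (x, y, z) in enumerate(f.positions):
                fh.write(f"{i} {x:.6f} {y:.6f} {z:.6f}\n")


def read_traj(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_traj`."""
    times: list[float] = []
    frames: list[np.ndarray] = []
    box: Box | None = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.startswith("#"):
            raise ValueError(f"expected frame header, got: {line!r}")
        tok = line.split()
        t = float(tok[2])
        b = Box(float(tok[4]), float(tok[5]), float(tok[6]))
        n = int(tok[8])
        if box is None:
            box = b
        pos = np.empty((n, 3))
        for j in range(n):
            parts = lines[i].split()
            pos[int(parts[0])] = [float(parts[1]), float(parts[2]), float(parts[3])]
            i += 1
        times.append(t)
        frames.append(pos)
    if box is None:
        raise ValueError(f"{path}: empty trajectory file")
    return Trajectory(np.array(times), np.stack(frames), box)


# ---------------------------------------------------------------------------
# umbrella window records
# ---------------------------------------------------------------------------


@dataclass
class Window:
    """One umbrella window: harmonic bias and its reaction-coordinate series."""

    center: float  # nm
    k: float  # kJ/mol/nm^2
    samples: np.ndarray  # xi values, nm
    times: np.ndarray | None = None  # ns, same length as samples

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.k < 0:
            raise ValueError("force constant must be non-negative")
        if self.samples.size == 0:
            raise ValueError("window has no samples")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.samples.shape:
                raise ValueError("times and samples disagree in length")

    @property
    def n(self) -> int:
        return self.samples.size

    def bias(self, xi: np.ndarray) -> np.ndarray:
        """Harmonic bias energy (k/2)(xi - center)^2 in kJ/mol."""
        return 0.5 * self.k * (np.asarray(xi, dtype=float) - self.center) ** 2


@dataclass
class UmbrellaWindowSet:
    """A ladder of umbrella windows at one temperature."""

    windows: list[Window]
    temperature: float  # K

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("empty window set")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])


def read_window_records(
    paths: Sequence[str | Path],
    centers: Sequence[float],
    ks: Sequence[float] | float,
    temperature: float,
    equilibration: float = 200.0,
) -> UmbrellaWindowSet:
    """Read per-window two-column (time, xi) text series.

    ``equilibration`` (ns) discards the initial span of each series:
    samples with ``t < t0 + equilibration`` are dropped, matching the
    restrained-equilibration protocol before production sampling.
    """
    if len(paths) != len(centers):
        raise ValueError("need one bias center per window file")
    if np.isscalar(ks):
        ks = [float(ks)] * len(paths)
    elif len(ks) != len(paths):
        raise ValueError("need one force constant per window file")
    windows = []
    for path, c, k in zip(paths, centers, ks):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty files handled below
            data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            raise ValueError(f"{path}: empty window record")
        if data.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (time, xi)")
        t, xi = data[:, 0], data[:, 1]
        keep = t >= t[0] + equilibration
        if not keep.any():
            raise ValueError(
                f"{path}: no samples left after {equilibration} ns equilibration discard"
            )
        windows.append(Window(center=float(c), k=float(k), samples=xi[keep], times=t[keep]))
    return UmbrellaWindowSet(windows, temperature)


# ---------------------------------------------------------------------------
# leaflet assignment
# ---------------------------------------------------------------------------


def assign_leaflets(
    frame: Frame,
    top: Topology,
    np_com_xy: np.ndarray | None = None,
    exclusion_radius: float = 2.15,
) -> np.ndarray:
    """Per-bead leaflet labels ('upper'/'lower'/'none') for one frame.

    The midplane is the mean z of all PO4 beads, excluding those within
    ``exclusion_radius`` nm laterally of the nanoparticle centre (the NP
    locally distorts head-group heights and would bias the midplane).
    Lipid molecules are assigned by the sign of their PO4 (or hydroxyl,
    for cholesterol) z relative to the midplane.
    """
    anchors = {}  # molecule_id -> anchor z
    po4 = top.select(role="PO4")
    roh = top.select(role="hydroxyl")
    if po4.size == 0:
        raise ValueError("no PO4 beads; cannot assign leaflets")
    ref = po4
    if np_com_xy is not None:
        d = lateral_distance(frame.positions[po4], np.asarray(np_com_xy), frame.box)
        ref = po4[d > exclusion_radius]
        if ref.size == 0:
            ref = po4
    z_mid = frame.positions[ref, 2].mean()
    mol = top.molecule_ids
    labels = np.array(["none"] * top.n_beads, dtype=object)
    for idx in np.concatenate([po4, roh]):
        anchors[mol[idx]] = frame.positions[idx, 2]
    for m, z in anchors.items():
        labels[mol == m] = "upper" if z >= z_mid else "lower"
    return labels
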