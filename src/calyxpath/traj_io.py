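"""Readers and writers for the external formats the pipeline consumes.

Topologies come from PDB ATOM/HETATM records with author residue numbering
preserved verbatim, so selections like Y82, S34 or F100 resolve against the
numbering used in the source structure.  Coordinate trajectories (DCD, XTC,
NetCDF) are read through MDAnalysis and normalised to the internal units
(angstrom / ns).  Constraint-pulling time series arrive as Grace-dialect
XVG files (``#`` and ``@`` comment lines, two numeric columns).

No science lives here: this module only builds the in-memory data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "PullRecord",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_pull_xvg",
    "write_pull_xvg",
    "TrajIOError",
]


class TrajIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


# standard atomic masses, Da
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "CU": 63.546, "SE": 78.971,
}

WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3"})

# standard amino-acid residue names (protein detection)
PROTEIN_RESNAMES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
})


def _infer_element(atom_name: str, res_name: str) -> str:
    """Guess the element from a PDB atom name.

    Follows the PDB convention: the element normally occupies the first
    one or two characters of the right-justified name; leading digits
    (e.g. ``1HB``) are stripped.  Two-letter elements are only accepted
    for non-protein residues to avoid mistaking ``CA`` (alpha carbon)
    for calcium.
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise TrajIOError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if (
        two in ELEMENT_MASSES
        and len(two) == 2
        and res_name.upper() not in PROTEIN_RESNAMES
        and res_name.upper() not in WATER_RESNAMES
        and two not in {"CA", "CB", "CD", "CE", "CG", "CZ", "CH", "ND",
                        "NE", "NH", "NZ", "OD", "OE", "OG", "OH", "SD", "SG"}
    ):
        return two
    one = stripped[0].upper()
    if one in ELEMENT_MASSES:
        return one
    raise TrajIOError(f"unknown element for atom name {atom_name!r}")


@dataclass(frozen=True)
class Topology:
    """Static description of the particle system.

    Atom indices are 0-based and contiguous; residue numbers keep the
    author (PDB) numbering of the source structure.
    """

    atom_name: np.ndarray          # (N,) str
    residue_name: np.ndarray       # (N,) str
    residue_seq: np.ndarray        # (N,) int, author numbering
    chain_id: np.ndarray           # (N,) str
    mass: np.ndarray               # (N,) float, Da
    element: np.ndarray            # (N,) str
    is_water: np.ndarray           # (N,) bool
    is_ligand: np.ndarray          # (N,) bool

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        for name in ("residue_name", "residue_seq", "chain_id", "mass",
                     "element", "is_water", "is_ligand"):
            if len(getattr(self, name)) != n:
                raise TrajIOError(f"topology field {name} has wrong length")
        if n and np.any(self.mass <= 0):
            raise TrajIOError("all masses must be positive")
        if np.any(self.is_water & self.is_ligand):
            raise TrajIOError("is_water and is_ligand are mutually exclusive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def is_heavy(self) -> np.ndarray:
        return self.element != "H"

    @property
    def is_protein(self) -> np.ndarray:
        return ~self.is_water & ~self.is_ligand

    def select(
        self,
        residue_seq: int | Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
        ligand: bool | None = None,
        water: bool | None = None,
    ) -> np.ndarray:
        """Return sorted atom indices matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_seq is not None:
            wanted = np.atleast_1d(np.asarray(residue_seq, dtype=int))
            mask &= np.isin(self.residue_seq, wanted)
        if atom_names is not None:
            names = {a.strip() for a in atom_names}
            mask &= np.isin(
                np.char.strip(self.atom_name.astype(str)), sorted(names)
            )
        if heavy_only:
            mask &= self.is_heavy
        if ligand is not None:
            mask &= self.is_ligand == ligand
        if water is not None:
            mask &= self.is_water == water
        return np.flatnonzero(mask)

    def protein_residues(self) -> list[tuple[str, int]]:
        """Unique (chain_id, residue_seq) pairs of protein residues, in order."""
        seen: dict[tuple[str, int], None] = {}
        prot = self.is_protein
        for c, r in zip(self.chain_id[prot], self.residue_seq[prot]):
            seen.setdefault((str(c), int(r)))
        return list(seen)


@dataclass
class Trajectory:
    """Per-frame coordinates (angstrom) with time stamps (ns)."""

    topology: Topology
    coordinates: np.ndarray        # (F, N, 3) float, A
    times: np.ndarray              # (F,) float, ns
    box: np.ndarray | None = None  # (F, 3) orthorhombic box lengths, A

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        f, n, three = self.coordinates.shape
        if three != 3:
            raise TrajIOError("coordinates must be (frames, atoms, 3)")
        if n != self.topology.n_atoms:
            raise TrajIOError(
                f"coordinate atom count {n} != topology atom count "
                f"{self.topology.n_atoms}"
            )
        if len(self.times) != f:
            raise TrajIOError("times and coordinates disagree on frame count")
        if f > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajIOError("times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajIOError("coordinates contain non-finite values")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (f, 3):
                raise TrajIOError("box must be (frames, 3) orthorhombic lengths")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def slice_frames(self, key) -> "Trajectory":
        return Trajectory(
            topology=self.topology,
            coordinates=self.coordinates[key],
            times=self.times[key],
            box=None if self.box is None else self.box[key],
        )


@dataclass(frozen=True)
class PullRecord:
    """One constraint-pulling time series in native pull units.

    Times are ps; force values are kJ mol^-1 nm^-1, position values nm
    (the native units of the pull code output).
    """

    times: np.ndarray              # (T,) ps
    values: np.ndarray             # (T,)
    velocity: float                # m/s
    kind: str                      # "force" | "position"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.kind not in ("force", "position"):
            raise TrajIOError(f"kind must be force or position, got {self.kind!r}")
        if len(self.times) != len(self.values):
            raise TrajIOError("times and values differ in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajIOError("pull record times must be strictly increasing")
        if self.kind == "force" and not self.velocity > 0:
            raise TrajIOError("force records require a positive pulling velocity")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_topology(
    path: str | Path,
    water_resnames: Iterable[str] = WATER_RESNAMES,
    ligand_resnames: Iterable[str] | None = None,
) -> Topology:
    """Parse ATOM/HETATM records of a PDB file into a :class:`Topology`.

    Masses come from the element column (77-78) when present, otherwise
    from the atom name.  Waters are flagged by residue name
    (default whitelist HOH/WAT/SOL/TIP3); ligands are HETATM records that
    are not water, unless an explicit ``ligand_resnames`` whitelist is
    given.
    """
    path = Path(path)
    waters = {w.upper() for w in water_resnames}
    ligands = None if ligand_resnames is None else {l.upper() for l in ligand_resnames}

    names, resnames, resseqs, chains, masses, elements = [], [], [], [], [], []
    het_flags: list[bool] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise TrajIOError(
                    f"{path.name}:{lineno}: truncated {rec.strip()} record"
                )
            try:
                name = line[12:16]
                resname = line[17:20].strip() or line[17:21].strip()
                chain = line[21].strip() or "A"
                resseq = int(line[22:26])
            except ValueError as exc:
                raise TrajIOError(
                    f"{path.name}:{lineno}: malformed {rec.strip()} record: {exc}"
                ) from exc
            elem_col = line[76:78].strip().upper() if len(line) >= 78 else ""
            if elem_col and elem_col in ELEMENT_MASSES:
                element = elem_col
            else:
                element = _infer_element(name, resname)
            names.append(name.strip())
            resnames.append(resname)
            resseqs.append(resseq)
            chains.append(chain)
            elements.append(element)
            masses.append(ELEMENT_MASSES[element])
            het_flags.append(rec == "HETATM")
    if not names:
        raise TrajIOError(f"{path.name}: no ATOM/HETATM records found")

    resname_arr = np.array(resnames)
    is_water = np.isin(np.char.upper(resname_arr), sorted(waters))
    if ligands is None:
        is_ligand = np.array(het_flags) & ~is_water
    else:
        is_ligand = np.isin(np.char.upper(resname_arr), sorted(ligands)) & ~is_water
    return Topology(
        atom_name=np.array(names),
        residue_name=resname_arr,
        residue_seq=np.array(resseqs, dtype=int),
        chain_id=np.array(chains),
        mass=np.array(masses, dtype=float),
        element=np.array(elements),
        is_water=is_water,
        is_ligand=is_ligand,
    )


def write_topology(
    topology: Topology,
    path: str | Path,
    coordinates: np.ndarray | None = None,
) -> None:
    """Write a minimal PDB (ATOM/HETATM + element column) for the topology."""
    coords = (
        np.zeros((topology.n_atoms, 3))
        if coordinates is None
        else np.asarray(coordinates, dtype=float)
    )
    if coords.shape != (topology.n_atoms, 3):
        raise TrajIOError("coordinates must be (n_atoms, 3)")
    with open(path, "w") as fh:
        for i in range(topology.n_atoms):
            het = topology.is_ligand[i] or topology.is_water[i]
            rec = "HETATM" if het else "ATOM  "
            name = str(topology.atom_name[i])
            # PDB name column convention: 1-3 char names start in column 14
            fname = f" {name:<3s}" if len(name) < 4 else name[:4]
            x, y, z = coords[i]
            fh.write(
                f"{rec}{(i % 99999) + 1:5d} {fname}"
                f" {str(topology.residue_name[i])[:3]:>3s} "
                f"{str(topology.chain_id[i])[:1]}"
                f"{int(topology.residue_seq[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {str(topology.element[i]):>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Coordinate trajectories (via MDAnalysis readers)
# ---------------------------------------------------------------------------

def read_trajectory(
    topology: Topology,
    path: str | Path,
    stride: int = 1,
    default_dt_ns: float | None = None,
) -> Trajectory:
    """Read a coordinate trajectory (DCD/XTC/NetCDF/...) onto a topology.

    Coordinates are returned in angstrom and times in ns regardless of
    the source format's native units (MDAnalysis performs the nm -> A
    conversion for XTC).  ``stride`` keeps every ``stride``-th frame.
    ``default_dt_ns`` overrides the frame spacing when the file carries
    no usable time information.
    """
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe.empty(topology.n_atoms, trajectory=False)
    try:
        u.load_new(str(path))
    except ValueError as exc:
        # MDAnalysis raises before we can compare counts ourselves
        raise TrajIOError(
            f"atom-count mismatch reading {path.name}: topology has "
            f"{topology.n_atoms} atoms ({exc})"
        ) from exc
    n_file_atoms = u.trajectory.n_atoms
    if n_file_atoms != topology.n_atoms:
        raise TrajIOError(
            f"atom-count mismatch: trajectory {path.name} has {n_file_atoms} "
            f"atoms, topology has {topology.n_atoms}"
        )
    coords, times, boxes = [], [], []
    have_box = True
    for i, ts in enumerate(u.trajectory):
        if i % stride:
            continue
        coords.append(ts.positions.astype(float).copy())
        times.append(float(ts.time))  # ps in MDAnalysis
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            have_box = False
        else:
            boxes.append(ts.dimensions[:3].astype(float).copy())
    u.trajectory.close()
    times_ns = np.asarray(times) * 1.0e-3
    if default_dt_ns is not None or (
        len(times_ns) > 1 and not np.all(np.diff(times_ns) > 0)
    ):
        dt = default_dt_ns if default_dt_ns is not None else 1.0e-3
        times_ns = np.arange(len(coords)) * dt * stride
    return Trajectory(
        topology=topology,
        coordinates=np.asarray(coords),
        times=times_ns,
        box=np.asarray(boxes) if have_box and boxes else None,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write trajectory coordinates to DCD (or any format MDAnalysis infers)."""
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
    dt_ps = (
        float(np.mean(np.diff(traj.times))) * 1.0e3 if traj.n_frames > 1 else 1.0
    )
    with mda.Writer(str(path), n_atoms=traj.topology.n_atoms, dt=dt_ps) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coordinates[f]
            if traj.box is not None:
                u.dimensions = [*traj.box[f], 90.0, 90.0, 90.0]
            u.trajectory.ts.time = traj.times[f] * 1.0e3
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# XVG pull files
# ---------------------------------------------------------------------------

def read_pull_xvg(
    path: str | Path,
    kind: str = "force",
    velocity: float = 1.0,
) -> PullRecord:
    """Parse a two-column Grace-dialect XVG file into a :class:`PullRecord`.

    Lines beginning with ``#`` or ``@`` are skipped.  The first column is
    time (ps), the second the constraint force (kJ mol^-1 nm^-1) or
    position (nm), as declared by ``kind``.
    """
    path = Path(path)
    times, values = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise TrajIOError(
                    f"{path.name}:{lineno}: expected two columns, got {line!r}"
                )
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise TrajIOError(
                    f"{path.name}:{lineno}: non-numeric data: {line!r}"
                ) from exc
    if not times:
        raise TrajIOError(f"{path.name}: no data lines found")
    return PullRecord(
        times=np.asarray(times),
        values=np.asarray(values),
        velocity=velocity,
        kind=kind,
    )


def write_pull_xvg(record: PullRecord, path: str | Path) -> None:
    """Write a PullRecord back to a two-column XVG file."""
    with open(path, "w") as fh:
        fh.write("# constraint pulling output\n")
        label = (
            "force (kJ/mol/nm)" if record.kind == "force" else "position (nm)"
        )
        fh.write(f'@    yaxis  label "{label}"\n')
        for t, v in zip(record.times, record.values):
            fh.write(f"{t:.6f} {v:.10g}\n")
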