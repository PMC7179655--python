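"""Molecular data model: atoms, residues, parameterized systems, trajectories.

Structures are read from PDB text through Bio.PDB; force-field parameters
(partial charges, Lennard-Jones, generalized-Born radii/screens) are attached
from a tabular source by :mod:`mmgbsa_ie.params`. Internally indices are
0-based; author (PDB) residue numbers are kept for reporting, which uses the
1-based PDB convention.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .errors import (
    ClassificationError,
    EmptyInputError,
    ParseError,
    TopologyError,
)

__all__ = [
    "Atom",
    "Residue",
    "ParamSystem",
    "Trajectory",
    "read_structure",
    "write_pdb",
    "load_trajectory_pdb",
    "save_trajectory_text",
    "load_trajectory_text",
    "classify_residue",
    "select_pocket",
    "infer_bonds",
]

# Polarity classes by 3-letter code, including common protonation variants.
# TYR/TRP sit in the polar class by default (aromatic hydroxyl / indole NH);
# override via CLASS_OVERRIDES if a different convention is wanted.
_CHARGED = {"ASP", "GLU", "LYS", "ARG", "HIP"}
_POLAR = {
    "SER", "THR", "ASN", "GLN", "HIS", "HIE", "HID", "TYR", "TRP", "CYS",
    "CYX", "ASH", "GLH", "LYN",
}
_NONPOLAR = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "GLY"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "HIE": "H", "HID": "H", "HIP": "H", "ASH": "D",
    "GLH": "E", "LYN": "K", "CYX": "C",
}


def classify_residue(name: str, hint: str | None = None) -> str:
    """Polarity class ('nonpolar' | 'polar' | 'charged') of an amino acid.

    The class selects the interior dielectric (1 / 3 / 10) used by the
    residue-dielectric alanine-scanning energetics. ``hint`` may force a
    protonation variant (e.g. ``hint='HIP'`` for a doubly protonated His).
    """
    code = (hint or name).strip().upper()
    if code in _CHARGED:
        return "charged"
    if code in _POLAR:
        return "polar"
    if code in _NONPOLAR:
        return "nonpolar"
    raise ClassificationError(f"unknown residue code: {name!r}")


@dataclass
class Atom:
    """One atom with its per-atom force-field parameters.

    Parameters default to NaN until :func:`mmgbsa_ie.params.attach_parameters`
    fills them in. ``charge`` is in e, ``lj_rmin_half`` in Å, ``lj_epsilon``
    in kcal/mol, ``gb_radius`` (intrinsic Born radius) in Å, ``gb_screen``
    dimensionless.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    charge: float = math.nan
    lj_rmin_half: float = math.nan
    lj_epsilon: float = math.nan
    gb_radius: float = math.nan
    gb_screen: float = math.nan

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def parameterized(self) -> bool:
        return not any(
            math.isnan(v)
            for v in (self.charge, self.lj_rmin_half, self.lj_epsilon,
                      self.gb_radius, self.gb_screen)
        )


@dataclass
class Residue:
    index: int
    name: str
    chain: str
    resseq: int                       # author (PDB) residue number
    atom_start: int
    atom_stop: int                    # exclusive
    polarity_class: str | None = None
    is_ligand: bool = False

    @property
    def atom_indices(self) -> range:
        return range(self.atom_start, self.atom_stop)

    @property
    def label(self) -> str:
        """Compact residue label, e.g. 'Y907' for TYR with resseq 907."""
        one = THREE_TO_ONE.get(self.name.upper(), self.name[:1].upper())
        return f"{one}{self.resseq}"


@dataclass
class ParamSystem:
    """Topology fused with per-atom force-field parameters.

    ``reference_coords`` holds the coordinates of the first MODEL of the
    source structure (the crystal frame used for pocket selection).
    """

    atoms: list[Atom]
    residues: list[Residue]
    reference_coords: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if self.reference_coords.shape != (n, 3):
            raise TopologyError(
                f"reference coordinates shape {self.reference_coords.shape} "
                f"does not match {n} atoms"
            )
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise TopologyError(f"bond ({i}, {j}) out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def ligand_residue(self) -> Residue:
        ligs = [r for r in self.residues if r.is_ligand]
        if len(ligs) != 1:
            raise TopologyError(
                f"expected exactly one ligand residue, found {len(ligs)}"
            )
        return ligs[0]

    @property
    def ligand_atom_indices(self) -> np.ndarray:
        lig = self.ligand_residue
        return np.arange(lig.atom_start, lig.atom_stop)

    @property
    def protein_atom_indices(self) -> np.ndarray:
        lig = self.ligand_residue
        return np.array(
            [i for i in range(self.n_atoms)
             if not (lig.atom_start <= i < lig.atom_stop)],
            dtype=int,
        )

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_ligand]

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        r = self.residues[residue_index]
        return np.arange(r.atom_start, r.atom_stop)

    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def array(self, attr: str) -> np.ndarray:
        """Per-atom parameter vector, e.g. ``system.array('charge')``."""
        return np.array([getattr(a, attr) for a in self.atoms], dtype=float)

    def classify_residues(self, hints: dict[int, str] | None = None) -> None:
        """Assign polarity classes to all protein residues in place.

        The ligand is classed by its net formal charge: 'charged' when the
        summed partial charges round to a nonzero integer, else 'nonpolar'.
        """
        hints = hints or {}
        for r in self.residues:
            if r.is_ligand:
                q = sum(self.atoms[i].charge for i in r.atom_indices)
                q = 0.0 if math.isnan(q) else q
                r.polarity_class = "charged" if abs(round(q)) >= 1 else "nonpolar"
            else:
                r.polarity_class = classify_residue(r.name, hints.get(r.index))

    def copy(self) -> "ParamSystem":
        return ParamSystem(
            atoms=[replace(a) for a in self.atoms],
            residues=[replace(r) for r in self.residues],
            reference_coords=self.reference_coords.copy(),
            bonds=list(self.bonds),
        )


@dataclass
class Trajectory:
    """Ordered frames of Cartesian coordinates with equally spaced times."""

    coords: np.ndarray      # (n_frames, n_atoms, 3), Å
    times: np.ndarray       # ps, strictly increasing, equally spaced

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParseError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if len(self.times) != len(self.coords):
            raise ParseError("times and frames length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ParseError("times must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise ParseError("frames must be equally spaced to 1e-6 ps")

    @classmethod
    def from_coords(cls, coords: np.ndarray, dt: float = 1.0,
                    t0: float = 0.0) -> "Trajectory":
        coords = np.asarray(coords, dtype=float)
        times = t0 + dt * np.arange(len(coords))
        return cls(coords=coords, times=times)

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_interval(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def __getitem__(self, item) -> np.ndarray:
        return self.coords[item]

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(coords=self.coords[start:stop],
                          times=self.times[start:stop])

    def check_against(self, system: ParamSystem) -> None:
        if self.n_atoms != system.n_atoms:
            raise TopologyError(
                f"trajectory has {self.n_atoms} atoms, system has {system.n_atoms}"
            )


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _as_handle(source) -> io.StringIO:
    if hasattr(source, "read"):
        return source
    text = str(source)
    if "\n" in text or text.strip().startswith(("ATOM", "HETATM", "MODEL")):
        return io.StringIO(text)
    return open(text)


def _parse_pdb(source):
    handle = _as_handle(source)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        return parser.get_structure("system", handle)
    except PDBConstructionException as exc:
        raise ParseError(str(exc)) from exc
    except ValueError as exc:  # malformed numeric fields
        raise ParseError(f"malformed PDB record: {exc}") from exc


def _select_altloc(residue) -> list:
    """Atoms of a Bio.PDB residue with the highest-occupancy altloc kept."""
    out = []
    for atom in residue:
        if atom.is_disordered():
            children = atom.disordered_get_list()
            best = max(children, key=lambda a: (a.get_occupancy() or 0.0))
            out.append(best)
        else:
            out.append(atom)
    return out


def read_structure(source, ligand_resname: str | None = None) -> ParamSystem:
    """Read a PDB stream (text, path, or handle) into a ParamSystem.

    Atoms are grouped into residues preserving file order; the coordinates of
    the first MODEL become the reference frame. HETATM residues (excluding
    waters) are ligand candidates: if exactly one is present it is flagged
    automatically, otherwise ``ligand_resname`` selects it. Alternate
    locations keep only the highest-occupancy altloc.
    """
    structure = _parse_pdb(source)
    models = list(structure)
    if not models:
        raise EmptyInputError("PDB contains no models")
    model = models[0]

    atoms: list[Atom] = []
    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, _ = res.get_id()
            hetflag = hetflag.strip()
            if hetflag == "W":
                continue  # waters are never part of the analysis
            start = len(atoms)
            for atom in _select_altloc(res):
                element = (atom.element or atom.get_name()[0]).strip().upper()
                atoms.append(Atom(
                    serial=len(atoms),
                    name=atom.get_name(),
                    element=element,
                    residue_index=len(residues),
                ))
                coords.append(np.asarray(atom.get_coord(), dtype=float))
            if len(atoms) == start:
                continue
            residues.append(Residue(
                index=len(residues),
                name=res.get_resname().strip(),
                chain=chain.id if isinstance(chain.id, str) else str(chain.id),
                resseq=int(resseq),
                atom_start=start,
                atom_stop=len(atoms),
                is_ligand=bool(hetflag),
            ))
    if not atoms:
        raise EmptyInputError("PDB contains no atoms")

    system = ParamSystem(
        atoms=atoms,
        residues=residues,
        reference_coords=np.array(coords, dtype=float),
    )
    _resolve_ligand(system, ligand_resname)
    return system


def _resolve_ligand(system: ParamSystem, ligand_resname: str | None) -> None:
    candidates = [r for r in system.residues if r.is_ligand]
    if ligand_resname is not None:
        chosen = [r for r in system.residues
                  if r.name.upper() == ligand_resname.upper()]
        if not chosen:
            raise TopologyError(f"no residue named {ligand_resname!r}")
        for r in system.residues:
            r.is_ligand = False
        if len(chosen) > 1:
            raise TopologyError(f"residue name {ligand_resname!r} is ambiguous")
        chosen[0].is_ligand = True
        return
    if len(candidates) > 1:
        names = sorted({r.name for r in candidates})
        raise TopologyError(
            f"multiple HETATM groups {names}; pass ligand_resname to choose"
        )
    # zero candidates is allowed at read time (apo structure); ligand-requiring
    # operations raise through ParamSystem.ligand_residue.


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified into columns 13-14 for
    # single-letter elements with short names.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(system: ParamSystem, coords: np.ndarray | None = None,
              stream=None) -> str | None:
    """Write one frame as PDB text (returns the text if no stream given)."""
    coords = system.reference_coords if coords is None else np.asarray(coords)
    if coords.shape != (system.n_atoms, 3):
        raise TopologyError("coordinate shape does not match system")
    lines = []
    for res in system.residues:
        record = "HETATM" if res.is_ligand else "ATOM  "
        for i in res.atom_indices:
            a = system.atoms[i]
            x, y, z = coords[i]
            lines.append(
                f"{record}{(i + 1) % 100000:5d} "
                f"{_format_atom_name(a.name, a.element)} "
                f"{res.name:<3s} {res.chain[:1] or 'A'}{res.resseq % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{a.element:>2s}"
            )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if stream is None:
        return text
    stream.write(text)
    return None


def write_trajectory_pdb(system: ParamSystem, traj: Trajectory, stream) -> None:
    """Write a trajectory as a multi-MODEL PDB."""
    for k in range(traj.n_frames):
        stream.write(f"MODEL     {k + 1:4d}\n")
        stream.write(write_pdb(system, traj.coords[k]).replace("END\n", ""))
        stream.write("ENDMDL\n")
    stream.write("END\n")


def load_trajectory_pdb(source, system: ParamSystem | None = None,
                        dt: float = 1.0) -> Trajectory:
    """Load a multi-MODEL PDB as a trajectory (frame spacing ``dt`` ps)."""
    structure = _parse_pdb(source)
    frames = []
    for model in structure:
        xyz = []
        for chain in model:
            for res in chain:
                hetflag = res.get_id()[0].strip()
                if hetflag == "W":
                    continue
                for atom in _select_altloc(res):
                    xyz.append(atom.get_coord())
        frames.append(np.array(xyz, dtype=float))
    if not frames:
        raise EmptyInputError("PDB contains no models")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ParseError("models have differing atom counts")
    traj = Trajectory.from_coords(np.stack(frames), dt=dt)
    if system is not None:
        traj.check_against(system)
    return traj


# ---------------------------------------------------------------------------
# Plain-text trajectory container
# ---------------------------------------------------------------------------

def save_trajectory_text(traj: Trajectory, path) -> None:
    """Write a trajectory as a documented whitespace text table.

    Header comments carry the frame/atom counts and time base; the body is
    one ``x y z`` row per atom, frames concatenated in order.
    """
    t0 = float(traj.times[0]) if traj.n_frames else 0.0
    header = (
        "mmgbsa-ie trajectory v1\n"
        f"n_frames={traj.n_frames} n_atoms={traj.n_atoms} "
        f"dt_ps={traj.frame_interval:.6f} t0_ps={t0:.6f}\n"
        "columns: x_A y_A z_A"
    )
    np.savetxt(path, traj.coords.reshape(-1, 3), fmt="%.6f", header=header)


def load_trajectory_text(path) -> Trajectory:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    required = {"n_frames", "n_atoms", "dt_ps", "t0_ps"}
    if not required <= meta.keys():
        raise ParseError(f"trajectory header missing {sorted(required - meta.keys())}")
    data = np.loadtxt(path)
    n_frames, n_atoms = int(meta["n_frames"]), int(meta["n_atoms"])
    if data.size != n_frames * n_atoms * 3:
        raise ParseError("trajectory body does not match header counts")
    coords = data.reshape(n_frames, n_atoms, 3)
    return Trajectory.from_coords(coords, dt=float(meta["dt_ps"]),
                                  t0=float(meta["t0_ps"]))


# ---------------------------------------------------------------------------
# Pocket selection and bonds
# ---------------------------------------------------------------------------

def select_pocket(system: ParamSystem,
                  reference_frame: np.ndarray | None = None,
                  cutoff: float = 5.0) -> list[int]:
    """Protein residues with a heavy atom within ``cutoff`` Å of the ligand.

    Distances are measured between heavy atoms only, on the reference
    (crystal) frame by default. Returns residue indices in ascending order.
    """
    if cutoff <= 0 and cutoff != 0.0:
        raise ValueError("cutoff must be >= 0")
    coords = system.reference_coords if reference_frame is None else np.asarray(reference_frame)
    lig = system.ligand_residue
    heavy = system.heavy_mask()
    lig_idx = [i for i in lig.atom_indices if heavy[i]]
    if not lig_idx:
        raise TopologyError("ligand has no heavy atoms")
    lig_xyz = coords[lig_idx]
    pocket = []
    for res in system.protein_residues:
        res_idx = [i for i in res.atom_indices if heavy[i]]
        if not res_idx:
            continue
        d = np.linalg.norm(coords[res_idx][:, None, :] - lig_xyz[None, :, :], axis=-1)
        if d.min() <= cutoff:
            pocket.append(res.index)
    return pocket


def infer_bonds(system: ParamSystem, coords: np.ndarray | None = None,
                heavy_cutoff: float = 1.9, h_cutoff: float = 1.25) -> list[tuple[int, int]]:
    """Infer covalent bonds from interatomic distances within each residue
    and between consecutive protein residues (peptide bond)."""
    coords = system.reference_coords if coords is None else np.asarray(coords)
    bonds: list[tuple[int, int]] = []
    heavy = system.heavy_mask()
    n = system.n_atoms
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    ri = np.array([a.residue_index for a in system.atoms])
    for i in range(n):
        for j in range(i + 1, n):
            if abs(ri[i] - ri[j]) > 1:
                continue
            cut = heavy_cutoff if (heavy[i] and heavy[j]) else h_cutoff
            if not heavy[i] and not heavy[j]:
                continue
            if d[i, j] <= cut:
                bonds.append((i, j))
    return bonds
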