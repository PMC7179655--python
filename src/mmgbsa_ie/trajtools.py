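"""Structural trajectory analytics: RMSD, 2D-RMSD, B-factors, hydrogen bonds,
center-of-mass distances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import (
    ATOMIC_MASSES,
    HBOND_ANGLE_CUTOFF,
    HBOND_DISTANCE_CUTOFF,
)
from .errors import EmptyInputError, MMGBSAError
from .system import ParamSystem, Trajectory

__all__ = ["HBondRecord", "rmsd", "rmsd_series", "rmsd_matrix", "bfactor",
           "detect_hbonds", "hbond_occupancy", "com_distance", "atom_masses"]


@dataclass
class HBondRecord:
    """Per-bond summary over a trajectory.

    Mean distance/angle are averaged over ALL frames, bonded or not, so the
    mean distance can exceed the detection cutoff at partial occupancy.
    """

    donor: int            # heavy donor atom index
    hydrogen: int
    acceptor: int
    mean_distance: float  # Å, donor-heavy to acceptor
    mean_angle: float     # degrees, donor–H–acceptor
    occupancy: float      # %

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 100.0):
            raise ValueError("occupancy must be a percentage")


def _superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch-align ``mobile`` onto ``reference`` (centroids + rotation)."""
    if len(mobile) < 3:
        raise MMGBSAError("superposition needs at least 3 atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def rmsd(frame: np.ndarray, reference: np.ndarray, selection=None,
         superpose: bool = True) -> float:
    """Root-mean-square deviation (Å), optionally after optimal superposition."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        frame, reference = frame[sel], reference[sel]
    if frame.shape != reference.shape:
        raise ValueError("selection sizes must match")
    if superpose:
        frame = _superpose(frame, reference)
    diff = frame - reference
    return float(np.sqrt((diff * diff).sum() / len(frame)))


def rmsd_series(traj: Trajectory, reference: np.ndarray, selection=None,
                superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD (Å) against a fixed reference frame."""
    return np.array([rmsd(traj.coords[k], reference, selection, superpose)
                     for k in range(traj.n_frames)])


def rmsd_matrix(traj_a: Trajectory, traj_b: Trajectory, selection_a=None,
                selection_b=None, stride: int = 1) -> np.ndarray:
    """2D-RMSD: M[i, j] = rmsd(frame_i of a, frame_j of b), superposed.

    The selections must map atom-to-atom between the two systems (equal
    sizes). Symmetric with zero diagonal when a and b are the same
    trajectory and selection.
    """
    sel_a = None if selection_a is None else np.asarray(selection_a, dtype=int)
    sel_b = None if selection_b is None else np.asarray(selection_b, dtype=int)
    fa = traj_a.coords[::stride] if sel_a is None else traj_a.coords[::stride][:, sel_a]
    fb = traj_b.coords[::stride] if sel_b is None else traj_b.coords[::stride][:, sel_b]
    if fa.shape[1:] != fb.shape[1:]:
        raise ValueError("selection sizes must match between trajectories")
    m = np.empty((len(fa), len(fb)))
    for i in range(len(fa)):
        for j in range(len(fb)):
            m[i, j] = rmsd(fa[i], fb[j], superpose=True)
    return m


def bfactor(traj: Trajectory, selection=None, align: bool = True) -> np.ndarray:
    """Isotropic temperature factors B_i = (8π²/3)·⟨|r_i − ⟨r_i⟩|²⟩ (Å²).

    With ``align`` the frames are superposed (Kabsch, on the selection) onto
    their mean structure first, so rigid-body drift does not inflate B.
    """
    if traj.n_frames < 2:
        raise EmptyInputError("B-factors need at least 2 frames")
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(selection, dtype=int))
    frames = traj.coords[:, sel, :].astype(float)
    if align:
        ref = frames[0]
        frames = np.stack([_superpose(f, ref) for f in frames])
        mean = frames.mean(axis=0)
        frames = np.stack([_superpose(f, mean) for f in frames])
    mean = frames.mean(axis=0)
    msf = ((frames - mean) ** 2).sum(axis=2).mean(axis=0)
    return (8.0 * np.pi**2 / 3.0) * msf


def _hbond_geometry(coords: np.ndarray, donor: int, hydrogen: int,
                    acceptor: int) -> tuple[np.ndarray, np.ndarray]:
    """Donor–acceptor distance and donor–H–acceptor angle per frame."""
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    d = np.linalg.norm(coords[:, donor] - coords[:, acceptor], axis=-1)
    v1 = coords[:, donor] - coords[:, hydrogen]
    v2 = coords[:, acceptor] - coords[:, hydrogen]
    cosang = (v1 * v2).sum(-1) / (np.linalg.norm(v1, axis=-1)
                                  * np.linalg.norm(v2, axis=-1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return d, ang


def detect_hbonds(frame: np.ndarray, donors, acceptors,
                  d_cut: float = HBOND_DISTANCE_CUTOFF,
                  a_cut: float = HBOND_ANGLE_CUTOFF) -> list[tuple[int, int, int]]:
    """Hydrogen bonds in one frame.

    ``donors``: (heavy, hydrogen) index pairs — carbon donors are allowed;
    ``acceptors``: acceptor heavy-atom indices. A bond is reported iff the
    donor-heavy–acceptor distance is ≤ d_cut AND the donor–H–acceptor angle
    is ≥ a_cut (both cutoffs inclusive).
    """
    out = []
    for pair in donors:
        if len(pair) != 2 or pair[1] is None:
            raise MMGBSAError(f"donor {pair} carries no hydrogen")
        d_idx, h_idx = int(pair[0]), int(pair[1])
        for a_idx in acceptors:
            a_idx = int(a_idx)
            if a_idx in (d_idx, h_idx):
                continue
            dist, ang = _hbond_geometry(frame, d_idx, h_idx, a_idx)
            if dist[0] <= d_cut and ang[0] >= a_cut:
                out.append((d_idx, h_idx, a_idx))
    return out


def hbond_occupancy(traj: Trajectory, donor, acceptor: int,
                    d_cut: float = HBOND_DISTANCE_CUTOFF,
                    a_cut: float = HBOND_ANGLE_CUTOFF) -> HBondRecord:
    """Occupancy (%) and all-frame mean geometry of one candidate bond."""
    if traj.n_frames < 1:
        raise EmptyInputError("need at least one frame")
    d_idx, h_idx = int(donor[0]), int(donor[1])
    dist, ang = _hbond_geometry(traj.coords, d_idx, h_idx, int(acceptor))
    bonded = (dist <= d_cut) & (ang >= a_cut)
    return HBondRecord(
        donor=d_idx, hydrogen=h_idx, acceptor=int(acceptor),
        mean_distance=float(dist.mean()), mean_angle=float(ang.mean()),
        occupancy=float(100.0 * bonded.mean()),
    )


def atom_masses(system: ParamSystem) -> np.ndarray:
    return np.array([ATOMIC_MASSES.get(a.element.upper(), 0.0)
                     for a in system.atoms])


def com_distance(traj: Trajectory, group_a, group_b,
                 masses: np.ndarray | None = None) -> np.ndarray:
    """Per-frame distance (Å) between the mass-weighted centroids of two
    groups. Pass uniform masses for geometric centroids."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("groups must be non-empty")
    if masses is None:
        masses = np.ones(traj.n_atoms)
    masses = np.asarray(masses, dtype=float)
    for g in (a, b):
        if masses[g].sum() <= 0:
            raise MMGBSAError("zero total mass in group")
    com_a = (traj.coords[:, a] * masses[a][None, :, None]).sum(1) / masses[a].sum()
    com_b = (traj.coords[:, b] * masses[b][None, :, None]).sum(1) / masses[b].sum()
    return np.linalg.norm(com_a - com_b, axis=-1)
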