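"""Synthetic fixtures: toy host–guest complexes, parameterized energy series,
planted-geometry hydrogen-bond trajectories.

All generators are pure functions of (spec, seed): the same inputs give
bit-identical outputs via an independent ``numpy.random.default_rng`` stream
per call. The toys use chemically plausible but simplified parameters (net
residue charges 0 or −1, |partial charges| ≤ 0.8 e) so the Coulomb and GB
terms are well conditioned; they validate estimators, not biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .system import Atom, ParamSystem, Residue, Trajectory, infer_bonds

__all__ = ["ToySpec", "make_toy_complex", "gaussian_energy_series",
           "planted_hbond_trajectory"]

# element → (rmin_half Å, epsilon kcal/mol, gb_radius Å, gb_screen)
_ELEMENT_PARAMS = {
    "C": (1.9080, 0.1094, 1.70, 0.72),
    "H": (1.4870, 0.0157, 1.20, 0.85),
    "O": (1.6612, 0.2100, 1.50, 0.85),
    "N": (1.8240, 0.1700, 1.55, 0.79),
    "S": (2.0000, 0.2500, 1.80, 0.96),
}


@dataclass
class ToySpec:
    """Specification of a miniature host–guest complex.

    ``planted_strengths`` (kcal/mol, one per residue) scale each residue's
    sidechain-tip charge so the planted attraction to the ligand is monotone
    in the stated strength — used for rank-recovery validation.
    """

    n_pocket_residues: int = 4
    residue_names: list[str] | None = None       # default cycles ALA/SER/GLU
    ligand_charge: float = 1.0                    # e
    n_frames: int = 100
    jitter: float = 0.05                          # Å per coordinate
    tip_distance: float = 4.5                     # Å, sidechain tip → ligand COM
    planted_strengths: list[float] | None = None  # kcal/mol
    frame_interval_ps: float = 1.0


def _ligand_template(charge: float) -> tuple[list[tuple[str, str, float]], np.ndarray]:
    """5-atom tetrahedral cation: central N carries most of the charge."""
    atoms = [("N1", "N", min(0.8, charge - 4 * 0.05)),
             ("C1", "C", 0.05), ("C2", "C", 0.05),
             ("C3", "C", 0.05), ("C4", "C", 0.05)]
    total = sum(q for _, _, q in atoms)
    atoms[0] = ("N1", "N", atoms[0][2] + (charge - total))
    b = 1.47
    t = b / math.sqrt(3.0)
    xyz = np.array([[0.0, 0.0, 0.0], [t, t, t], [t, -t, -t],
                    [-t, t, -t], [-t, -t, t]])
    return atoms, xyz


# residue templates: (atom name, element, charge); CA at local origin with the
# sidechain extending along +x toward the ligand.
_RESIDUE_TEMPLATES = {
    "ALA": ([("N", "N", -0.30), ("CA", "C", 0.20), ("CB", "C", -0.10),
             ("HB1", "H", 0.05), ("HB2", "H", 0.05), ("HB3", "H", 0.05),
             ("C", "C", 0.45), ("O", "O", -0.40)],
            np.array([[0.0, -1.4, 0.6], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                      [2.0, 0.9, 0.3], [2.0, -0.9, 0.3], [1.6, 0.0, -1.1],
                      [-1.2, 0.8, 0.0], [-1.3, 2.0, 0.0]])),
    "SER": ([("N", "N", -0.30), ("CA", "C", 0.25), ("CB", "C", 0.20),
             ("OG", "O", -0.65), ("HG", "H", 0.40), ("HB2", "H", 0.05),
             ("HB3", "H", 0.05), ("C", "C", 0.40), ("O", "O", -0.40)],
            np.array([[0.0, -1.4, 0.6], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                      [2.2, 1.2, 0.0], [3.1, 1.1, 0.3], [1.8, -0.5, 0.9],
                      [1.8, -0.5, -0.9], [-1.2, 0.8, 0.0], [-1.3, 2.0, 0.0]])),
    "GLU": ([("N", "N", -0.30), ("CA", "C", 0.10), ("CB", "C", -0.05),
             ("CG", "C", 0.05), ("CD", "C", 0.60), ("OE1", "O", -0.75),
             ("OE2", "O", -0.75), ("C", "C", 0.50), ("O", "O", -0.40)],
            np.array([[0.0, -1.4, 0.6], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                      [2.2, 1.2, 0.2], [3.7, 1.2, 0.2], [4.3, 0.1, 0.1],
                      [4.3, 2.3, 0.3], [-1.2, 0.8, 0.0], [-1.3, 2.0, 0.0]])),
}


def make_toy_complex(spec: ToySpec, seed: int = 0) -> tuple[ParamSystem, Trajectory]:
    """Build a miniature parameterized complex plus a jittered trajectory.

    Residues sit on a ring of radius ``ring_radius`` around the ligand at
    the origin, sidechains pointing inward. Frames are the reference
    geometry plus i.i.d. Gaussian jitter of amplitude ``spec.jitter`` Å.
    """
    if spec.n_pocket_residues < 1:
        raise ValueError("need at least one pocket residue")
    rng = np.random.default_rng(seed)
    names = spec.residue_names or [
        ("ALA", "SER", "GLU")[i % 3] for i in range(spec.n_pocket_residues)]
    if len(names) != spec.n_pocket_residues:
        raise ValueError("residue_names length mismatch")
    strengths = spec.planted_strengths
    if strengths is not None and len(strengths) != spec.n_pocket_residues:
        raise ValueError("planted_strengths length mismatch")

    atoms: list[Atom] = []
    residues: list[Residue] = []
    coords: list[np.ndarray] = []

    def add_residue(name, template_atoms, template_xyz, resseq, is_ligand=False):
        start = len(atoms)
        for (aname, el, q), xyz in zip(template_atoms, template_xyz):
            rmh, eps, gbr, scr = _ELEMENT_PARAMS[el]
            atoms.append(Atom(serial=len(atoms), name=aname, element=el,
                              residue_index=len(residues), charge=q,
                              lj_rmin_half=rmh, lj_epsilon=eps,
                              gb_radius=gbr, gb_screen=scr))
            coords.append(np.asarray(xyz, dtype=float))
        residues.append(Residue(index=len(residues), name=name, chain="A",
                                resseq=resseq, atom_start=start,
                                atom_stop=len(atoms), is_ligand=is_ligand))

    for k, name in enumerate(names):
        tatoms, txyz = _RESIDUE_TEMPLATES[name.upper()]
        tatoms = [list(a) for a in tatoms]
        if strengths is not None:
            # scale every sidechain charge so the residue's net attraction to
            # the ligand is monotone in the planted strength (strength 5 on
            # the GLU template reproduces the full carboxylate)
            factor = 0.2 * float(strengths[k])
            backbone = {"N", "CA", "C", "O"}
            for a in tatoms:
                if a[0] not in backbone:
                    a[2] *= factor
        angle = 2.0 * math.pi * k / len(names)
        c, s = math.cos(angle), math.sin(angle)
        # sidechains extend along +x in the template; place each residue so
        # its furthest heavy sidechain atom sits at tip_distance from the
        # ligand center, with +x pointing inward
        heavy_x = max(x[0] for (aname, el, q), x in zip(tatoms, txyz)
                      if el != "H")
        ring = spec.tip_distance + heavy_x
        pos = ring * np.array([c, 0.0, s])
        inward = -pos / np.linalg.norm(pos)
        up = np.array([0.0, 1.0, 0.0])
        side = np.cross(up, inward)
        frame_rot = np.column_stack([inward, up, side])
        xyz = (np.asarray(txyz) @ frame_rot.T) + pos
        add_residue(name.upper(), [tuple(a) for a in tatoms], xyz, resseq=k + 1)

    lig_atoms, lig_xyz = _ligand_template(spec.ligand_charge)
    add_residue("LIG", lig_atoms, lig_xyz, resseq=len(names) + 1, is_ligand=True)

    reference = np.array(coords, dtype=float)
    system = ParamSystem(atoms=atoms, residues=residues,
                         reference_coords=reference)
    system.bonds = infer_bonds(system)
    system.classify_residues()

    jitter = rng.normal(0.0, spec.jitter,
                        size=(spec.n_frames, len(atoms), 3))
    traj = Trajectory.from_coords(reference[None] + jitter,
                                  dt=spec.frame_interval_ps)
    return system, traj


def gaussian_energy_series(mu: float, sigma: float, n: int,
                           seed: int = 0) -> np.ndarray:
    """i.i.d. normal interaction-energy draws (kcal/mol)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n, float(mu))
    return rng.normal(mu, sigma, size=n)


def _hbond_positions(distance: float, angle_deg: float) -> np.ndarray:
    """Donor at origin, H at (1,0,0); place the acceptor at the requested
    donor–acceptor distance and donor–H–acceptor angle."""
    theta = math.radians(180.0 - angle_deg)
    u = np.array([math.cos(theta), math.sin(theta), 0.0])
    # |H + t·u| = distance  with  H = (1,0,0)
    b = 2.0 * u[0]
    t = (-b + math.sqrt(b * b - 4.0 * (1.0 - distance**2))) / 2.0
    acceptor = np.array([1.0, 0.0, 0.0]) + t * u
    return np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], acceptor])


def planted_hbond_trajectory(occupancy_target: float, n_frames: int,
                             seed: int = 0) -> tuple[Trajectory, dict]:
    """Donor–H–acceptor triad toggling between bonded (3.0 Å / 165°) and
    broken (4.5 Å / 100°) geometry with Bernoulli(occupancy/100) per frame.

    Returns the trajectory and a spec dict with ``donor=(heavy, hydrogen)``,
    ``acceptor`` and the per-frame ground-truth ``bonded`` mask.
    """
    if not 0.0 <= occupancy_target <= 100.0:
        raise ValueError("occupancy target must be a percentage")
    rng = np.random.default_rng(seed)
    bonded_xyz = _hbond_positions(3.0, 165.0)
    broken_xyz = _hbond_positions(4.5, 100.0)
    bonded = rng.random(n_frames) < occupancy_target / 100.0
    coords = np.where(bonded[:, None, None], bonded_xyz[None], broken_xyz[None])
    traj = Trajectory.from_coords(coords, dt=1.0)
    return traj, {"donor": (0, 1), "acceptor": 2, "bonded": bonded}
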