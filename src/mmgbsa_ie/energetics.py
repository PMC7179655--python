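"""Gas-phase molecular-mechanics interaction energies.

Coulomb and Lennard-Jones energies between two disjoint atom groups, per
frame, with no nonbonded cutoff: end-state analysis sums every pair. The
interior dielectric enters as a 1/ε divisor of the Coulomb sum; for a scanned
residue it follows the residue's polarity class (1/3/10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_CONSTANT, DIELECTRIC_BY_CLASS
from .errors import EmptyInputError, SingularityError
from .system import ParamSystem, Trajectory

__all__ = ["EnergySeries", "coulomb_energy", "lj_energy",
           "interaction_energy_series"]

_MIN_DISTANCE = 1e-6  # Å; below this two atoms are treated as coincident


@dataclass
class EnergySeries:
    """Per-frame interaction-energy components between two atom groups."""

    frame_times: np.ndarray      # ps
    e_vdw: np.ndarray            # kcal/mol
    e_ele: np.ndarray            # kcal/mol
    group_a: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    group_b: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.e_vdw = np.asarray(self.e_vdw, dtype=float)
        self.e_ele = np.asarray(self.e_ele, dtype=float)
        if not (len(self.frame_times) == len(self.e_vdw) == len(self.e_ele)):
            raise ValueError("energy series arrays must share one length")

    @property
    def e_total(self) -> np.ndarray:
        return self.e_vdw + self.e_ele

    @property
    def mean_total(self) -> float:
        return float(self.e_total.mean())

    def __len__(self) -> int:
        return len(self.frame_times)

    def slice(self, idx) -> "EnergySeries":
        return EnergySeries(self.frame_times[idx], self.e_vdw[idx],
                            self.e_ele[idx], self.group_a, self.group_b)


def _check_groups(group_a, group_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("atom groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("atom groups must be disjoint")
    return a, b


def _pair_distances(coords: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    diff = coords[..., a, None, :] - coords[..., None, b, :]
    r = np.sqrt((diff * diff).sum(axis=-1))
    if np.any(r < _MIN_DISTANCE):
        raise SingularityError("coincident atoms in pairwise energy")
    return r


def coulomb_energy(coords: np.ndarray, charges: np.ndarray,
                   group_a, group_b, eps_in: float = 1.0) -> float:
    """Pairwise Coulomb energy (kcal/mol) between two disjoint groups.

    ``sum_ij k_e q_i q_j / (eps_in * r_ij)`` with k_e = 332.0636
    kcal·Å/(mol·e²); no distance cutoff.
    """
    if eps_in < 1.0:
        raise ValueError("eps_in must be >= 1")
    a, b = _check_groups(group_a, group_b)
    charges = np.asarray(charges, dtype=float)
    r = _pair_distances(coords, a, b)
    qq = np.outer(charges[a], charges[b])
    return float(COULOMB_CONSTANT / eps_in * (qq / r).sum())


def lj_energy(coords: np.ndarray, rmin_half: np.ndarray, epsilon: np.ndarray,
              group_a, group_b) -> float:
    """Pairwise 12-6 Lennard-Jones energy (kcal/mol), Lorentz–Berthelot.

    ``eps_ij [ (Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6 ]`` with
    Rmin_ij = rmin_half_i + rmin_half_j and eps_ij = sqrt(eps_i eps_j).
    """
    a, b = _check_groups(group_a, group_b)
    rmin_half = np.asarray(rmin_half, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    r = _pair_distances(coords, a, b)
    rmin = rmin_half[a][:, None] + rmin_half[b][None, :]
    eps = np.sqrt(np.outer(epsilon[a], epsilon[b]))
    x6 = (rmin / r) ** 6
    return float((eps * (x6 * x6 - 2.0 * x6)).sum())


def _frame_energies(coords: np.ndarray, charges, rmin_half, epsilon,
                    a: np.ndarray, b: np.ndarray,
                    eps_in: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-frame (e_ele, e_vdw) over a (F, n, 3) coordinate stack."""
    r = _pair_distances(coords, a, b)                      # (F, |a|, |b|)
    qq = np.outer(np.asarray(charges)[a], np.asarray(charges)[b])
    e_ele = COULOMB_CONSTANT / eps_in * (qq / r).sum(axis=(-2, -1))
    rmin = np.asarray(rmin_half)[a][:, None] + np.asarray(rmin_half)[b][None, :]
    eps = np.sqrt(np.outer(np.asarray(epsilon)[a], np.asarray(epsilon)[b]))
    x6 = (rmin / r) ** 6
    e_vdw = (eps * (x6 * x6 - 2.0 * x6)).sum(axis=(-2, -1))
    return e_ele, e_vdw


def interaction_energy_series(traj: Trajectory, system: ParamSystem,
                              residue_index: int,
                              eps_in: float | None = None) -> EnergySeries:
    """Residue–ligand interaction energy per frame.

    When ``eps_in`` is None it is taken from the residue's polarity class
    (1 for nonpolar, 3 for polar, 10 for charged). The whole protein can be
    used as the "residue" by passing ``residue_index=None`` (eps_in defaults
    to 1 in that case, the whole-complex convention).
    """
    if traj.n_frames == 0:
        raise EmptyInputError("empty trajectory")
    traj.check_against(system)
    lig = system.ligand_atom_indices
    if residue_index is None:
        group_a = system.protein_atom_indices
        if eps_in is None:
            eps_in = 1.0
    else:
        res = system.residues[residue_index]
        if res.is_ligand:
            raise ValueError("residue must differ from the ligand")
        group_a = system.residue_atom_indices(residue_index)
        if eps_in is None:
            if res.polarity_class is None:
                system.classify_residues()
            eps_in = DIELECTRIC_BY_CLASS[res.polarity_class]
    a, b = _check_groups(group_a, lig)
    e_ele, e_vdw = _frame_energies(
        traj.coords, system.array("charge"), system.array("lj_rmin_half"),
        system.array("lj_epsilon"), a, b, eps_in)
    return EnergySeries(frame_times=traj.times, e_vdw=e_vdw, e_ele=e_ele,
                        group_a=a, group_b=b)
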