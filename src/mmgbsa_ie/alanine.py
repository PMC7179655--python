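"""Single-trajectory computational alanine scanning.

Mutants are generated by sidechain truncation: every atom beyond Cβ is
deleted from each frame of the wild-type trajectory, the γ heavy atom is
retained as a β-hydrogen repositioned to 1.09 Å along the original Cβ→γ
bond, and the residue receives standard alanine parameters with the methyl
charge closed so the mutated residue is net neutral. Per-residue ΔΔG is the
mutant-minus-wild difference of binding free energy; a positive value means
the wild residue stabilises binding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE
from .energetics import EnergySeries, interaction_energy_series
from .entropy import (
    Window,
    WindowPlan,
    aggregate_windows,
    interaction_entropy,
)
from .errors import EmptyInputError, MutationError, TopologyError
from .gb import GBContext, gb_binding_energy
from .params import sasa_radii
from .sasa import delta_np, shrake_rupley_sasa
from .system import ParamSystem, Residue, THREE_TO_ONE, Trajectory

__all__ = ["MutationSpec", "DdGRecord", "BindingSummary", "mutate_to_alanine",
           "ddg_components", "scan_residue", "total_binding_energy",
           "classify_hotspots", "residue_sum_summary", "binding_summary"]

# Standard alanine sidechain charges (e) and LJ types for the methyl group.
ALA_CB_CHARGE = -0.1825
ALA_HB_CHARGE = 0.0603
CT_RMIN_HALF, CT_EPSILON = 1.9080, 0.1094
HC_RMIN_HALF, HC_EPSILON = 1.4870, 0.0157
H_GB_RADIUS, H_GB_SCREEN = 1.2, 0.85
CB_H_BOND_LENGTH = 1.09  # Å

# Greek-letter remoteness ordering of PDB atom names: keep A (α) and B (β),
# truncate Γ and beyond.
_REMOTENESS = {"A": 0, "B": 1, "G": 2, "D": 3, "E": 4, "Z": 5, "H": 6}
_NAME_RE = re.compile(r"^([CNOSH])([ABGDEZH])?\d*$")
_GAMMA_PRIORITY = ["CG", "CG1", "OG", "OG1", "SG", "CG2"]


def _remoteness(name: str) -> int | None:
    m = _NAME_RE.match(name.strip().upper())
    if m is None or m.group(2) is None:
        return None
    return _REMOTENESS[m.group(2)]


def _is_beyond_beta(name: str) -> bool:
    r = _remoteness(name)
    return r is not None and r >= 2


@dataclass
class MutationSpec:
    """One sidechain-truncation mutation (X → Ala)."""

    residue_index: int
    wild_name: str = ""
    rule: str = "truncate-beyond-CB"
    hydrogen_completion: str = "gamma-to-HB1"

    def label_for(self, residue: Residue) -> str:
        one = THREE_TO_ONE.get(residue.name.upper(), residue.name[:1])
        return f"{one}{residue.resseq}A"


@dataclass
class DdGRecord:
    """One alanine-scan row: component ΔΔ terms with window SDs (kcal/mol)."""

    label: str
    dd_e_vdw: float
    dd_e_ele: float
    dd_g_gb: float
    dd_g_np: float
    dd_h: float
    minus_t_dd_s: float
    dd_g: float
    sd_e_vdw: float = 0.0
    sd_e_ele: float = 0.0
    sd_g_gb: float = 0.0
    sd_g_np: float = 0.0
    sd_h: float = 0.0
    sd_t_dd_s: float = 0.0
    sd_g: float = 0.0
    n_windows: int = 1

    def __post_init__(self) -> None:
        # 0.0105 rather than 0.01: values printed at 2 decimals can carry a
        # full 0.01 discrepancy that floating point renders as 0.010000...2
        comp = self.dd_e_vdw + self.dd_e_ele + self.dd_g_gb + self.dd_g_np
        if abs(self.dd_h - comp) > 0.0105:
            raise ValueError("ΔΔH does not equal the sum of its components")
        if abs(self.dd_g - (self.dd_h + self.minus_t_dd_s)) > 0.0105:
            raise ValueError("ΔΔG does not equal ΔΔH + (−TΔΔS)")

    @classmethod
    def from_windows(cls, label: str, per_window: dict[str, np.ndarray]) -> "DdGRecord":
        means, sds = {}, {}
        for key, vals in per_window.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size >= 2:
                means[key], sds[key] = aggregate_windows(vals)
            else:
                means[key], sds[key] = float(vals[0]), 0.0
        return cls(
            label=label,
            dd_e_vdw=means["dd_e_vdw"], dd_e_ele=means["dd_e_ele"],
            dd_g_gb=means["dd_g_gb"], dd_g_np=means["dd_g_np"],
            dd_h=means["dd_h"], minus_t_dd_s=means["minus_t_dd_s"],
            dd_g=means["dd_g"],
            sd_e_vdw=sds["dd_e_vdw"], sd_e_ele=sds["dd_e_ele"],
            sd_g_gb=sds["dd_g_gb"], sd_g_np=sds["dd_g_np"],
            sd_h=sds["dd_h"], sd_t_dd_s=sds["minus_t_dd_s"], sd_g=sds["dd_g"],
            n_windows=len(np.atleast_1d(per_window["dd_g"])),
        )


@dataclass
class BindingSummary:
    """Overall binding free energy (kcal/mol) with window SDs."""

    dh_mean: float
    minus_tds_mean: float
    dg_mean: float
    dh_sd: float = 0.0
    minus_tds_sd: float = 0.0
    dg_sd: float = 0.0
    n_windows: int = 0

    def __post_init__(self) -> None:
        if abs(self.dg_mean - (self.dh_mean + self.minus_tds_mean)) > 0.01:
            raise ValueError("ΔG must equal ΔH + (−TΔS)")


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def mutate_to_alanine(system: ParamSystem, traj: Trajectory,
                      spec: MutationSpec) -> tuple[ParamSystem, Trajectory]:
    """Build the alanine mutant of one residue over every frame.

    Backbone atoms and all other residues are untouched (bit-exact
    coordinates). ALA → ALA is the identity mutation; GLY has no sidechain
    to truncate and raises :class:`MutationError`. PRO is supported as an
    approximation (ring opened at Cβ, backbone N left as-is).
    """
    traj.check_against(system)
    res = system.residues[spec.residue_index]
    if res.is_ligand:
        raise MutationError("cannot mutate the ligand")
    name = res.name.upper()
    if name == "GLY":
        raise MutationError("GLY has no Cβ; alanine mutation unsupported")
    atom_names = {system.atoms[i].name.upper(): i for i in res.atom_indices}
    if "CB" not in atom_names:
        raise TopologyError(f"residue {res.label} has no CB atom")

    if name == "ALA":
        return system.copy(), Trajectory(coords=traj.coords.copy(),
                                         times=traj.times.copy())

    removed = {i for i in res.atom_indices
               if _is_beyond_beta(system.atoms[i].name)}
    gamma_idx = None
    for pname in _GAMMA_PRIORITY:
        if pname in atom_names and atom_names[pname] in removed:
            gamma_idx = atom_names[pname]
            break
    if gamma_idx is None:  # fall back to any removed heavy, then any removed
        heavies = [i for i in sorted(removed) if not system.atoms[i].is_hydrogen]
        gamma_idx = heavies[0] if heavies else (sorted(removed)[0] if removed else None)
    if gamma_idx is None:
        raise TopologyError(f"residue {res.label} has nothing beyond CB")
    removed.discard(gamma_idx)  # the γ atom survives as HB1

    keep = [i for i in range(system.n_atoms) if i not in removed]
    old_to_new = {old: new for new, old in enumerate(keep)}
    cb_idx, gamma_new = atom_names["CB"], old_to_new[gamma_idx]

    mut = system.copy()
    new_atoms = [mut.atoms[i] for i in keep]
    for new, atom in enumerate(new_atoms):
        atom.serial = new
    # rebuild residue ranges
    new_residues = []
    cursor = 0
    for r in mut.residues:
        kept_here = [i for i in r.atom_indices if i not in removed]
        r.atom_start, r.atom_stop = cursor, cursor + len(kept_here)
        cursor += len(kept_here)
        new_residues.append(r)
    mres = new_residues[spec.residue_index]
    mres.name = "ALA"
    mres.polarity_class = "nonpolar"

    # alanine parameters for the methyl group
    hb1 = new_atoms[gamma_new]
    hb1.name, hb1.element = "HB1", "H"
    hb1.lj_rmin_half, hb1.lj_epsilon = HC_RMIN_HALF, HC_EPSILON
    hb1.gb_radius, hb1.gb_screen = H_GB_RADIUS, H_GB_SCREEN
    for i in mres.atom_indices:
        a = new_atoms[i]
        nm = a.name.upper()
        if nm == "CB":
            a.charge = ALA_CB_CHARGE
            a.lj_rmin_half, a.lj_epsilon = CT_RMIN_HALF, CT_EPSILON
        elif nm.startswith("HB") and a is not hb1:
            a.charge = ALA_HB_CHARGE
            a.lj_rmin_half, a.lj_epsilon = HC_RMIN_HALF, HC_EPSILON
    # close the residue's net charge to alanine's formal 0 on HB1
    other = sum(new_atoms[i].charge for i in mres.atom_indices
                if new_atoms[i] is not hb1)
    hb1.charge = -other

    new_bonds = [(old_to_new[i], old_to_new[j]) for i, j in mut.bonds
                 if i not in removed and j not in removed]

    # reposition HB1 along the original Cβ→γ vector at 1.09 Å, every frame
    def reposition(coords_all: np.ndarray) -> np.ndarray:
        out = coords_all[..., keep, :].copy()
        vec = coords_all[..., gamma_idx, :] - coords_all[..., cb_idx, :]
        norm = np.linalg.norm(vec, axis=-1, keepdims=True)
        out[..., gamma_new, :] = (coords_all[..., cb_idx, :]
                                  + CB_H_BOND_LENGTH * vec / norm)
        return out

    mut_system = ParamSystem(
        atoms=new_atoms, residues=new_residues,
        reference_coords=reposition(system.reference_coords),
        bonds=new_bonds,
    )
    mut_traj = Trajectory(coords=reposition(traj.coords), times=traj.times.copy())
    return mut_system, mut_traj


# ---------------------------------------------------------------------------
# ΔΔG assembly
# ---------------------------------------------------------------------------

def ddg_components(wild: EnergySeries, mutant: EnergySeries,
                   T: float = DEFAULT_TEMPERATURE,
                   wild_gb=None, mutant_gb=None,
                   wild_np=None, mutant_np=None,
                   enthalpy_indices=None,
                   k_sd: float | None = 3.0) -> dict[str, float]:
    """Mutant-minus-wild ΔΔ components for one window (kcal/mol).

    Enthalpy terms average over ``enthalpy_indices`` (default: all frames);
    the entropy difference is IE(mutant) − IE(wild), each series filtered at
    ``k_sd`` standard deviations. Solvation arrays are per-enthalpy-frame
    binding values (complex − protein − ligand); missing arrays mean zero
    solvation change.
    """
    if len(wild) != len(mutant):
        raise ValueError("wild and mutant series must be frame-aligned")
    if len(wild) == 0:
        raise EmptyInputError("empty energy series")
    idx = np.arange(len(wild)) if enthalpy_indices is None \
        else np.asarray(enthalpy_indices, dtype=int)

    dd_e_vdw = float(mutant.e_vdw[idx].mean() - wild.e_vdw[idx].mean())
    dd_e_ele = float(mutant.e_ele[idx].mean() - wild.e_ele[idx].mean())

    def solv_diff(w, m):
        if w is None and m is None:
            return 0.0
        w = np.zeros(len(idx)) if w is None else np.asarray(w, dtype=float)
        m = np.zeros(len(idx)) if m is None else np.asarray(m, dtype=float)
        if len(w) != len(m):
            raise ValueError("solvation arrays must be frame-aligned")
        return float(m.mean() - w.mean())

    dd_g_gb = solv_diff(wild_gb, mutant_gb)
    dd_g_np = solv_diff(wild_np, mutant_np)

    ie_wild = interaction_entropy(wild.e_total, T, k_sd=k_sd)
    ie_mut = interaction_entropy(mutant.e_total, T, k_sd=k_sd)
    minus_t_dd_s = ie_mut.minus_t_ds - ie_wild.minus_t_ds

    dd_h = dd_e_vdw + dd_e_ele + dd_g_gb + dd_g_np
    return {
        "dd_e_vdw": dd_e_vdw, "dd_e_ele": dd_e_ele,
        "dd_g_gb": dd_g_gb, "dd_g_np": dd_g_np,
        "dd_h": dd_h, "minus_t_dd_s": minus_t_dd_s,
        "dd_g": dd_h + minus_t_dd_s,
    }


def _enthalpy_indices(n_frames: int, n_wanted: int) -> np.ndarray:
    n = min(n_wanted, n_frames)
    return np.unique(np.round(np.linspace(0, n_frames - 1, n)).astype(int))


def _binding_solvation(system: ParamSystem, coords: np.ndarray,
                       gb_ctx: GBContext, sasa_points: int) -> tuple[float, float]:
    g_gb = gb_binding_energy(coords, system, gb_ctx)
    radii = sasa_radii(system)
    prot, lig = system.protein_atom_indices, system.ligand_atom_indices
    s_c = shrake_rupley_sasa(coords, radii, n_points=sasa_points).total
    s_p = shrake_rupley_sasa(coords[prot], radii[prot], n_points=sasa_points).total
    s_l = shrake_rupley_sasa(coords[lig], radii[lig], n_points=sasa_points).total
    return g_gb, delta_np(s_c, s_p, s_l)


def scan_residue(system: ParamSystem, traj: Trajectory, windows: list[Window],
                 residue_index: int, plan: WindowPlan | None = None,
                 T: float = DEFAULT_TEMPERATURE, k_sd: float = 3.0,
                 sasa_points: int = 240,
                 frame_offsets: dict[int, int] | None = None) -> DdGRecord:
    """Full MM/GBSA+IE alanine scan of one residue over the given windows.

    ``windows`` index into ``traj`` frames (replicates concatenated must be
    resolved by ``frame_offsets``: replicate → first frame in ``traj``;
    default assumes a single replicate starting at frame 0).
    """
    plan = plan or WindowPlan()
    from .constants import DIELECTRIC_BY_CLASS
    from .gb import atom_dielectrics
    res = system.residues[residue_index]
    if res.polarity_class is None:
        system.classify_residues()
    spec = MutationSpec(residue_index=residue_index, wild_name=res.name)
    label = spec.label_for(res)
    mut_system, mut_traj = mutate_to_alanine(system, traj, spec)

    # the mutation x→a keeps the wild residue's class dielectric throughout,
    # so ΔΔ terms compare like with like
    wild_eps = DIELECTRIC_BY_CLASS[res.polarity_class]
    wild_all = interaction_energy_series(traj, system, residue_index,
                                         eps_in=wild_eps)
    mut_all = interaction_energy_series(mut_traj, mut_system, residue_index,
                                        eps_in=wild_eps)

    per_window: dict[str, list[float]] = {k: [] for k in (
        "dd_e_vdw", "dd_e_ele", "dd_g_gb", "dd_g_np", "dd_h",
        "minus_t_dd_s", "dd_g")}
    offsets = frame_offsets or {}
    gb_wild = GBContext(eps_in=atom_dielectrics(system))
    eps_mut = atom_dielectrics(mut_system)
    mres = mut_system.residues[residue_index]
    eps_mut[mres.atom_start:mres.atom_stop] = wild_eps
    gb_mut = GBContext(eps_in=eps_mut)
    for win in windows:
        off = offsets.get(win.replicate, 0)
        lo, hi = off + win.start_frame, off + win.stop_frame
        w = wild_all.slice(slice(lo, hi))
        m = mut_all.slice(slice(lo, hi))
        idx = _enthalpy_indices(len(w), plan.enthalpy_frames_per_window)
        wild_gb = np.empty(len(idx))
        mut_gb = np.empty(len(idx))
        wild_np = np.empty(len(idx))
        mut_np = np.empty(len(idx))
        for k, fi in enumerate(idx):
            wild_gb[k], wild_np[k] = _binding_solvation(
                system, traj.coords[lo + fi], gb_wild, sasa_points)
            mut_gb[k], mut_np[k] = _binding_solvation(
                mut_system, mut_traj.coords[lo + fi], gb_mut, sasa_points)
        comps = ddg_components(w, m, T=T, wild_gb=wild_gb, mutant_gb=mut_gb,
                               wild_np=wild_np, mutant_np=mut_np,
                               enthalpy_indices=idx, k_sd=k_sd)
        for key, val in comps.items():
            per_window[key].append(val)
    return DdGRecord.from_windows(label, {k: np.array(v) for k, v in per_window.items()})


def total_binding_energy(records: list[DdGRecord]) -> float:
    """ΔG_bind = −Σ_x ΔΔG(x→a) over the pocket records (kcal/mol)."""
    if not records:
        raise EmptyInputError("no alanine-scan records")
    return -float(sum(r.dd_g for r in records))


def residue_sum_summary(records: list[DdGRecord]) -> BindingSummary:
    """Table-1-shaped totals from the residue-sum route (negated sums).

    SDs propagate in quadrature across residues.
    """
    if not records:
        raise EmptyInputError("no alanine-scan records")
    dh = -sum(r.dd_h for r in records)
    tds = -sum(r.minus_t_dd_s for r in records)
    return BindingSummary(
        dh_mean=dh, minus_tds_mean=tds, dg_mean=dh + tds,
        dh_sd=float(np.sqrt(sum(r.sd_h**2 for r in records))),
        minus_tds_sd=float(np.sqrt(sum(r.sd_t_dd_s**2 for r in records))),
        dg_sd=float(np.sqrt(sum(r.sd_g**2 for r in records))),
        n_windows=records[0].n_windows,
    )


def binding_summary(system: ParamSystem, traj: Trajectory,
                    windows: list[Window], plan: WindowPlan | None = None,
                    T: float = DEFAULT_TEMPERATURE, k_sd: float = 3.0,
                    sasa_points: int = 240,
                    frame_offsets: dict[int, int] | None = None) -> BindingSummary:
    """Whole-complex binding free energy (protein–ligand route).

    ΔH per window = ⟨E_int(P,L)⟩ + ⟨ΔG_gb⟩ + ⟨ΔG_np⟩ over the enthalpy
    frames (gas-phase dielectric 1 for the whole complex); −TΔS per window
    from the interaction-entropy estimator on every frame in the window.
    """
    plan = plan or WindowPlan()
    from .gb import atom_dielectrics
    ctx = GBContext(eps_in=atom_dielectrics(system))
    series_all = interaction_energy_series(traj, system, None, eps_in=1.0)
    offsets = frame_offsets or {}
    dh_w, tds_w = [], []
    for win in windows:
        off = offsets.get(win.replicate, 0)
        lo, hi = off + win.start_frame, off + win.stop_frame
        s = series_all.slice(slice(lo, hi))
        idx = _enthalpy_indices(len(s), plan.enthalpy_frames_per_window)
        gb_vals = np.empty(len(idx))
        np_vals = np.empty(len(idx))
        for k, fi in enumerate(idx):
            gb_vals[k], np_vals[k] = _binding_solvation(
                system, traj.coords[lo + fi], ctx, sasa_points)
        dh_w.append(float(s.e_total[idx].mean() + gb_vals.mean() + np_vals.mean()))
        tds_w.append(interaction_entropy(s.e_total, T, k_sd=k_sd).minus_t_ds)
    dh, dh_sd = aggregate_windows(dh_w) if len(dh_w) > 1 else (dh_w[0], 0.0)
    tds, tds_sd = aggregate_windows(tds_w) if len(tds_w) > 1 else (tds_w[0], 0.0)
    return BindingSummary(dh_mean=dh, minus_tds_mean=tds, dg_mean=dh + tds,
                          dh_sd=dh_sd, minus_tds_sd=tds_sd,
                          dg_sd=float(np.sqrt(dh_sd**2 + tds_sd**2)),
                          n_windows=len(windows))


def classify_hotspots(records: list[DdGRecord],
                      threshold: float = 1.0) -> list[str]:
    """Residue labels with ΔΔG above ``threshold``, descending by ΔΔG."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hot = [r for r in records if r.dd_g > threshold]
    hot.sort(key=lambda r: -r.dd_g)
    return [r.label[:-1] if r.label.endswith("A") else r.label for r in hot]
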