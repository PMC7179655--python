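"""Sidechain-truncation mutants and ΔΔG assembly."""

import numpy as np
import pytest

import mmgbsa_ie as m
from mmgbsa_ie import reference as ref
from mmgbsa_ie.alanine import (
    DdGRecord,
    MutationSpec,
    mutate_to_alanine,
    scan_residue,
)
from mmgbsa_ie.energetics import EnergySeries
from mmgbsa_ie.errors import EmptyInputError, MutationError
from mmgbsa_ie.system import Atom, ParamSystem, Residue, Trajectory

KT300 = 1.9872041e-3 * 300.0

# full tyrosine: 21 atoms including hydrogens
_TYR_ATOMS = [
    ("N", "N"), ("H", "H"), ("CA", "C"), ("HA", "H"), ("CB", "C"),
    ("HB2", "H"), ("HB3", "H"), ("CG", "C"), ("CD1", "C"), ("HD1", "H"),
    ("CD2", "C"), ("HD2", "H"), ("CE1", "C"), ("HE1", "H"), ("CE2", "C"),
    ("HE2", "H"), ("CZ", "C"), ("OH", "O"), ("HH", "H"), ("C", "C"),
    ("O", "O"),
]


def _make_residue_system(atom_list, resname):
    atoms = [Atom(serial=i, name=n, element=e, residue_index=0, charge=0.0,
                  lj_rmin_half=1.5, lj_epsilon=0.1, gb_radius=1.5,
                  gb_screen=0.8)
             for i, (n, e) in enumerate(atom_list)]
    residues = [Residue(index=0, name=resname, chain="A", resseq=907,
                        atom_start=0, atom_stop=len(atoms))]
    rng = np.random.default_rng(0)
    coords = rng.uniform(-3, 3, (len(atoms), 3))
    # put CB and CG at controlled positions for the repositioning check
    names = [n for n, _ in atom_list]
    if "CB" in names and "CG" in names:
        coords[names.index("CB")] = [0.0, 0.0, 0.0]
        coords[names.index("CG")] = [1.52, 0.0, 0.0]
    system = ParamSystem(atoms=atoms, residues=residues,
                         reference_coords=coords)
    traj = Trajectory.from_coords(np.repeat(coords[None], 3, axis=0))
    return system, traj


class TestMutation:
    def test_identity_alanine(self, toy):
        system, traj = toy
        mut_sys, mut_traj = mutate_to_alanine(system, traj, MutationSpec(0))
        assert mut_sys.n_atoms == system.n_atoms
        assert np.array_equal(mut_traj.coords, traj.coords)

    def test_tyrosine_atom_count(self):
        """TYR (21 atoms with H) truncates to the 10-atom alanine template."""
        system, traj = _make_residue_system(_TYR_ATOMS, "TYR")
        mut_sys, mut_traj = mutate_to_alanine(system, traj, MutationSpec(0))
        assert mut_sys.n_atoms == 10
        names = {a.name for a in mut_sys.atoms}
        assert names == {"N", "H", "CA", "HA", "CB", "HB1", "HB2", "HB3",
                         "C", "O"}
        assert mut_traj.n_frames == traj.n_frames

    def test_hb1_bond_geometry(self):
        """The retained γ carbon becomes HB1 at 1.09 Å along the Cβ→γ bond."""
        system, traj = _make_residue_system(_TYR_ATOMS, "TYR")
        mut_sys, _ = mutate_to_alanine(system, traj, MutationSpec(0))
        names = [a.name for a in mut_sys.atoms]
        cb = mut_sys.reference_coords[names.index("CB")]
        hb1 = mut_sys.reference_coords[names.index("HB1")]
        assert np.linalg.norm(hb1 - cb) == pytest.approx(1.09, abs=1e-10)
        assert hb1[0] == pytest.approx(1.09)  # along original +x bond

    def test_glycine_rejected(self):
        gly = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
        system, traj = _make_residue_system(gly, "GLY")
        with pytest.raises(MutationError):
            mutate_to_alanine(system, traj, MutationSpec(0))

    def test_mutant_residue_neutral(self, toy):
        system, traj = toy
        mut_sys, _ = mutate_to_alanine(system, traj, MutationSpec(2))  # GLU
        res = mut_sys.residues[2]
        q = sum(mut_sys.atoms[i].charge for i in res.atom_indices)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert res.name == "ALA"

    def test_backbone_and_other_residues_bit_exact(self, toy):
        system, traj = toy
        mut_sys, mut_traj = mutate_to_alanine(system, traj, MutationSpec(2))
        wild_names = [(a.name, a.residue_index) for a in system.atoms]
        for new_i, atom in enumerate(mut_sys.atoms):
            if atom.name == "HB1" and atom.residue_index == 2:
                continue
            old_i = wild_names.index((atom.name, atom.residue_index))
            assert np.array_equal(mut_traj.coords[:, new_i],
                                  traj.coords[:, old_i])

    def test_proline_supported(self):
        pro = [("N", "N"), ("CA", "C"), ("HA", "H"), ("CB", "C"),
               ("HB2", "H"), ("HB3", "H"), ("CG", "C"), ("HG2", "H"),
               ("HG3", "H"), ("CD", "C"), ("HD2", "H"), ("HD3", "H"),
               ("C", "C"), ("O", "O")]
        system, traj = _make_residue_system(pro, "PRO")
        mut_sys, _ = mutate_to_alanine(system, traj, MutationSpec(0))
        assert {a.name for a in mut_sys.atoms} == {
            "N", "CA", "HA", "CB", "HB1", "HB2", "HB3", "C", "O"}


class TestDdgComponents:
    @staticmethod
    def _const_series(value, n=100):
        return EnergySeries(frame_times=np.arange(n), e_vdw=np.full(n, value),
                            e_ele=np.zeros(n))

    def test_identical_series_all_zero(self):
        s = self._const_series(-3.0)
        comps = m.ddg_components(s, s)
        assert all(v == 0.0 for v in comps.values())

    def test_constant_shift(self):
        """Wild at −2, mutant at −1: ΔΔH = +1, −TΔΔS = 0, ΔΔG = +1."""
        comps = m.ddg_components(self._const_series(-2.0),
                                 self._const_series(-1.0))
        assert comps["dd_h"] == pytest.approx(1.0)
        assert comps["minus_t_dd_s"] == 0.0
        assert comps["dd_g"] == pytest.approx(1.0)

    def test_gaussian_wild_constant_mutant(self):
        """Fluctuating wild vs still mutant: −TΔΔS = −σ²/(2kT) = −0.839."""
        n = 10**6
        noise = m.gaussian_energy_series(-5.0, 1.0, n, seed=9)
        wild = EnergySeries(frame_times=np.arange(n), e_vdw=noise,
                            e_ele=np.zeros(n))
        mutant = self._const_series(float(noise.mean()), n)
        comps = m.ddg_components(wild, mutant, T=300.0, k_sd=None)
        assert comps["minus_t_dd_s"] == pytest.approx(-1 / (2 * KT300), abs=0.01)
        assert comps["dd_h"] == pytest.approx(0.0, abs=0.01)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            m.ddg_components(self._const_series(-2.0, 50),
                             self._const_series(-1.0, 60))


class TestTotals:
    def test_sign_convention(self):
        recs = [DdGRecord("X1A", 1.0, 0, 0, 0, 1.0, 0.0, 1.0),
                DdGRecord("X2A", 2.0, 0, 0, 0, 2.0, 0.0, 2.0)]
        assert m.total_binding_energy(recs) == pytest.approx(-3.0)

    def test_all_zero(self):
        recs = [DdGRecord("X1A", 0, 0, 0, 0, 0, 0, 0)] * 3
        assert m.total_binding_energy(recs) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            m.total_binding_energy([])

    def test_published_column_sums(self):
        """The per-residue columns sum to the residue-sum totals (−19.73 and
        −17.11), which differ from the whole-complex route as documented."""
        r1 = ref.records(ref.parp1_alanine_scan())
        r2 = ref.records(ref.parp2_alanine_scan())
        assert m.total_binding_energy(r1) == pytest.approx(-19.73, abs=1e-9)
        assert m.total_binding_energy(r2) == pytest.approx(-17.11, abs=1e-9)

    def test_kahan_vs_naive_accumulation(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(-2, 2, 500)
        recs = [DdGRecord(f"X{i}A", v, 0, 0, 0, v, 0.0, v)
                for i, v in enumerate(vals)]
        total = m.total_binding_energy(recs)
        kahan = c = 0.0
        for v in vals:
            y = -v - c
            t = kahan + y
            c = (t - kahan) - y
            kahan = t
        assert total == pytest.approx(kahan, abs=1e-9)


class TestHotspots:
    def test_published_hotspot_sets(self):
        hot1 = m.classify_hotspots(ref.records(ref.parp1_alanine_scan()))
        hot2 = m.classify_hotspots(ref.records(ref.parp2_alanine_scan()))
        assert hot1 == ["Y907", "Y889", "Y896", "H862", "E988"]
        assert hot2 == ["Y473", "Y455", "Y462", "E558", "H428"]

    def test_all_below_threshold(self):
        recs = [DdGRecord("X1A", 0.5, 0, 0, 0, 0.5, 0.0, 0.5)]
        assert m.classify_hotspots(recs) == []


class TestScanResidue:
    def test_identity_mutation_all_zero(self, toy, small_windows):
        system, traj = toy
        windows, plan = small_windows
        rec = scan_residue(system, traj, windows, 0, plan, sasa_points=120)
        for v in (rec.dd_e_vdw, rec.dd_e_ele, rec.dd_g_gb, rec.dd_g_np,
                  rec.dd_h, rec.minus_t_dd_s, rec.dd_g):
            assert v == 0.0

    def test_attractive_residue_positive_ddg(self, toy, small_windows):
        """Deleting the salt-bridging glutamate destabilises binding."""
        system, traj = toy
        windows, plan = small_windows
        rec = scan_residue(system, traj, windows, 2, plan, sasa_points=120)
        assert rec.dd_g > 0.0
        assert rec.label == "E3A"
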