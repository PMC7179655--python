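"""Force-field parameter tables.

The canonical exchange format is a CSV (comma or whitespace separated) with
header ``residue, atom, charge_e, rmin_half_A, epsilon_kcal, gb_radius_A,
gb_screen`` keyed by (residue name, atom name), or by an explicit ``serial``
column. Binary MD-engine topologies are normalised into this table by
external adapters; the core never reads them.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import AmbiguousParameterError, MissingParameterError
from .system import ParamSystem

PARAM_COLUMNS = [
    "residue", "atom", "charge_e", "rmin_half_A", "epsilon_kcal",
    "gb_radius_A", "gb_screen",
]

# Intrinsic Born radii by element (mbondi2-style, Å); hydrogens bonded to
# nitrogen take 1.3 Å, all other hydrogens 1.2 Å.
GB_RADIUS_BY_ELEMENT = {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.5, "F": 1.5,
    "S": 1.8, "P": 1.85, "CL": 1.7, "BR": 1.85, "I": 1.98,
}
GB_RADIUS_H_ON_N = 1.3

# HCT descreening scale factors by element.
GB_SCREEN_BY_ELEMENT = {
    "H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "F": 0.88,
    "S": 0.96, "P": 0.86, "CL": 0.80, "BR": 0.80, "I": 0.80,
}


def read_parameter_table(source) -> pd.DataFrame:
    """Read a parameter table (comma- or whitespace-separated, '#' comments)."""
    df = pd.read_csv(source, sep=None, engine="python", comment="#",
                     skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    return df


def write_parameter_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def attach_parameters(system: ParamSystem, table: pd.DataFrame) -> ParamSystem:
    """Populate every atom's charge/LJ/GB fields from a parameter table.

    Keyed by the ``serial`` column when present, else by (residue, atom).
    Raises :class:`MissingParameterError` naming every unmatched atom and
    :class:`AmbiguousParameterError` on duplicate keys.
    """
    out = system.copy()
    if "serial" in table.columns:
        keys = table["serial"].astype(int).tolist()
        lookup_by_serial = True
    else:
        keys = list(zip(table["residue"].astype(str).str.strip().str.upper(),
                        table["atom"].astype(str).str.strip().str.upper()))
        lookup_by_serial = False
    if len(set(keys)) != len(keys):
        seen, dups = set(), []
        for k in keys:
            if k in seen:
                dups.append(k)
            seen.add(k)
        raise AmbiguousParameterError(f"duplicate parameter keys: {sorted(set(map(str, dups)))}")
    rows = dict(zip(keys, table.to_dict("records")))

    missing = []
    for atom in out.atoms:
        res = out.residues[atom.residue_index]
        key = atom.serial if lookup_by_serial else (res.name.upper(), atom.name.upper())
        row = rows.get(key)
        if row is None:
            missing.append(f"{res.name}{res.resseq}:{atom.name}")
            continue
        atom.charge = float(row["charge_e"])
        atom.lj_rmin_half = float(row["rmin_half_A"])
        atom.lj_epsilon = float(row["epsilon_kcal"])
        atom.gb_radius = float(row.get("gb_radius_A", math.nan))
        atom.gb_screen = float(row.get("gb_screen", math.nan))
    if missing:
        raise MissingParameterError(missing)

    _fill_default_gb(out)
    return out


def _fill_default_gb(system: ParamSystem) -> None:
    """Fill NaN GB radii/screens from the element-based default tables."""
    bonded_to_n = set()
    for i, j in system.bonds:
        ai, aj = system.atoms[i], system.atoms[j]
        if ai.is_hydrogen and aj.element.upper() == "N":
            bonded_to_n.add(i)
        if aj.is_hydrogen and ai.element.upper() == "N":
            bonded_to_n.add(j)
    for atom in system.atoms:
        el = atom.element.upper()
        if math.isnan(atom.gb_radius):
            if atom.is_hydrogen and atom.serial in bonded_to_n:
                atom.gb_radius = GB_RADIUS_H_ON_N
            else:
                atom.gb_radius = GB_RADIUS_BY_ELEMENT.get(el, 1.5)
        if math.isnan(atom.gb_screen):
            atom.gb_screen = GB_SCREEN_BY_ELEMENT.get(el, 0.8)


def parameter_table_from_system(system: ParamSystem) -> pd.DataFrame:
    """Export a system's per-atom parameters as the canonical CSV table."""
    rows = []
    for atom in system.atoms:
        res = system.residues[atom.residue_index]
        rows.append({
            "residue": res.name, "atom": atom.name,
            "charge_e": atom.charge, "rmin_half_A": atom.lj_rmin_half,
            "epsilon_kcal": atom.lj_epsilon, "gb_radius_A": atom.gb_radius,
            "gb_screen": atom.gb_screen, "serial": atom.serial,
        })
    return pd.DataFrame(rows)


def sasa_radii(system: ParamSystem) -> np.ndarray:
    """Radii used for surface area: the LJ rmin_half values (Å)."""
    return system.array("lj_rmin_half")
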