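"""Published reference values for NMS-P118 binding to PARP-1 and PARP-2.

Per-residue computational alanine-scanning results (MM/GBSA + interaction
entropy, mean ± SD over 15 five-ns windows) for the two catalytic-domain
complexes (PDB 5A00 and 4ZZY), the overall binding free energies, the
protein–ligand hydrogen-bond survey, and the experimental selectivity ratio.
These tables serve as validation inputs for table-level operations (hot-spot
thresholding, paired residue comparison); they are data, not outputs of this
package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["parp1_alanine_scan", "parp2_alanine_scan", "RESIDUE_PAIRING",
           "PARP1_BINDING", "PARP2_BINDING", "EXPERIMENTAL",
           "hbond_survey", "N_WINDOWS"]

N_WINDOWS = 15  # windows behind each mean ± SD

_COLUMNS = ["mutation",
            "dd_e_vdw", "sd_e_vdw", "dd_e_ele", "sd_e_ele",
            "dd_g_gb", "sd_g_gb", "dd_g_np", "sd_g_np",
            "dd_h", "sd_h", "minus_t_dd_s", "sd_t_dd_s",
            "dd_g", "sd_g"]

_PARP1_ROWS = [
    ("Y907A", 6.41, 0.15, -0.09, 0.19, -0.25, 0.24, 0.27, 0.04, 6.33, 0.15, -0.73, 0.13, 5.60, 0.26),
    ("Y889A", 4.05, 0.14, 0.09, 0.30, -0.04, 0.26, 0.24, 0.02, 4.35, 0.18, -0.66, 0.23, 3.69, 0.24),
    ("Y896A", 3.33, 0.09, 0.90, 0.05, -0.86, 0.04, 0.13, 0.01, 3.51, 0.09, -0.41, 0.05, 3.10, 0.13),
    ("H862A", 1.53, 0.16, -0.44, 0.12, 0.67, 0.12, 0.06, 0.00, 1.81, 0.16, -0.17, 0.04, 1.64, 0.19),
    ("E988A", 1.04, 0.13, 4.94, 0.11, -4.43, 0.10, 0.09, 0.02, 1.65, 0.14, -0.28, 0.11, 1.37, 0.25),
    ("E763A", 1.20, 0.21, 4.90, 0.28, -4.43, 0.27, 0.16, 0.04, 1.83, 0.25, -0.87, 0.29, 0.96, 0.23),
    ("K903A", 1.38, 0.21, -3.59, 0.23, 3.15, 0.20, 0.07, 0.02, 1.00, 0.17, -0.13, 0.05, 0.87, 0.16),
    ("D766A", 0.19, 0.08, 4.00, 0.21, -3.54, 0.20, 0.01, 0.01, 0.67, 0.10, -0.15, 0.08, 0.52, 0.03),
    ("V762A", 0.56, 0.03, -0.19, 0.02, 0.19, 0.02, 0.03, 0.01, 0.60, 0.03, -0.11, 0.03, 0.49, 0.05),
    ("Q759A", 0.84, 0.05, 0.35, 0.26, -0.41, 0.23, 0.05, 0.02, 0.83, 0.04, -0.39, 0.31, 0.44, 0.30),
    ("F897A", 0.23, 0.01, 0.24, 0.02, -0.18, 0.03, 0.00, 0.00, 0.30, 0.02, -0.02, 0.01, 0.28, 0.02),
    ("S904A", -0.55, 0.29, 1.87, 0.29, -0.58, 0.14, 0.00, 0.00, 0.74, 0.13, -0.46, 0.14, 0.28, 0.21),
    ("W861A", 0.06, 0.00, -0.01, 0.02, 0.12, 0.01, 0.00, 0.00, 0.17, 0.01, 0.00, 0.00, 0.17, 0.01),
    ("T887A", 0.16, 0.06, 0.12, 0.15, -0.09, 0.13, 0.01, 0.00, 0.20, 0.09, -0.03, 0.04, 0.17, 0.10),
    ("Y989A", 0.07, 0.01, -0.02, 0.01, 0.05, 0.01, 0.00, 0.00, 0.10, 0.01, 0.00, 0.00, 0.10, 0.01),
    ("P885A", 0.04, 0.02, 0.09, 0.02, -0.08, 0.02, 0.00, 0.00, 0.05, 0.02, -0.01, 0.01, 0.04, 0.02),
    ("N987A", 0.01, 0.00, 0.02, 0.02, -0.02, 0.02, 0.00, 0.00, 0.01, 0.00, 0.00, 0.00, 0.01, 0.00),
    ("S864A", 0.03, 0.01, -0.05, 0.12, 0.03, 0.12, 0.00, 0.00, 0.02, 0.01, -0.02, 0.02, 0.00, 0.02),
]

_PARP2_ROWS = [
    ("Y473A", 6.34, 0.13, 0.18, 0.10, -0.55, 0.11, 0.34, 0.01, 6.31, 0.12, -0.91, 0.08, 5.40, 0.16),
    ("Y455A", 3.35, 0.70, 0.32, 0.25, -0.18, 0.24, 0.19, 0.08, 3.67, 0.76, -0.53, 0.19, 3.14, 0.58),
    ("Y462A", 3.40, 0.39, 0.92, 0.08, -0.94, 0.07, 0.16, 0.05, 3.54, 0.40, -0.43, 0.09, 3.11, 0.42),
    ("E558A", 1.08, 0.08, 4.99, 0.11, -4.46, 0.11, 0.11, 0.02, 1.71, 0.09, -0.27, 0.07, 1.44, 0.14),
    ("H428A", 1.32, 0.21, -0.10, 0.31, 0.29, 0.31, 0.06, 0.01, 1.57, 0.25, -0.18, 0.05, 1.39, 0.28),
    ("K469A", 1.10, 0.08, -3.41, 0.07, 3.00, 0.07, 0.09, 0.01, 0.77, 0.08, -0.07, 0.02, 0.69, 0.08),
    ("I331A", 0.81, 0.08, -0.31, 0.12, 0.31, 0.04, 0.08, 0.05, 0.88, 0.12, -0.38, 0.07, 0.51, 0.17),
    ("L327A", 0.41, 0.30, -0.02, 0.07, 0.06, 0.07, 0.04, 0.03, 0.49, 0.31, -0.06, 0.05, 0.43, 0.29),
    ("P451A", 0.24, 0.15, 0.03, 0.02, -0.01, 0.03, 0.02, 0.02, 0.28, 0.17, -0.04, 0.03, 0.24, 0.15),
    ("F463A", 0.22, 0.02, 0.25, 0.03, -0.22, 0.04, 0.00, 0.00, 0.25, 0.04, -0.03, 0.01, 0.23, 0.05),
    ("W427A", 0.06, 0.00, -0.01, 0.02, 0.12, 0.02, 0.00, 0.00, 0.17, 0.01, 0.00, 0.00, 0.17, 0.01),
    ("S470A", -0.60, 0.26, 1.83, 0.29, -0.61, 0.11, 0.00, 0.00, 0.63, 0.10, -0.47, 0.08, 0.16, 0.14),
    ("S328A", 0.38, 0.15, 0.65, 0.50, -0.73, 0.51, 0.05, 0.04, 0.35, 0.16, -0.26, 0.29, 0.09, 0.17),
    ("Y559A", 0.06, 0.01, -0.03, 0.01, 0.06, 0.01, 0.00, 0.00, 0.09, 0.01, 0.00, 0.00, 0.09, 0.01),
    ("N557A", 0.01, 0.00, 0.04, 0.01, -0.04, 0.01, 0.00, 0.00, 0.01, 0.00, 0.00, 0.00, 0.01, 0.00),
    ("Q332A", 0.69, 0.56, -0.39, 1.11, 0.26, 1.15, 0.07, 0.08, 0.64, 0.57, -0.63, 0.73, 0.01, 0.29),
    ("S430A", 0.03, 0.01, -0.02, 0.07, 0.01, 0.07, 0.00, 0.00, 0.02, 0.01, -0.02, 0.00, 0.00, 0.01),
]


def parp1_alanine_scan() -> pd.DataFrame:
    """Published per-residue alanine-scan table for the PARP-1 complex."""
    return pd.DataFrame(_PARP1_ROWS, columns=_COLUMNS)


def parp2_alanine_scan() -> pd.DataFrame:
    """Published per-residue alanine-scan table for the PARP-2 complex."""
    return pd.DataFrame(_PARP2_ROWS, columns=_COLUMNS)


# Structurally corresponding pocket residues, PARP-1 label → PARP-2 label.
RESIDUE_PAIRING = {
    "Y907": "Y473", "Y889": "Y455", "Y896": "Y462", "H862": "H428",
    "E988": "E558", "E763": "Q332", "K903": "K469", "V762": "I331",
    "Q759": "S328", "F897": "F463", "W861": "W427", "S904": "S470",
    "Y989": "Y559", "P885": "P451", "N987": "N557", "S864": "S430",
}

# Overall binding free energies (kcal/mol, mean ± SD over 15 windows).
PARP1_BINDING = {"dh": -24.31, "dh_sd": 0.43, "minus_tds": 5.11,
                 "minus_tds_sd": 0.53, "dg": -19.20, "dg_sd": 0.48}
PARP2_BINDING = {"dh": -22.29, "dh_sd": 0.43, "minus_tds": 6.13,
                 "minus_tds_sd": 0.83, "dg": -16.16, "dg_sd": 0.85}

# Experimental dissociation-constant selectivity and derived free energies.
EXPERIMENTAL = {"kd_ratio": 154.0, "dg_parp1": -10.90, "dg_parp2": -7.90}

_HBOND_ROWS = [
    ("PARP-1", "O28", "H862:CA-HA", 3.50, 144.92, 54.31),
    ("PARP-1", "F27", "Q759:CB-HB3", 3.08, 126.79, 77.93),
    ("PARP-1", "F26", "Q759:CA-HA", 3.68, 134.10, 27.08),
    ("PARP-2", "O28", "H428:CA-HA", 3.55, 147.82, 44.14),
    ("PARP-2", "F27", "S328:CB-HB2", 4.77, 104.31, 10.53),
    ("PARP-2", "F27", "S328:CA-HA", 3.91, 123.98, 25.61),
]


def records(table: pd.DataFrame) -> list:
    """Published scan rows as DdGRecord objects (for table-level analyses)."""
    from .alanine import DdGRecord

    out = []
    for _, row in table.iterrows():
        out.append(DdGRecord(
            label=row["mutation"],
            dd_e_vdw=row["dd_e_vdw"], dd_e_ele=row["dd_e_ele"],
            dd_g_gb=row["dd_g_gb"], dd_g_np=row["dd_g_np"],
            dd_h=row["dd_h"], minus_t_dd_s=row["minus_t_dd_s"],
            dd_g=row["dd_g"],
            sd_e_vdw=row["sd_e_vdw"], sd_e_ele=row["sd_e_ele"],
            sd_g_gb=row["sd_g_gb"], sd_g_np=row["sd_g_np"],
            sd_h=row["sd_h"], sd_t_dd_s=row["sd_t_dd_s"], sd_g=row["sd_g"],
            n_windows=N_WINDOWS,
        ))
    return out


def hbond_survey() -> pd.DataFrame:
    """Published ligand–protein hydrogen-bond occupancy survey."""
    return pd.DataFrame(
        _HBOND_ROWS,
        columns=["system", "acceptor", "donor", "mean_distance_A",
                 "mean_angle_deg", "occupancy_pct"])
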