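"""Physical constants and model defaults.

All energies are in kcal/mol, lengths in Å, times in ps, charges in units of
the elementary charge e, temperatures in K.
"""

# Coulomb constant in kcal·Å/(mol·e²) (AMBER convention).
COULOMB_CONSTANT = 332.0636

# Boltzmann constant in kcal/(mol·K).
BOLTZMANN_KCAL = 1.9872041e-3

# Simulation temperature the analysis defaults to.
DEFAULT_TEMPERATURE = 300.0

# Exterior (solvent) dielectric for the generalized-Born model.
EPS_SOLVENT = 80.0

# OBC-II ("igb = 2") generalized-Born shape constants and radius offset (Å).
OBC_ALPHA = 1.0
OBC_BETA = 0.8
OBC_GAMMA = 4.85
GB_OFFSET = 0.09

# Empirical nonpolar solvation: dG_np = GAMMA_NP * SASA + BETA_NP.
GAMMA_NP = 0.00542  # kcal/(mol·Å²)
BETA_NP = 0.92      # kcal/mol

# Interior dielectric assigned per residue polarity class.
DIELECTRIC_BY_CLASS = {"nonpolar": 1.0, "polar": 3.0, "charged": 10.0}

# Default water-probe radius for solvent-accessible surface area (Å).
PROBE_RADIUS = 1.4

# Geometric hydrogen-bond criteria: donor-heavy–acceptor distance (Å) and
# donor–H–acceptor angle (degrees). Both cutoffs are inclusive.
HBOND_DISTANCE_CUTOFF = 3.5
HBOND_ANGLE_CUTOFF = 120.0

# Per-residue free-energy contribution above which a pocket residue is called
# a hot spot (kcal/mol).
HOTSPOT_THRESHOLD = 1.0

# Standard atomic masses (amu) for mass-weighted centroids.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845,
}
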