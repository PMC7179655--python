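# Methods

## Scope and model

The package performs end-state binding free-energy analysis on existing MD
trajectories; it does not run dynamics. The object of study is the
per-residue decomposition of a protein–ligand binding free energy by
single-trajectory computational alanine scanning: the mutant trajectory is
the wild-type trajectory with one sidechain truncated beyond Cβ, so wild and
mutant are frame-aligned by construction and every ΔΔ quantity is a paired
difference on identical geometries. The approximation inherent in the
single-trajectory route — no sidechain repacking or backbone relaxation in
the mutant — is accepted deliberately: it cancels most sampling noise and is
what makes per-residue differences of a few tenths of kcal/mol resolvable.

Energy model, per frame:

- **Gas phase.** Pairwise Coulomb (k_e = 332.0636 kcal·Å/(mol·e²)) and 12-6
  Lennard-Jones with Lorentz–Berthelot combination, no distance cutoff.
  Residue–ligand pairs are never bonded, so 1–4/bonded exclusions cannot
  arise; this is asserted, not special-cased.
- **Polar solvation.** Generalized Born in the OBC "igb = 2"
  parameterization: effective radii from the pairwise HCT descreening
  integral (closed form derived by shell integration; the buried-neighbour
  case adds the full-shell term) rescaled through
  tanh(αΨ − βΨ² + γΨ³) with α = 1.0, β = 0.8, γ = 4.85 and radius offset
  0.09 Å; pair energy through the canonical f_GB interpolation including
  Born self terms. Solvent dielectric 80, zero salt.
- **Nonpolar solvation.** ΔG_np = γ·SASA + β with γ = 0.00542
  kcal/(mol·Å²), β = 0.92 kcal/mol. SASA by Shrake–Rupley sampling on a
  deterministic Fibonacci-spiral point set (default 960 points/atom; the
  isolated-sphere quadrature error is ≈0.1% at that density). SASA radii
  default to the LJ rmin_half values; probe 1.4 Å. β cancels in ΔΔ
  differences but is kept in every absolute ΔG_np so the nonpolar column of
  a scan table remains a pure difference of reported quantities.
- **Entropy.** Interaction entropy: −TΔS = kT·ln⟨exp(βΔE_int)⟩ over the
  window's frames, computed with a log-sum-exp guard; k_B = 1.9872041×10⁻³
  kcal/(mol·K), default T = 300 K. The estimator is translation-invariant,
  non-negative (Jensen), and monotone in fluctuation width — all are tested
  properties.

## Residue-class dielectrics

Interior dielectrics are assigned per residue polarity class: charged
(ASP, GLU, LYS, ARG, HIP) ε = 10; polar (SER, THR, ASN, GLN, HIS/HIE/HID,
TYR, TRP, CYS and protonation variants) ε = 3; nonpolar (ALA, VAL, LEU,
ILE, PRO, PHE, MET, GLY) ε = 1. TYR/TRP sit in the polar class by standard
sidechain chemistry; the table is a module constant and deliberately easy
to override. The class dielectric of the *wild* residue is used for both
wild and mutant series of a mutation, so the ΔΔ difference compares like
with like. By default the dielectric divides both the gas-phase Coulomb
term and the GB interaction of that residue (one switch governs both
placements); mixed-dielectric GB pairs use the geometric mean
ε_ij = √(ε_i ε_j), which is symmetric and reduces to the pure case. The
ligand is classed by its net formal charge (charged when the summed partial
charges round to a nonzero integer). Whole-complex energetics (the
Table-1-shaped route) use ε = 1 for the gas-phase Coulomb term, the usual
end-state convention.

## Mutation rule

Atoms whose PDB remoteness letter is γ or beyond (G/D/E/Z/H) are deleted;
Cβ becomes an alanine methyl carbon; the γ heavy atom (CG/CG1/OG/OG1/SG
priority) is renamed HB1 and repositioned to 1.09 Å along the original
Cβ→γ vector in every frame. CB and the surviving β-hydrogens take standard
alanine charges (−0.1825 / +0.0603 e) and CT/HC Lennard-Jones types; HB1
absorbs the residual charge so the mutant residue is exactly neutral —
required for the class-dielectric assignment of the mutant to be
meaningful. GLY cannot be scanned (no Cβ); ALA→ALA is the identity and
yields bit-exact zero ΔΔG; PRO is supported as an approximation (ring
opened at Cβ, backbone N left untouched) and flagged as such.

## Protocol defaults

| parameter | default | meaning |
|---|---|---|
| window length | 5000 ps | averaging window (5 ns) |
| windows/replicate | 5 | non-overlapping, stability-selected |
| replicates | 3 | independent trajectories |
| enthalpy frames | 100/window | equally spaced |
| entropy frames | all (5000)/window | full 1-ps sampling |
| outlier filter | 3 SD, single pass | mean/SD of the unfiltered series |
| pocket cutoff | 5.0 Å | heavy-atom distance, crystal frame |
| hot-spot threshold | 1.0 kcal/mol | ΔΔG above ⇒ hot spot |
| temperature | 300 K | matches the simulations analysed |

Window selection minimises the within-window standard deviation of the
ligand heavy-atom RMSD to the crystal frame (greedy, earliest-start
tie-break, prefix-sum rolling variance so 10⁵-frame replicates plan in
milliseconds). When a replicate has no slack the greedy picker can fail to
place all windows; it then falls back to the best equally phased
partition. Explicit window lists override selection. The outlier filter is
deliberately not iterated: iterating changes the estimator.

Reported SDs are sample SDs (n−1) across windows. The package computes the
overall binding free energy by two routes that need not agree: the
residue-sum (negated sum of pocket ΔΔG values) and the whole-complex
protein–ligand route; published tables of this kind show the same
discrepancy between their per-residue sums and their totals, and both
numbers are emitted side by side.

## Statistical comparisons

Paired residue differences between two scans propagate SDs in quadrature
and use Welch's unequal-variance t-test on the window-level summary
statistics (mean, SD, n windows per side), flagging p < 0.01. Welch on
summary statistics is a documented choice, not a claim that any particular
published analysis used exactly this variant.

## Synthetic data

The generators exist so every estimator can be validated against planted
ground truth without downloads:

- `make_toy_complex` — 3–10-atom caricature residues (ALA/SER/GLU
  templates) on a ring around a 5-atom charged ligand, each sidechain tip
  placed at a fixed 4.5 Å from the ligand centre; frames are the reference
  geometry plus seeded Gaussian jitter. Planted per-residue strengths scale
  sidechain charges so the true attraction ranking is known.
- `gaussian_energy_series` — i.i.d. normal interaction energies, for the
  σ²/(2kT) closed form of the entropy estimator.
- `planted_hbond_trajectory` — a donor–H–acceptor triad toggling between
  bonded (3.0 Å/165°) and broken (4.5 Å/100°) geometry with per-frame
  Bernoulli occupancy.

All generators are pure functions of (spec, seed) via independent
`numpy.random.default_rng` streams; identical inputs give bit-identical
outputs. What the toys do **not** emulate: conformational relaxation,
correlated fluctuations, water structure, or real force-field charge
distributions — passing tests demonstrate estimator correctness, not
biological fidelity. Test problem sizes (60-frame trajectories, two 30-frame
windows, 120-point SASA spheres) are chosen so the full suite validates the
complete pipeline in well under a minute of numerics; the defaults used for
real data are the protocol values above.

## Numerical choices

- Hydrogen bonds: donor-heavy-atom→acceptor distance ≤ 3.5 Å AND
  donor–H–acceptor angle ≥ 120°, both inclusive; carbon donors allowed.
  Mean distance/angle are averaged over *all* frames, so a bond at partial
  occupancy can report a mean distance beyond the cutoff — matching how
  occupancy surveys are usually tabulated.
- B-factors: (8π²/3)·⟨Δr²⟩ after optional Kabsch alignment to the mean
  structure (two passes: align to frame 0, then to the mean).
- RMSD superposition via SVD (scipy Rotation.align_vectors); fewer than
  three atoms with superposition requested is an error.
- Energies on coincident atoms (r < 10⁻⁶ Å) raise a singularity error
  rather than returning infinities; non-finite descreening integrals do the
  same.
- The interaction-entropy logsumexp path equals naive exponentiation to
  10⁻¹⁰ whenever the naive path is finite; a tiny negative result from
  rounding is clamped to zero.
- Internal units: Å, ps, kcal/mol, e; atom/residue indices 0-based
  internally, 1-based (PDB numbering) in all reports.

## Known limitations

- No Poisson–Boltzmann or surface-based GB (igb = 8) alternatives; no salt
  screening.
- No normal-mode or quasi-harmonic entropy; the interaction-entropy
  estimator converges slowly when βσ is large (heavy-tailed exponential
  average), which is exactly why the window/filter protocol exists.
- Single-trajectory scanning cannot capture mutation-induced
  reorganisation; non-alanine mutations are out of scope.
- The PDB reader keeps the highest-occupancy altloc and drops waters; it
  does not model insertion-code ordering subtleties beyond Bio.PDB's.
- Analysis assumes whole, imaged molecules (no periodic re-imaging).
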