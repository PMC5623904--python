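# Methods

This note documents the models implemented in `npmhub`, the assumptions
behind the synthetic-data generators, and the numerical choices that a user
extending or auditing the package needs to know. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## NoLS scanning (`seqscan`)

Nucleolar localization signals are short lysine/arginine-rich stretches in
disordered regions, usually arranged in variably spaced clusters. Published
NoLS predictors are neural networks whose weights are not reproducible from
the literature; this package instead uses a declared charge-count surrogate:
the sequence is scanned in 13-residue windows with step 1, and each window
scores `min(1, n_basic / s_max)` with `s_max = 6` — the basic count of the
experimentally confirmed Fbw7γ-derived epitope, so that epitope saturates
the score. Windows above the 0.8 threshold (strictly greater, per-window)
merge by coordinate union into putative NoLS segments. Histidine is not
counted as basic by default (pKa near neutrality) but the basic set is
configurable. Peptides shorter than the window are scored as one truncated
window and flagged. The surrogate reproduces presence/absence calls on the
peptides studied here (the Fbw7γ, CENP-W and Tat epitopes score ≥ 0.8; the
unrelated control peptides score ≤ 1/3); it does not reproduce any
predictor's numeric score profile, and coordinates are 1-based inclusive.

## Equilibrium binding (`binding`)

For a dansylated peptide at fixed total concentration *n* (5 μM throughout)
titrated with protein at total concentration *a*, 1:1 mass action gives the
complex concentration as the smaller root of x² − (n+a+K_D)x + na = 0. The
observed fluorescence is

    F(a) = C + k·a + B · bound(a; n, K_D) / n           (quadratic model)
    F(a) = C + k·a + B · a / (K_D + a)                  (hyperbolic model)

with B the saturation amplitude, C the zero-protein signal and k a linear
drift describing the slope at high protein concentration. The hyperbola is
the pseudo-first-order limit n/K_D → 0; the implementation asserts the
sup-norm difference is below 10⁻³·B at n/K_D = 10⁻³.

Fitting is Levenberg–Marquardt least squares over (log K_D, B, C, k), with
an analytic Jacobian; log-parameterisation keeps K_D positive. The optional
stoichiometry multiplier *m* rescales the varied-species concentration
(a_eff = m·a) and is also log-parameterised. Initialisation: K_D at the
concentration of half the observed rise, B at the observed span, C at
F(a_min), k at the terminal slope; on failure or a plainly poor fit, a
multistart over 5 log-spaced K_D values is taken. Replicates are fitted
independently and summarised as mean ± s.d. of K_D (sample s.d., ddof = 1),
matching how triplicate titrations are conventionally reported; pooled
global fitting is deliberately out of scope. A curve with no measurable
fluorescence change, or a fitted amplitude indistinguishable from zero, is
reported as "no interaction" rather than as an error. Least-squares fitting
of this model family is invariant to affine rescaling of the fluorescence
axis, which the tests verify.

Fold changes are reported both as the raw K_D ratio and rounded to one
significant figure, the resolution at which mutant panels are usually
discussed.

### Statistical behaviour of triplicate recovery

With 2% multiplicative noise and 3 replicates, the check "mean recovered
K_D within 3 recovered s.d. of truth" is a |t₂| ≤ 3√3 test: even for an
ideal unbiased estimator it fails ≈ 3.5% of repetitions, so observed
per-preset coverages over 100 seeded repetitions scatter in the low-to-mid
90s by construction. The acceptance suite runs this check verbatim for
every mutant preset; individual presets landing at 92–94 of 100 reflect the
sampling distribution of the check itself, not a fitting defect (noise-free
curves are recovered to machine precision).

## Coarse-grained structure model (`structmodel`)

Structures reduce to two beads per residue: a backbone bead at the Cα
(radius 2.0 Å) and a sidechain bead at the sidechain heavy-atom centroid
(per-residue radius table; glycine's sidechain bead co-locates with its
Cα). Formal charges: K/R +1, D/E −1 on the sidechain bead, all else 0.
This preserves exactly the feature the analyses depend on — the spatial
charge topology — and nothing else.

The electrostatic potential is screened Coulomb with a distance-dependent
dielectric, φ(p) = Σᵢ 332·qᵢ/(4rᵢ·rᵢ) kcal/mol per unit probe charge, with
a 40 Å cutoff; the ε(r) = 4r form mirrors the distance-dependent dielectric
customary in force-field minimisations. It is a qualitative surrogate for a
Poisson–Boltzmann solution: adequate for locating the dominant negative
patch and ranking charge complementarity, not for absolute energetics.
Probes closer to a bead than its radius plus a 1.4 Å solvent probe are
excluded. The acidic patch is the single-linkage cluster (3 Å) of the
lowest-potential probe quantile, reported with all charged residues within
6 Å.

Cavity detection is grid-based (1 Å): a free grid point is buried when
receptor beads occlude it in at least 11 of 14 scan directions (6 axes + 8
cube diagonals); buried points are connected-component labelled and the
largest component is the cavity (volume = voxel count × spacing³).
Thresholds below 11 misclassify points hovering over flat surfaces (a flat
slab blocks 9 of 14 directions from just above it); 11 cleanly separates
enclosed pores, which block 12, from open dishes. Components smaller than
12 Å³ (roughly one solvent probe) are voxel-scale dimples between bead
blobs and are discarded. The grid is anchored to the bead bounding box, so
detection is rigid-motion invariant up to half-voxel registration of the
centroid.

## Hierarchical peptide docking (`docking`)

The peptide is a chain of Cα beads with a fixed 3.8 Å virtual bond and one
sidechain bead per residue (2.5 Å offset). Degrees of freedom are rigid
body (3+3) plus one virtual torsion per Cα–Cα axis. The reference
conformation is a planar zigzag with a 150° virtual bond angle: a
non-straight backbone is essential, since with collinear axes the torsions
could only spin sidechains, never bend the chain. Backbone connectivity is
preserved exactly by construction under any torsion values.

The score is a declared coarse-grained energy,

    E = Σ 332·qᵢqⱼ/(4r·r)  (r < 40 Å)  +  Σ ε_rep·(σᵢⱼ/r)⁸,

with σᵢⱼ the sum of bead radii, ε_rep = 1 kcal/mol, pair distances floored
at 0.5 Å, and per-pair repulsion capped at 10³ kcal/mol (coincident beads
are flagged). No attempt is made to emulate any proprietary docking score:
the recognition being modelled is electrostatics-driven, and the score
states that assumption explicitly. Energies are comparable within a system,
not across force fields.

Search is simulated annealing over the DOF vector with a geometric
temperature schedule (5 → 0.05 kcal/mol over 300 steps for free docking,
150 for template-biased runs, which start already placed). Proposals mix
translations (scale widened with temperature), rotations, single-torsion
moves, and jump moves concentrated in the hot phase (15% of proposals,
decaying to 3%): re-placement near the search centre, insertion-oriented
placement along the cavity's principal axis (obtained by PCA of the cavity
grid points — a generic geometric hint, not a planted answer), and radial
retreat hops that let sterically trapped poses escape to bulk. At least one
bead must remain inside the 20 Å search sphere. Every stage is exactly
reproducible from (config, seed); per-run streams derive from a
SeedSequence keyed by stage name, fragment index and run index.

The protocol: (1) all tripeptides are docked with 10 independent runs each
and the per-run best poses are clustered greedily in energy order at 1.2 Å
receptor-frame RMSD (no re-superposition; ties break on provenance id);
(2) each hexamer window is docked biased toward templates formed by merging
representatives of its two constituent tripeptides (pairs taken in combined
energy order, capped at 25 per window); (3) the whole peptide is docked
biased toward the 100 top-scoring hexamer poses, each anchoring its own
window; (4) the top pose is locally minimised. The harmonic bias
(5 kcal/mol/Å² by default) acts only during the search; reported energies
are always bias-free.

Template-biased runs are initialised at the template by an exact fit: the
rigid part is read off the torsion-independent beads of the first mapped
residue pair, then each torsion is solved in closed form from its immediate
dependents (the next Cα and sidechain bead). A realizable template is
recovered to machine precision; merged two-fragment templates (whose
junction is generally not realizable) get a best-effort fit that the biased
search reconciles. Consequently the zero-bias limit of a template run is
not sample-for-sample identical to unbiased docking — it differs in its
initial condition — which we consider the right trade-off: it is what makes
stiff-bias template reproduction exact and the hierarchy efficient.

Minimisation runs steepest descent with backtracking line search to an RMS
gradient of 0.005, then conjugate gradients to a maximum gradient component
of 0.0004 (score units per DOF unit), with an iteration cap and plateau
detection; the energy trace over accepted steps is non-increasing. On the
rugged capped-repulsion landscape of a full docking pose the strict CG
threshold is often unreachable; the result is then flagged unconverged and
still valid as a local refinement.

Salt bridges are acidic-receptor/basic-peptide sidechain bead pairs within
4 Å, reported with source residue numbering (peptide residues in
parent-protein numbering, e.g. R47 for the first arginine of the Fbw7γ
peptide 44–56).

## Trajectory analytics (`trajanalysis`)

Kabsch superposition via SVD with the proper-rotation determinant
correction; fewer than 3 points or collinear references are rejected. RMSD
time series superpose each frame on the reference using a fit selection
(receptor Cα by default, isolating peptide motion) and measure over a
second selection. The per-residue profile is the RMS over frames of each
Cα's displacement from its reference position; with that convention the
residue-averaged profile and the time-averaged trajectory RMSD agree
exactly in quadrature (mean over residues of profile² equals mean over
frames of RMSD²), which the tests assert. A burn-in flag is available; the
default averages the full trajectory.

## Synthetic data (`synthetic_data`)

No raw experimental data are deposited for this system, so all inputs are
generated under declared models.

**Titrations.** Presets carry the published dissociation constants for
every measured complex (wild type and the alanine-mutant panel against the
Fbw7γ, CENP-W and Tat peptides). Only K_D values are published, so the
fluorescence constants are package defaults — B = 1, C = 0, k = 0.001 μM⁻¹
— chosen once so the linear drift is visible but small, as in typical
dansyl titrations; they are declared, not inferred. Noise is multiplicative
Gaussian (default CV 2%), since fluorescence error scales with signal;
noise_cv = 0 reproduces the model exactly. Defaults mirror the experimental
design: 5 μM peptide, triplicates, protein from 0 to 200–400 μM.

**Toy receptor.** A crown-shaped, exactly n-fold symmetric (default
5-fold) bead assembly: acidic (−1) beads stack along a central pore of
radius 4.25 Å (three per monomer, 3.6 Å z-spacing, alternate levels
staggered by half the azimuthal spacing so no off-axis inter-bead
potential pocket outcompetes the pore axis), inside a neutral cylindrical
body (radius 9 Å) that closes the lateral and diagonal scan directions so
the pore registers as a cavity. Total charge is −n_fold × acidic beads per
monomer. The pore centre is recorded as the planted optimum, and the
construction guarantees — verified by brute-force grid evaluation in the
tests — that the screened-Coulomb potential minimum lies on the pore axis.
Bead overlap (pairwise distance below the radius sum) is rejected. What
this toy shares with a real pentamer is exactly what the protocol needs:
a symmetric acidic funnel feeding a central cavity. What it lacks —
sidechain rotamers, dielectric heterogeneity, shape complexity — means
docking success here demonstrates protocol correctness, not predictive
accuracy on real structures.

**Trajectories.** Each peptide bead follows a discrete Ornstein–Uhlenbeck
process about its start coordinate, with stationary per-coordinate s.d.
sigma_anchor for anchored residues (default residues 1–6, emulating a
peptide held by its N-terminal half) and sigma_free otherwise; the step
noise is scaled so the requested stationary s.d. is exact for the chosen
mean-reversion rate. Frame 0 equals the start pose exactly; receptor beads
ride along as a static frame for fit selections. Time units are nominal;
no force field is implied. The OU stationary relation (free-bead RMSD →
σ√3) is used as a quantitative cross-check of the analytics.

## Pipeline (`pipeline`, CLI `npmhub`)

A flat YAML config drives `scan → fit → dock → traj`. Stage seeds derive
from the global seed XOR a CRC32 hash of the stage name, so any stage can
be re-run in isolation with its exact stream. Outputs are fixed-name CSVs
plus a manifest (config hash, seed, stage seeds, package version); summary
tables are byte-identical across reruns of the same config and seed. A
stage failure yields a partial bundle with the error recorded and a nonzero
exit from the CLI, after config validation has passed up front (a dock
stage without a receptor fails validation before anything runs).

## Problem sizes

Defaults are desk-scale by design: 10 annealing runs per tripeptide at 300
steps, 25 template pairs per hexamer window, 100 full-peptide templates —
one full hierarchy on the toy receptor takes seconds-to-tens-of-seconds on
one core. The statistical suites use 100 seeded repetitions (titration
recovery) and 20 seeded protocol runs (docking).

## Known limitations

* The charge-score NoLS scan has no learned specificity: any K/R-rich
  window scores high, including non-NoLS basic stretches.
* The binding model is strictly 1:1 per monomer with a linear drift; no
  cooperativity, no multi-site binding, no spectral modelling, and no
  explicit ionic-strength term (salt series are just separate datasets).
* The docking score has no desolvation, hydrogen bonding or torsional
  strain; pose ranks are meaningful only within the declared energy model,
  and receptor flexibility is absent.
* Cavity volumes depend on the declared burial rule and bead radii; they
  are not comparable to volumes from other cavity detectors.
* Trajectory generation is a fluctuation model for validating analytics,
  not dynamics; conclusions about real complexes require real simulations.
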