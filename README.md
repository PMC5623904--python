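# npmhub

Computational toolkit for studying how the pentameric N-terminal domain of
nucleophosmin (Nter-NPM1) recognizes the short, basic nucleolar localization
signals (NoLS) of its partner proteins — the Fbw7γ tumor suppressor, HIV-1
Tat and CENP-W among them. NPM1 acts as a "nucleolar hub": a single large
negatively charged surface, running from the pentamer's outer face into its
central cavity, binds many different arginine/lysine-rich peptides with
micromolar affinity and no single hot-spot residue.

The package is aimed at structural bioinformaticians and biophysicists who
want to reproduce or extend this style of analysis end to end with desk-scale
compute. It provides:

* **`seqscan`** — sliding-window NoLS detection. Each 13-residue window gets
  the transparent charge score `min(1, n_basic / 6)` (K/R counted, threshold
  0.8), plus basic-residue cluster analysis.
* **`binding`** — equilibrium fluorescence-titration models and fitting. With
  peptide at fixed total concentration *n* and protein varied ([A]₀), the
  observed signal follows the standard quadratic solution of 1:1 mass action,

  F([A]₀) = C + k·[A]₀ + (B/n) · ½[(n+[A]₀+K_D) − √((n+[A]₀+K_D)² − 4n[A]₀)],

  collapsing to the hyperbola F = C + k·[A]₀ + B·[A]₀/(K_D+[A]₀) under
  pseudo-first-order conditions. Nonlinear least squares recovers K_D (with
  replicate mean ± s.d.), optionally with a free stoichiometry multiplier,
  and mutant/wild-type fold changes.
* **`structmodel`** — PDB I/O, reduction to a two-bead-per-residue charged
  model (Cα + sidechain centroid; K/R +1, D/E −1), a screened-Coulomb
  surface potential (ε(r)=4r, 40 Å cutoff), negative-patch location and
  grid-based cavity detection.
* **`docking`** — a hierarchical "divide and conquer" flexible-peptide
  docking protocol: exhaustive tripeptide docking by simulated annealing
  (10 runs each), pose clustering at 1.2 Å RMSD, hexamer docking biased
  toward merged tripeptide templates, whole-peptide docking biased toward
  the 100 top hexamer poses, final energy minimization, and salt-bridge
  reporting.
* **`trajanalysis`** — Kabsch superposition, RMSD time series and
  per-residue displacement profiles for multi-model trajectories.
* **`synthetic_data`** — generators for every input: titration curves from
  named presets carrying the published dissociation constants of the
  wild-type and alanine-mutant complexes, a crown-shaped pentamer-like toy
  receptor with an acidic central pore (and a planted electrostatic optimum
  for objective docking tests), and anchored-peptide toy trajectories.
* **`pipeline` / `npmhub` CLI** — one-config orchestration
  (`scan → fit → dock → traj`) with per-stage seeding and a reproducibility
  manifest.

## Worked example

```python
import npmhub as nh

# 1 — scan the Fbw7γ-derived peptide (residues 43-56) for a NoLS
profile, segments = nh.scan_nols("LPFCRRRMKRKLDH")
print([(s.start, s.end, s.peak_score) for s in segments])
print(nh.count_basic("LPFCRRRMKRKLDH"), len(nh.basic_clusters("LPFCRRRMKRKLDH")))

# 2 — synthesize noisy triplicate titrations and recover K_D
wt, triple = nh.presets()["wt_fbw7g"], nh.presets()["triple_fbw7g"]
design = nh.TitrationDesign.linear(a_max=400, n_points=25, replicates=3,
                                   noise_cv=0.02, seed=7)
fit_wt = nh.fit_titration(nh.make_titration(wt, design))
fit_tr = nh.fit_titration(nh.make_titration(triple, design))
print(f"wild type : K_D = {fit_wt.kd:.2f} +/- {fit_wt.kd_sd:.2f} uM")
print(f"triple mut: K_D = {fit_tr.kd:.2f} +/- {fit_tr.kd_sd:.2f} uM")

# 3 — dock the 13-mer into the toy pentamer's acidic pore
receptor = nh.make_toy_receptor()
result = nh.run_hierarchy(receptor, "PFCRRRMKRKLDH",
                          nh.DockingConfig(seed=0), parent_start=44)
print(f"top pose {result.final_pose.total_energy:.1f} kcal/mol, "
      f"{len(result.salt_bridges)} salt bridges")
```

Output:

```
[(1, 14, 1.0)]
6 2
wild type : K_D = 3.56 +/- 0.25 uM
triple mut: K_D = 22.33 +/- 0.55 uM
top pose -113.4 kcal/mol, 7 salt bridges
```

The peptide scores as a saturated NoLS (six basic residues in two clusters),
the fits recover the generating dissociation constants of 3.2 and 22.0 μM
within replicate noise (a ~7-fold loss of affinity for the
D36A-E39A-E93A triple mutant), and the docked peptide ends up threading the
acidic pore, pairing its arginines/lysines with the wall glutamates — e.g.
`GLU20:B -- K51 (3.26 Å)`.

The same pipeline runs from the shell:

```sh
npmhub run-all --outdir demo_run --seed 0
npmhub dock --receptor toy --peptide PFCRRRMKRKLDH --seed 1
npmhub fixtures titration --preset quintuple_fbw7g --out quint.csv
```

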