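"""Synthetic inputs for the whole pipeline: titrations, toy receptors,
anchored trajectories.

No raw experimental data are deposited for this system, so every input the
analyses need is generated here under declared models:

* titration curves drawn from the quadratic binding model at the published
  dissociation constants (named presets cover the wild-type complexes with
  the Fbw7 gamma*, CENP-W* and Tat* NoLS peptides and the full alanine-mutant
  panel), with multiplicative Gaussian noise emulating fluorescence error;
* a crown-shaped n-fold symmetric toy receptor whose acidic beads line a
  central pore, with the pore axis recorded as the planted electrostatic
  optimum so docking tests have an objective target;
* peptide trajectories with Ornstein-Uhlenbeck fluctuation about a start
  pose, tighter for anchored (N-terminal) residues than for free ones,
  emulating a peptide held by its N-terminus.

Preset fluorescence constants B=1, C=0, k=0.001 per uM are package defaults
(only K_D values are published); they make the linear drift visible but
small, as in typical dansyl titrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binding import BindingParams, TitrationCurve, quadratic_model
from .docking import Pose
from .structmodel import Atom, ReceptorModel, write_pdb
from .trajanalysis import Trajectory

__all__ = [
    "BindingParams",
    "TitrationCurve",
    "TitrationDesign",
    "ToyReceptorSpec",
    "TrajectorySpec",
    "Preset",
    "presets",
    "canonical_preset_names",
    "PEPTIDES",
    "make_titration",
    "make_toy_receptor",
    "make_toy_trajectory",
    "write_titration_csv",
    "read_titration_csv",
    "write_receptor_pdb",
    "write_trajectory_pdb",
]

# NoLS-derived peptides recognized by the receptor's N-terminal pentamer,
# keyed by complex label; parent residue numbering of the first residue.
PEPTIDES = {
    "fbw7g": ("LPFCRRRMKRKLDH", 43),
    "cenpw": ("KRKAPRGFLKRVFKRKK", 14),
    "tat": ("AGRKKRRQRRRPPQ", 47),
    "unrelated_long": ("DDEAQTLAKFVLSQK", 1),
    "unrelated_short": ("VLSQK", 1),
}

# published dissociation constants (uM): {protein variant: {peptide: kd}}
_KD_TABLE = {
    "wt": {"fbw7g": 3.2, "cenpw": 6.2, "tat": 2.4},
    "d36a": {"fbw7g": 10.8},
    "e37a": {"fbw7g": 12.5},
    "e39a": {"fbw7g": 6.2},
    "e93a": {"fbw7g": 5.0},
    "e121a": {"fbw7g": 13.3},
    "d36a_e39a": {"fbw7g": 13.5},
    "d36a_e93a": {"fbw7g": 8.4},
    "e39a_e93a": {"fbw7g": 7.6},
    "triple": {"fbw7g": 22.0, "cenpw": 18.4, "tat": 11.1},
    "quad_e37": {"fbw7g": 151.5, "cenpw": 71.4, "tat": 57.4},
    "quad_e121": {"fbw7g": 224.3, "cenpw": 82.8, "tat": 63.8},
    "quintuple": {"fbw7g": 653.7, "cenpw": 734.0, "tat": 642.6},
}

# long-form mutant labels accepted as aliases
_MUTANT_ALIASES = {
    "d36a_e39a_e93a": "triple",
    "d36a_e37a_e39a_e93a": "quad_e37",
    "d36a_e39a_e93a_e121a": "quad_e121",
    "d36a_e37a_e39a_e93a_e121a": "quintuple",
}


@dataclass(frozen=True)
class Preset(BindingParams):
    """A BindingParams with the complex identity attached."""

    peptide: str = ""
    protein: str = ""
    kd_sd: float = 0.0


def presets() -> dict[str, Preset]:
    """Named binding presets for every published complex.

    Keys are "<variant>_<peptide>", e.g. "wt_fbw7g", "triple_tat",
    "quintuple_fbw7g"; long-form mutant names (e.g.
    "d36a_e39a_e93a_fbw7g") alias the same presets.
    """
    sd = {
        ("wt", "fbw7g"): 0.6, ("wt", "cenpw"): 0.9, ("wt", "tat"): 0.5,
        ("d36a", "fbw7g"): 2.6, ("e37a", "fbw7g"): 1.4,
        ("e39a", "fbw7g"): 1.5, ("e93a", "fbw7g"): 1.6,
        ("e121a", "fbw7g"): 3.8, ("d36a_e39a", "fbw7g"): 2.0,
        ("d36a_e93a", "fbw7g"): 1.5, ("e39a_e93a", "fbw7g"): 1.9,
        ("triple", "fbw7g"): 3.0, ("triple", "cenpw"): 2.6,
        ("triple", "tat"): 2.1,
        ("quad_e37", "fbw7g"): 20.5, ("quad_e37", "cenpw"): 9.1,
        ("quad_e37", "tat"): 7.0,
        ("quad_e121", "fbw7g"): 35.9, ("quad_e121", "cenpw"): 5.6,
        ("quad_e121", "tat"): 5.0,
        ("quintuple", "fbw7g"): 46.9, ("quintuple", "cenpw"): 158.0,
        ("quintuple", "tat"): 70.8,
    }
    out = {}
    for variant, by_pep in _KD_TABLE.items():
        for pep, kd in by_pep.items():
            preset = Preset(kd=kd, peptide=PEPTIDES[pep][0], protein=variant,
                            kd_sd=sd.get((variant, pep), 0.0))
            out[f"{variant}_{pep}"] = preset
    for alias, short in _MUTANT_ALIASES.items():
        for pep in _KD_TABLE[short]:
            out[f"{alias}_{pep}"] = out[f"{short}_{pep}"]
    return out


def canonical_preset_names() -> list[str]:
    """Preset keys excluding long-form aliases, in stable order."""
    return [f"{variant}_{pep}"
            for variant, by_pep in _KD_TABLE.items() for pep in by_pep]


@dataclass(frozen=True)
class TitrationDesign:
    """Sampling design of a synthetic titration."""

    a_values: tuple
    replicates: int = 3
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.a_values, dtype=float)
        if np.any(a < 0):
            raise ValueError("concentrations must be non-negative")
        if len(a) >= 2 and not np.all(np.diff(a) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @staticmethod
    def linear(a_max: float = 200.0, n_points: int = 25,
               replicates: int = 3, noise_cv: float = 0.02,
               seed: int = 0) -> "TitrationDesign":
        return TitrationDesign(
            a_values=tuple(np.linspace(0.0, a_max, n_points)),
            replicates=replicates, noise_cv=noise_cv, seed=seed)


def make_titration(params: BindingParams,
                   design: TitrationDesign) -> TitrationCurve:
    """Synthetic titration under the quadratic model.

    F_ij = model(a_i) * (1 + eps_ij), eps ~ Normal(0, noise_cv), seeded;
    noise_cv = 0 reproduces the model exactly.
    """
    a = np.asarray(design.a_values, dtype=float)
    f_model = quadratic_model(a, params)
    rng = np.random.default_rng(design.seed)
    eps = rng.normal(0.0, design.noise_cv if design.noise_cv > 0 else 0.0,
                     size=(design.replicates, len(a)))
    if design.noise_cv == 0:
        eps[:] = 0.0
    f = f_model[None, :] * (1.0 + eps)
    return TitrationCurve(a=a, f=f, n_fixed=params.n)


@dataclass(frozen=True)
class ToyReceptorSpec:
    """Crown-shaped n-fold symmetric bead receptor with an acidic pore.

    Acidic (-1) beads stack along the pore wall at ``ring_radius``; neutral
    beads form a cylindrical body at ``neutral_radius`` that closes the
    diagonal scan directions so the pore registers as a cavity.
    """

    n_fold: int = 5
    ring_radius: float = 4.25
    acidic_per_monomer: int = 3
    neutral_per_monomer: int = 15
    neutral_radius: float = 9.0
    bead_radius: float = 1.7
    stack_spacing: float = 3.6

    def __post_init__(self) -> None:
        if self.n_fold < 3:
            raise ValueError("n_fold must be >= 3")
        if self.ring_radius <= 2 * self.bead_radius:
            raise ValueError("ring_radius must exceed 2 * bead_radius")
        if self.acidic_per_monomer < 0 or self.neutral_per_monomer < 0:
            raise ValueError("bead counts must be >= 0")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")


def make_toy_receptor(spec: ToyReceptorSpec = ToyReceptorSpec()) -> ReceptorModel:
    """Build the toy receptor; raises if any beads overlap.

    The bead set has exact ``n_fold`` rotational symmetry about z; total
    charge is -n_fold * acidic_per_monomer; metadata records the planted
    optimum (pore center and axis).
    """
    pos, chg, rad, resids, chains, roles, resnames = [], [], [], [], [], [], []
    resid = 0
    for k in range(spec.n_fold):
        phi = 2.0 * math.pi * k / spec.n_fold
        chain = chr(ord("A") + k)
        # acidic beads stacked along z at the pore wall; alternate levels
        # staggered by half the azimuthal spacing so the wall has no deep
        # inter-bead pockets competing with the pore axis
        for j in range(spec.acidic_per_monomer):
            z = (j - (spec.acidic_per_monomer - 1) / 2.0) * spec.stack_spacing
            ang = phi + (j % 2) * math.pi / spec.n_fold
            resid += 1
            pos.append((spec.ring_radius * math.cos(ang),
                        spec.ring_radius * math.sin(ang), z))
            chg.append(-1.0)
            rad.append(spec.bead_radius)
            resids.append(resid)
            chains.append(chain)
            roles.append("sidechain")
            resnames.append("GLU")
        # neutral body: rings of 3 beads per monomer per level
        per_ring = 3
        n_rings = max(1, math.ceil(spec.neutral_per_monomer / per_ring))
        wedge = 2.0 * math.pi / spec.n_fold
        for j in range(spec.neutral_per_monomer):
            ring, p = divmod(j, per_ring)
            ang = phi + (p + 0.5 + 0.5 * (ring % 2)) * wedge / per_ring
            z = (ring - (n_rings - 1) / 2.0) * 3.5
            resid += 1
            pos.append((spec.neutral_radius * math.cos(ang),
                        spec.neutral_radius * math.sin(ang), z))
            chg.append(0.0)
            rad.append(spec.bead_radius)
            resids.append(resid)
            chains.append(chain)
            roles.append("sidechain")
            resnames.append("ALA")
    receptor = ReceptorModel(
        np.array(pos), np.array(chg), np.array(rad),
        resids, chains, roles, resnames,
        metadata={
            "symmetry": spec.n_fold,
            "planted_center": (0.0, 0.0, 0.0),
            "planted_axis": (0.0, 0.0, 1.0),
            "spec": spec,
        })
    receptor.check_overlaps()
    return receptor


@dataclass(frozen=True)
class TrajectorySpec:
    """Ornstein-Uhlenbeck fluctuation about a start pose.

    ``anchor_residues`` are 1-based peptide residue indices held near the
    start position (fluctuation scale sigma_anchor); all other residues
    fluctuate with sigma_free.  ``relaxation`` is the per-frame
    mean-reversion rate.
    """

    n_frames: int = 200
    dt: float = 0.005           # ns per frame, nominal
    anchor_residues: frozenset = frozenset(range(1, 7))
    sigma_anchor: float = 0.5   # A stationary per-coordinate s.d.
    sigma_free: float = 3.0
    relaxation: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (0 < self.relaxation <= 1):
            raise ValueError("relaxation must be in (0, 1]")
        if self.sigma_anchor > self.sigma_free:
            raise ValueError("sigma_anchor must be <= sigma_free")
        if self.sigma_anchor < 0:
            raise ValueError("sigmas must be non-negative")


def make_toy_trajectory(start_pose: Pose, spec: TrajectorySpec,
                        receptor: ReceptorModel | None = None) -> Trajectory:
    """Anchored-peptide trajectory: frame 0 equals the start pose exactly.

    Each peptide bead follows a discrete OU process about its start
    coordinate with per-residue stationary s.d.; receptor beads (when a
    receptor is given) are carried as a static frame for fit selections.
    """
    model = start_pose.model
    if spec.anchor_residues and max(spec.anchor_residues) > model.n_residues:
        raise ValueError("anchor residue index beyond peptide length")
    rng = np.random.default_rng(spec.seed)
    n_pep = model.n_beads
    sigma = np.empty(n_pep)
    for i in range(model.n_residues):
        s = (spec.sigma_anchor if (i + 1) in spec.anchor_residues
             else spec.sigma_free)
        sigma[2 * i] = sigma[2 * i + 1] = s
    theta = spec.relaxation
    # step noise giving the requested stationary per-coordinate s.d.
    step_sd = sigma * math.sqrt(max(1.0 - (1.0 - theta) ** 2, 0.0))

    x0 = start_pose.coords
    frames_pep = np.empty((spec.n_frames, n_pep, 3))
    frames_pep[0] = x0
    x = x0.copy()
    for t in range(1, spec.n_frames):
        noise = rng.normal(size=(n_pep, 3)) * step_sd[:, None]
        x = x0 + (1.0 - theta) * (x - x0) + noise
        frames_pep[t] = x

    groups = ["peptide"] * n_pep
    resids = [model.residue_number(i // 2) for i in range(n_pep)]
    names = ["CA" if i % 2 == 0 else "SC" for i in range(n_pep)]
    frames = frames_pep
    if receptor is not None:
        rec = np.broadcast_to(receptor.positions,
                              (spec.n_frames,) + receptor.positions.shape)
        frames = np.concatenate([rec, frames_pep], axis=1)
        groups = ["receptor"] * receptor.n_beads + groups
        resids = list(receptor.resids) + resids
        names = ["CA" if r == "backbone" else "SC"
                 for r in receptor.roles] + names
        # receptor beads are all fit-selectable; mark sidechain beads CA-like
        # only when they are the sole bead type present
        if not any(n == "CA" for n in names[:receptor.n_beads]):
            names[:receptor.n_beads] = ["CA"] * receptor.n_beads
    times = np.arange(spec.n_frames) * spec.dt
    return Trajectory(frames=frames, times=times, groups=groups,
                      resids=resids, names=names,
                      metadata={"spec": spec})


# ---------------------------------------------------------------------------
# plain-text I/O


def write_titration_csv(path, curve: TitrationCurve) -> None:
    import pandas as pd

    rows = []
    for rep in range(curve.n_replicates):
        for a, f in zip(curve.a, curve.f[rep]):
            rows.append({"replicate": rep + 1, "a_uM": a, "fluorescence": f})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titration_csv(path, n_fixed: float = 5.0) -> TitrationCurve:
    import pandas as pd

    df = pd.read_csv(path)
    reps = sorted(df["replicate"].unique())
    a = None
    f = []
    for rep in reps:
        sub = df[df["replicate"] == rep].sort_values("a_uM")
        if a is None:
            a = sub["a_uM"].to_numpy()
        f.append(sub["fluorescence"].to_numpy())
    return TitrationCurve(a=a, f=np.array(f), n_fixed=n_fixed)


def write_receptor_pdb(path, receptor: ReceptorModel) -> None:
    """Single-model PDB, one pseudo-atom per bead, charge in the B-factor."""
    write_pdb(path, [receptor.to_atoms()],
              remark="coarse-grained bead model; bead charge stored in the "
                     "B-factor column")


def write_trajectory_pdb(path, traj: Trajectory) -> None:
    models = []
    for t in range(traj.n_frames):
        atoms = []
        for i in range(traj.frames.shape[1]):
            atoms.append(Atom(
                name=traj.names[i], resname="GLY",
                resseq=int(traj.resids[i]), icode="",
                chain="P" if traj.groups[i] == "peptide" else "R",
                xyz=traj.frames[t, i], element="C"))
        models.append(atoms)
    write_pdb(path, models, remark="coarse-grained bead trajectory")
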