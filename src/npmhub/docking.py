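"""Hierarchical coarse-grained peptide docking ("divide and conquer").

Long flexible basic peptides are docked onto the acidic receptor surface in
stages: (1) every contiguous tripeptide is docked by stochastic search and
its poses clustered; (2) each hexamer window is docked with a harmonic bias
toward templates assembled from the representatives of its two constituent
tripeptides; (3) the whole peptide is docked biased by the top-scoring
hexamer poses, each anchoring its own window; (4) the top pose is locally
energy-minimized.  Salt bridges of the final pose are reported.

The peptide is a two-bead-per-residue chain: backbone beads at C-alpha
positions with a fixed 3.8 A virtual bond, one sidechain bead per residue
carrying the formal charge.  Degrees of freedom are rigid-body translation
and rotation plus one virtual torsion about each consecutive CA-CA axis, so
the backbone connectivity is preserved exactly by construction.

The score is a declared coarse-grained energy (kcal/mol):

    E = sum_pairs 332 q_i q_j / (4 r * r)   (r < 40 A, screened Coulomb)
      + sum_pairs eps_rep * (sigma_ij / r)^8  (soft-sphere repulsion)
      [+ harmonic template bias during biased search only]

Electrostatics dominate by design: the recognition this package models is
charge-driven, and the score makes that explicit rather than emulating any
proprietary docking function.  Stochastic search is simulated annealing
with a geometric temperature schedule; every stage is exactly reproducible
from (config, seed).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structmodel import (
    COULOMB, CUTOFF, DIELECTRIC_SLOPE, ONE_TO_THREE, SIDECHAIN_RADIUS,
    BACKBONE_RADIUS, ReceptorModel, find_cavity,
)

__all__ = [
    "PeptideModel",
    "Pose",
    "PoseSet",
    "Template",
    "DockingConfig",
    "Fragment",
    "enumerate_fragments",
    "score_pose",
    "dock_fragment",
    "cluster_poses",
    "template_dock",
    "run_hierarchy",
    "minimize_pose",
    "salt_bridges",
    "pose_rmsd",
    "HierarchyResult",
    "SaltBridge",
]

CA_CA_DISTANCE = 3.8     # A, fixed virtual bond between consecutive CA beads


def _rv2m(v: np.ndarray) -> np.ndarray:
    """Rotation vector -> matrix (Rodrigues); plain numpy for speed."""
    angle = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if angle < 1e-12:
        return np.eye(3)
    kx, ky, kz = v / angle
    k = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


def _m2rv(m: np.ndarray) -> np.ndarray:
    """Rotation matrix -> rotation vector via a quaternion (Shepperd)."""
    tr = m[0, 0] + m[1, 1] + m[2, 2]
    if tr > 0:
        s = math.sqrt(tr + 1.0) * 2.0
        w = 0.25 * s
        x = (m[2, 1] - m[1, 2]) / s
        y = (m[0, 2] - m[2, 0]) / s
        z = (m[1, 0] - m[0, 1]) / s
    elif m[0, 0] >= m[1, 1] and m[0, 0] >= m[2, 2]:
        s = math.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2.0
        w = (m[2, 1] - m[1, 2]) / s
        x = 0.25 * s
        y = (m[0, 1] + m[1, 0]) / s
        z = (m[0, 2] + m[2, 0]) / s
    elif m[1, 1] >= m[2, 2]:
        s = math.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2.0
        w = (m[0, 2] - m[2, 0]) / s
        x = (m[0, 1] + m[1, 0]) / s
        y = 0.25 * s
        z = (m[1, 2] + m[2, 1]) / s
    else:
        s = math.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2.0
        w = (m[1, 0] - m[0, 1]) / s
        x = (m[0, 2] + m[2, 0]) / s
        y = (m[1, 2] + m[2, 1]) / s
        z = 0.25 * s
    vec = np.array([x, y, z])
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return np.zeros(3)
    angle = 2.0 * math.atan2(norm, w)
    return vec / norm * angle
SIDECHAIN_OFFSET = 2.5   # A, sidechain bead offset from its CA (0 for Gly)
ONE_LETTER_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}
_D_MIN = 0.5             # A, distance floor flagging coincident beads
_STERIC_CAP = 1000.0     # kcal/mol cap per pair at the floor


@dataclass(frozen=True)
class DockingConfig:
    """Search-space, protocol and annealing parameters."""

    center: tuple | None = None     # None -> planted optimum or cavity centroid
    radius: float = 20.0            # A search sphere
    runs: int = 10                  # independent searches per fragment
    cluster_cutoff: float = 1.2     # A pose-clustering RMSD
    max_combos: int = 25            # tripeptide template pairs per hexamer window
    full_template_count: int = 100  # hexamer poses guiding the whole peptide
    runs_per_template: int = 1
    k_bias: float = 5.0             # kcal/mol/A^2 harmonic template bias
    anneal_steps: int = 300
    template_anneal_steps: int = 150  # biased runs refine from the template
    t_start: float = 5.0            # kcal/mol
    t_end: float = 0.05
    seed: int = 0
    epsilon_rep: float = 1.0        # kcal/mol soft-sphere prefactor
    step_trans: float = 1.2         # A proposal scales
    step_rot: float = 0.35          # rad
    step_torsion: float = 0.6       # rad
    sd_rms_gradient: float = 0.005    # steepest-descent stop (kcal/mol/A-equiv)
    cg_max_gradient: float = 0.0004   # conjugate-gradient stop (max component)
    minimize_max_iter: int = 400

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.cluster_cutoff <= 0:
            raise ValueError("cluster cutoff must be positive")
        if self.anneal_steps < 1 or self.t_start <= 0 or self.t_end <= 0:
            raise ValueError("invalid annealing schedule")


class PeptideModel:
    """Coarse-grained flexible peptide.

    Beads are interleaved per residue: index 2i is the backbone (CA) bead of
    residue i, 2i+1 its sidechain bead.  Residue numbering in reports uses
    ``parent_start`` (the residue number of the first peptide residue in the
    parent protein).
    """

    #: virtual CA-CA-CA bond angle of the reference (extended) conformation.
    #: A non-straight backbone is essential: it makes consecutive CA-CA
    #: axes non-collinear, so the virtual torsions genuinely bend the chain.
    VIRTUAL_ANGLE_DEG = 150.0

    def __init__(self, sequence: str, parent_start: int = 1):
        sequence = sequence.upper()
        if not sequence:
            raise ValueError("empty sequence")
        for ch in sequence:
            if ch not in ONE_TO_THREE:
                raise ValueError(f"unknown residue {ch!r}")
        self.sequence = sequence
        self.parent_start = parent_start
        n = len(sequence)
        ref = np.zeros((2 * n, 3))
        charges = np.zeros(2 * n)
        radii = np.zeros(2 * n)
        # planar zigzag backbone with fixed virtual bond angle
        half_turn = math.radians(180.0 - self.VIRTUAL_ANGLE_DEG) / 2.0
        ca = np.zeros(3)
        for i, aa in enumerate(sequence):
            ref[2 * i] = ca
            off = 0.0 if aa == "G" else SIDECHAIN_OFFSET
            ref[2 * i + 1] = ca + (0.0, 0.0, off)
            charges[2 * i + 1] = ONE_LETTER_CHARGE.get(aa, 0.0)
            radii[2 * i] = BACKBONE_RADIUS
            radii[2 * i + 1] = SIDECHAIN_RADIUS.get(ONE_TO_THREE[aa], 2.0)
            phi = half_turn if i % 2 == 0 else -half_turn
            ca = ca + CA_CA_DISTANCE * np.array([math.cos(phi),
                                                 math.sin(phi), 0.0])
        self.reference = ref
        self.charges = charges
        self.radii = radii

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return 2 * self.n_residues

    @property
    def n_torsions(self) -> int:
        return self.n_residues - 1

    @property
    def n_dof(self) -> int:
        return 6 + self.n_torsions

    def residue_number(self, i: int) -> int:
        return self.parent_start + i

    def apply_torsions(self, torsions: np.ndarray) -> np.ndarray:
        """Internal coordinates after rotating about each CA-CA axis."""
        coords = self.reference.copy()
        for k, theta in enumerate(torsions):
            if theta == 0.0:
                continue
            p0 = coords[2 * k]
            axis = coords[2 * (k + 1)] - p0
            axis = axis / np.linalg.norm(axis)
            m = _rv2m(theta * axis)
            # downstream: backbone beads of residues >= k+2, sidechains >= k+1
            idx = [2 * j for j in range(k + 2, self.n_residues)]
            idx += [2 * j + 1 for j in range(k + 1, self.n_residues)]
            coords[idx] = (coords[idx] - p0) @ m.T + p0
        return coords

    def coordinates(self, dofs: np.ndarray,
                    local: np.ndarray | None = None) -> np.ndarray:
        """Bead coordinates for a DOF vector [tx,ty,tz, rotvec(3), torsions].

        ``local`` may supply pre-computed post-torsion coordinates (they only
        depend on dofs[6:]), letting rigid-body moves skip the torsion pass.
        """
        dofs = np.asarray(dofs, dtype=float)
        if dofs.shape != (self.n_dof,):
            raise ValueError(f"expected {self.n_dof} DOFs, got {dofs.shape}")
        if local is None:
            local = self.apply_torsions(dofs[6:])
        return local @ _rv2m(dofs[3:6]).T + dofs[:3]


@dataclass
class EnergyBreakdown:
    electrostatic: float
    steric: float
    bias: float = 0.0
    capped: bool = False

    @property
    def total(self) -> float:
        """Reported energy: physical terms only, the bias is search-time."""
        return self.electrostatic + self.steric

    @property
    def search_total(self) -> float:
        return self.total + self.bias


@dataclass
class Pose:
    """A placed peptide conformation in the receptor frame."""

    model: PeptideModel
    dofs: np.ndarray
    coords: np.ndarray
    energy: EnergyBreakdown
    provenance: dict = field(default_factory=dict)

    @property
    def total_energy(self) -> float:
        return self.energy.total


class PoseSet(list):
    """Collection of poses sharing one peptide topology."""

    def sorted_by_energy(self) -> "PoseSet":
        return PoseSet(sorted(
            self, key=lambda p: (p.total_energy, p.provenance.get("id", 0))))


@dataclass
class Template:
    """Target coordinates for a subset of peptide residues (both beads)."""

    residue_indices: np.ndarray  # 0-based indices into the docked model
    coords: np.ndarray           # (2*len(residue_indices), 3)

    def bead_indices(self, model: PeptideModel) -> np.ndarray:
        idx = []
        for i in self.residue_indices:
            if not (0 <= i < model.n_residues):
                raise ValueError(
                    f"template residue {i} outside model of length "
                    f"{model.n_residues}")
            idx.extend((2 * i, 2 * i + 1))
        return np.array(idx, dtype=int)


@dataclass(frozen=True)
class Fragment:
    sequence: str
    start: int  # 1-based position in the parent sequence


def enumerate_fragments(sequence: str, k: int) -> list[Fragment]:
    """All contiguous k-mers of the sequence with 1-based parent offsets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} shorter than k={k}")
    return [Fragment(sequence[i:i + k], i + 1)
            for i in range(len(sequence) - k + 1)]


def score_pose(receptor: ReceptorModel, coords: np.ndarray,
               charges: np.ndarray, radii: np.ndarray,
               config: DockingConfig,
               template_coords: np.ndarray | None = None,
               template_beads: np.ndarray | None = None) -> EnergyBreakdown:
    """Coarse-grained receptor-peptide energy with optional template bias."""
    d = cdist(receptor.positions, coords)
    capped = bool(np.any(d < _D_MIN))
    d_eff = np.maximum(d, _D_MIN)
    qq = np.outer(receptor.charges, charges)
    elec = float(np.sum(np.where(
        d < CUTOFF, COULOMB * qq / (DIELECTRIC_SLOPE * d_eff * d_eff), 0.0)))
    sigma = receptor.radii[:, None] + radii[None, :]
    steric = float(np.sum(np.minimum(
        config.epsilon_rep * (sigma / d_eff) ** 8, _STERIC_CAP)))
    bias = 0.0
    if template_coords is not None:
        diff = coords[template_beads] - template_coords
        bias = 0.5 * config.k_bias * float(np.sum(diff * diff))
    return EnergyBreakdown(electrostatic=elec, steric=steric, bias=bias,
                           capped=capped)


def resolve_center(receptor: ReceptorModel,
                   config: DockingConfig) -> np.ndarray:
    """Search-sphere center: explicit config, planted optimum, or cavity."""
    if config.center is not None:
        return np.asarray(config.center, dtype=float)
    if "planted_center" in receptor.metadata:
        return np.asarray(receptor.metadata["planted_center"], dtype=float)
    cav = find_cavity(receptor)
    if not cav.found:
        raise ValueError("no cavity found and no search center given")
    return cav.center


def cavity_axis(receptor: ReceptorModel) -> np.ndarray | None:
    """Principal axis of the receptor's largest cavity (PCA of its grid
    points), used to orient insertion moves; None if there is no cavity or
    no dominant direction."""
    cav = find_cavity(receptor)
    if not cav.found or cav.n_points < 8:
        return None
    pts = cav.points - cav.points.mean(axis=0)
    w, v = np.linalg.eigh(np.cov(pts.T))
    if w[-1] < 1.5 * w[-2]:
        return None
    return v[:, -1]


def _cached_axis(receptor: ReceptorModel):
    if "_cavity_axis" not in receptor.metadata:
        receptor.metadata["_cavity_axis"] = cavity_axis(receptor)
    return receptor.metadata["_cavity_axis"]


def _rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-stage/-fragment/-run RNG stream."""
    clean = tuple(zlib.crc32(k.encode()) if isinstance(k, str) else int(k)
                  for k in keys)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % (2 ** 31), spawn_key=clean))


def _random_rotvec(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v /= max(np.linalg.norm(v), 1e-12)
    return v * rng.uniform(0.0, math.pi)


def _anneal(receptor, model, config, rng, center,
            template: Template | None = None,
            init_dofs: np.ndarray | None = None,
            axis: np.ndarray | None = None,
            provenance: dict | None = None,
            n_steps: int | None = None) -> Pose:
    """One simulated-annealing search; returns its best pose."""
    if n_steps is None:
        n_steps = config.anneal_steps
    t_coords = t_beads = None
    if template is not None:
        t_beads = template.bead_indices(model)
        t_coords = template.coords

    def energy(coords):
        return score_pose(receptor, coords, model.charges, model.radii,
                          config, t_coords, t_beads)

    if init_dofs is None:
        dofs = np.zeros(model.n_dof)
        u = rng.normal(size=3)
        u /= max(np.linalg.norm(u), 1e-12)
        dofs[:3] = center + u * config.radius * 0.3 * rng.random() ** (1 / 3)
        dofs[3:6] = _random_rotvec(rng)
        dofs[6:] = rng.uniform(-math.pi, math.pi, size=model.n_torsions)
    else:
        dofs = np.asarray(init_dofs, dtype=float).copy()

    local = model.apply_torsions(dofs[6:])
    coords = model.coordinates(dofs, local=local)
    e = energy(coords)
    best = (dofs.copy(), coords.copy(), e)
    cur_search = e.search_total
    ratio = config.t_end / config.t_start
    for step in range(n_steps):
        temp = config.t_start * ratio ** (step / max(n_steps - 1, 1))
        trial = dofs.copy()
        trial_local = local
        kind = rng.random()
        # jump moves dominate the hot phase (exploration), then fade
        jump_prob = 0.15 if step < n_steps // 2 else 0.03
        if kind < jump_prob:
            # jump move: re-place near the search center (large-scale hop)
            sub = rng.random()
            if axis is not None and sub < 0.5:
                # insertion-oriented: align the peptide's long axis with the
                # cavity's principal axis, random spin/tilt, land on the axis
                pl = trial_local - trial_local.mean(axis=0)
                _, evecs = np.linalg.eigh(np.cov(pl.T))
                long_dir = evecs[:, -1]
                tdir = axis if rng.random() < 0.5 else -axis
                cross = np.cross(long_dir, tdir)
                sn = np.linalg.norm(cross)
                ang = math.atan2(sn, float(np.dot(long_dir, tdir)))
                m_align = (_rv2m(cross / sn * ang) if sn > 1e-9
                           else _rv2m(np.array([0.0, 0.0, ang])))
                m_spin = _rv2m(tdir * rng.uniform(0.0, 2.0 * math.pi))
                m_tilt = _rv2m(rng.normal(scale=0.1, size=3))
                trial[3:6] = _m2rv(m_tilt @ m_spin @ m_align)
                target = (center + axis * rng.uniform(-3.0, 3.0)
                          + rng.normal(scale=0.5, size=3))
            elif sub < 0.7:
                u = rng.normal(size=3)
                u /= max(np.linalg.norm(u), 1e-12)
                spread = 0.15 if sub < 0.6 else 1.0
                target = (center + u * spread * config.radius
                          * rng.random() ** (1 / 3))
                trial[3:6] = _random_rotvec(rng)
            else:
                # retreat move: hop radially outward to escape steric traps
                away = coords.mean(axis=0) - center
                nrm = np.linalg.norm(away)
                away = (away / nrm if nrm > 1e-9
                        else np.array([1.0, 0.0, 0.0]))
                target = (center + away
                          * min(0.9 * config.radius,
                                nrm + rng.uniform(8.0, 14.0)))
                trial[3:6] = _random_rotvec(rng)
            new_coords = model.coordinates(trial, local=trial_local)
            trial[:3] += target - new_coords.mean(axis=0)
        elif kind < 0.45:
            # translation step widens with temperature for early exploration
            scale = config.step_trans * (1.0 + 2.0 * temp / config.t_start)
            trial[:3] += rng.normal(scale=scale, size=3)
        elif kind < 0.7 or model.n_torsions == 0:
            delta = _rv2m(rng.normal(scale=config.step_rot, size=3))
            trial[3:6] = _m2rv(delta @ _rv2m(trial[3:6]))
        else:
            j = 6 + rng.integers(model.n_torsions)
            trial[j] += rng.normal(scale=config.step_torsion)
            trial_local = model.apply_torsions(trial[6:])
        trial_coords = model.coordinates(trial, local=trial_local)
        # keep at least one bead inside the search sphere
        if np.min(np.linalg.norm(trial_coords - center, axis=1)) > config.radius:
            continue
        e_trial = energy(trial_coords)
        delta = e_trial.search_total - cur_search
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            dofs, local, coords, e = trial, trial_local, trial_coords, e_trial
            cur_search = e_trial.search_total
            if e.search_total < best[2].search_total:
                best = (dofs.copy(), coords.copy(), e)
    prov = dict(provenance or {})
    return Pose(model=model, dofs=best[0], coords=best[1], energy=best[2],
                provenance=prov)


def dock_fragment(receptor: ReceptorModel, model: PeptideModel,
                  config: DockingConfig,
                  stage: str = "fragment", fragment_index: int = 0) -> PoseSet:
    """Independent seeded annealing runs; best pose of each run is kept."""
    if config.runs < 1:
        raise ValueError("runs must be >= 1")
    center = resolve_center(receptor, config)
    axis = _cached_axis(receptor)
    poses = PoseSet()
    for run in range(config.runs):
        rng = _rng(config.seed, stage, fragment_index, run)
        pose = _anneal(receptor, model, config, rng, center, axis=axis,
                       provenance={"stage": stage, "fragment": fragment_index,
                                   "run": run, "seed": config.seed,
                                   "id": fragment_index * 10 ** 6 + run})
        poses.append(pose)
    return poses


def pose_rmsd(p1: Pose, p2: Pose) -> float:
    """Receptor-frame RMSD over all beads, no re-superposition."""
    if p1.coords.shape != p2.coords.shape:
        raise ValueError("poses do not share a topology")
    diff = p1.coords - p2.coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def cluster_poses(poses, cutoff: float = 1.2) -> PoseSet:
    """Greedy energy-ordered clustering; representatives energy-sorted.

    The best pose seeds a cluster and absorbs everything within ``cutoff``
    RMSD; ties in energy break on provenance id.
    """
    remaining = list(PoseSet(poses).sorted_by_energy())
    reps = PoseSet()
    while remaining:
        rep = remaining.pop(0)
        reps.append(rep)
        remaining = [p for p in remaining if pose_rmsd(rep, p) >= cutoff]
    return reps


def _rigid_fit(src: np.ndarray, dst: np.ndarray):
    """Proper rotation R and translation t minimizing |R src + t - dst|."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, dc - rot @ sc


def _template_init(model: PeptideModel, template: Template) -> np.ndarray:
    """Initial DOFs fitting the model onto the template.

    The rigid part is read off the torsion-independent beads of the first
    mapped residue pair (CA_w, SC_w, CA_{w+1}); each virtual torsion k is
    then solved in closed form from its immediate dependents (CA_{k+2} and
    SC_{k+1}) when they are mapped.  A template that is realizable by the
    model is recovered exactly; merged multi-fragment templates get a
    least-squares-flavored fit that the biased search then refines.
    """
    beads = template.bead_indices(model)
    bead_to_pos = {int(j): pos for pos, j in enumerate(beads)}
    residues = sorted(int(i) for i in template.residue_indices)
    w = residues[0]
    tgt = template.coords

    torsions = np.zeros(model.n_torsions)
    # local frame with all torsions zero: the anchor triplet sits at its
    # reference position (unaffected by torsions >= w when torsions < w = 0)
    anchor = [2 * w]
    if model.sequence[w] != "G":
        anchor.append(2 * w + 1)
    if w + 1 in residues:
        anchor.append(2 * (w + 1))
    if len(anchor) < 3:     # single mapped residue: centroid match only
        rot = np.eye(3)
        trans = tgt[bead_to_pos[2 * w]] - model.reference[2 * w]
    else:
        rot, trans = _rigid_fit(model.reference[anchor],
                                np.array([tgt[bead_to_pos[j]]
                                          for j in anchor]))
    t_local = (tgt - trans) @ rot           # template in the local frame

    coords = model.reference.copy()
    for k in range(w, model.n_torsions):
        p0 = coords[2 * k]
        u = coords[2 * (k + 1)] - p0
        u = u / np.linalg.norm(u)
        dependents = []
        if 2 * (k + 2) in bead_to_pos:      # CA of residue k+2
            dependents.append(2 * (k + 2))
        if 2 * (k + 1) + 1 in bead_to_pos:  # sidechain of residue k+1
            dependents.append(2 * (k + 1) + 1)
        num = den = 0.0
        for j in dependents:
            a = coords[j] - p0
            b = t_local[bead_to_pos[j]] - p0
            a_perp = a - u * (a @ u)
            b_perp = b - u * (b @ u)
            num += np.cross(a_perp, b_perp) @ u
            den += a_perp @ b_perp
        theta = math.atan2(num, den) if dependents and \
            (abs(num) > 1e-12 or abs(den) > 1e-12) else 0.0
        torsions[k] = theta
        if theta != 0.0:
            down = ([2 * j for j in range(k + 2, model.n_residues)]
                    + [2 * j + 1 for j in range(k + 1, model.n_residues)])
            m = _rv2m(theta * u)
            coords[down] = (coords[down] - p0) @ m.T + p0

    local = model.apply_torsions(torsions)
    rot, trans = _rigid_fit(local[beads], tgt)
    dofs = np.zeros(model.n_dof)
    dofs[3:6] = _m2rv(rot)
    dofs[:3] = trans
    dofs[6:] = torsions
    return dofs


def template_dock(receptor: ReceptorModel, model: PeptideModel,
                  templates, config: DockingConfig,
                  stage: str = "template", base_index: int = 0) -> PoseSet:
    """Biased docking: one annealing run per template (times runs_per_template).

    The harmonic bias pulls mapped beads toward template coordinates during
    the search only; reported pose energies exclude it.
    """
    center = resolve_center(receptor, config)
    axis = _cached_axis(receptor)
    poses = PoseSet()
    for t_idx, template in enumerate(templates):
        template.bead_indices(model)  # validates the residue mapping
        for run in range(config.runs_per_template):
            rng = _rng(config.seed, stage, base_index, t_idx, run)
            init = _template_init(model, template)
            pose = _anneal(
                receptor, model, config, rng, center, template=template,
                init_dofs=init, axis=axis,
                n_steps=config.template_anneal_steps,
                provenance={"stage": stage, "template": t_idx, "run": run,
                            "window": base_index, "seed": config.seed,
                            "id": (base_index * 10 ** 6 + t_idx) * 100 + run})
            poses.append(pose)
    return poses


def _numeric_gradient(fun, x, h: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2 * h)
    return g


def minimize_pose(receptor: ReceptorModel, pose: Pose,
                  config: DockingConfig) -> Pose:
    """Local minimization in DOF space: steepest descent, then conjugate
    gradients.

    Steepest descent runs until the RMS gradient falls below
    ``sd_rms_gradient``; Polak-Ribiere conjugate gradients then continue until
    the maximum gradient component is below ``cg_max_gradient`` (score units
    per DOF unit).  Energy is non-increasing over accepted steps; an
    iteration cap sets ``converged`` in the provenance if hit first.
    """
    model = pose.model

    def fun(dofs):
        return score_pose(receptor, model.coordinates(dofs),
                          model.charges, model.radii, config).total

    x = np.asarray(pose.dofs, dtype=float).copy()
    e = fun(x)
    if not math.isfinite(e):
        raise ValueError("non-finite starting energy")

    def line_search(x, e, direction, alpha):
        """Backtracking step; returns (x, e, alpha) or None on failure."""
        while alpha > 1e-14:
            xn = x + alpha * direction
            en = fun(xn)
            if en <= e:
                return xn, en, alpha
            alpha *= 0.5
        return None

    trace = [e]
    alpha = 0.1
    converged_sd = False
    stall = 0
    it = 0
    g = _numeric_gradient(fun, x)
    while it < config.minimize_max_iter:
        rms = float(np.sqrt(np.mean(g * g)))
        if rms <= config.sd_rms_gradient:
            converged_sd = True
            break
        gn = np.linalg.norm(g)
        step = line_search(x, e, -g / max(gn, 1e-12), alpha)
        if step is None:
            break
        x, e_new, alpha = step
        stall = stall + 1 if e - e_new < 1e-10 * max(abs(e), 1.0) else 0
        e = e_new
        alpha = min(alpha * 1.5, 1.0)
        trace.append(e)
        g = _numeric_gradient(fun, x)
        it += 1
        if stall >= 8:  # energy plateau: treat as locally converged
            converged_sd = True
            break

    # conjugate-gradient polish to the max-derivative threshold
    from scipy.optimize import minimize as _scipy_minimize

    converged_cg = float(np.max(np.abs(g))) <= config.cg_max_gradient
    if not converged_cg:
        res = _scipy_minimize(
            fun, x, method="CG", jac=lambda xx: _numeric_gradient(fun, xx),
            callback=lambda xk: trace.append(fun(xk)),
            options={"gtol": config.cg_max_gradient, "norm": np.inf,
                     "maxiter": max(config.minimize_max_iter - it, 1)})
        if res.fun <= e:  # accept only a non-increasing outcome
            x, e = res.x, float(res.fun)
            it += int(res.nit)
            converged_cg = bool(res.status == 0)
        trace.append(e)

    coords = model.coordinates(x)
    energy = score_pose(receptor, coords, model.charges, model.radii, config)
    prov = dict(pose.provenance)
    prov.update({"stage": "minimized", "converged": converged_cg,
                 "sd_converged": converged_sd, "iterations": it,
                 "energy_trace": trace})
    return Pose(model=model, dofs=x, coords=coords, energy=energy,
                provenance=prov)


@dataclass(frozen=True)
class SaltBridge:
    receptor_residue: str   # e.g. "GLU121:A"
    peptide_residue: str    # parent numbering, e.g. "R47"
    distance: float


def salt_bridges(receptor: ReceptorModel, pose: Pose,
                 cutoff: float = 4.0) -> list[SaltBridge]:
    """Acidic(receptor)-basic(peptide) sidechain-bead pairs within cutoff."""
    model = pose.model
    rec_idx = [i for i in range(receptor.n_beads)
               if receptor.roles[i] == "sidechain" and receptor.charges[i] < 0]
    pep_idx = [2 * i + 1 for i in range(model.n_residues)
               if model.charges[2 * i + 1] > 0]
    bridges = []
    for ri in rec_idx:
        for pi in pep_idx:
            dist = float(np.linalg.norm(receptor.positions[ri]
                                        - pose.coords[pi]))
            if dist <= cutoff:
                res_i = pi // 2
                bridges.append(SaltBridge(
                    receptor_residue=(f"{receptor.resnames[ri]}"
                                      f"{receptor.resids[ri]}:"
                                      f"{receptor.chains[ri]}"),
                    peptide_residue=(f"{model.sequence[res_i]}"
                                     f"{model.residue_number(res_i)}"),
                    distance=dist,
                ))
    return sorted(bridges, key=lambda b: b.distance)


@dataclass
class HierarchyResult:
    final_pose: Pose | None
    ranked_poses: PoseSet
    tripeptide_representatives: dict     # fragment index -> PoseSet
    hexamer_pose_count: int
    mean_pairwise_rmsd_top10: float
    salt_bridges: list
    tripeptide_poses: dict = field(default_factory=dict)  # raw stage-1 poses
    full_templates: list = field(default_factory=list)  # stage-3 guides
    notices: list = field(default_factory=list)


def _mean_pairwise_rmsd(poses) -> float:
    if len(poses) < 2:
        return 0.0
    vals = [pose_rmsd(poses[i], poses[j])
            for i in range(len(poses)) for j in range(i + 1, len(poses))]
    return float(np.mean(vals))


def run_hierarchy(receptor: ReceptorModel, sequence: str,
                  config: DockingConfig,
                  parent_start: int = 1) -> HierarchyResult:
    """The full divide-and-conquer protocol on one peptide sequence."""
    notices = []
    n = len(sequence)
    if n < 3:
        raise ValueError("peptide must have at least 3 residues")

    # stage 1: exhaustive tripeptide docking + clustering
    frags = enumerate_fragments(sequence, 3)
    reps: dict[int, PoseSet] = {}
    raw: dict[int, PoseSet] = {}
    for i, frag in enumerate(frags):
        model = PeptideModel(frag.sequence, parent_start + i)
        poses = dock_fragment(receptor, model, config,
                              stage="tripeptide", fragment_index=i)
        raw[i] = poses
        reps[i] = cluster_poses(poses, config.cluster_cutoff)

    if n < 6:
        notices.append("peptide shorter than 6 residues: protocol stopped "
                       "after tripeptide stage")
        return HierarchyResult(
            final_pose=None, ranked_poses=PoseSet(),
            tripeptide_representatives=reps, hexamer_pose_count=0,
            mean_pairwise_rmsd_top10=0.0, salt_bridges=[],
            tripeptide_poses=raw, notices=notices)

    # stage 2: hexamer windows biased by their two constituent tripeptides
    hex_poses = PoseSet()
    for w in range(n - 5):
        model = PeptideModel(sequence[w:w + 6], parent_start + w)
        combos = sorted(
            ((a.total_energy + b.total_energy, ia, ib)
             for ia, a in enumerate(reps[w])
             for ib, b in enumerate(reps[w + 3])),
        )[:config.max_combos]
        templates = [
            Template(residue_indices=np.arange(6),
                     coords=np.vstack([reps[w][ia].coords,
                                       reps[w + 3][ib].coords]))
            for _, ia, ib in combos
        ]
        hex_poses.extend(template_dock(receptor, model, templates, config,
                                       stage="hexamer", base_index=w))

    # stage 3: whole peptide biased by the top-scoring hexamer poses,
    # each anchoring its own window
    top_hex = hex_poses.sorted_by_energy()[:config.full_template_count]
    model_full = PeptideModel(sequence, parent_start)
    templates = [
        Template(residue_indices=np.arange(p.provenance["window"],
                                           p.provenance["window"] + 6),
                 coords=p.coords)
        for p in top_hex
    ]
    full_poses = template_dock(receptor, model_full, templates, config,
                               stage="full", base_index=0)
    ranked = full_poses.sorted_by_energy()

    # stage 4: final minimization of the top pose
    final = minimize_pose(receptor, ranked[0], config)
    bridges = salt_bridges(receptor, final)
    return HierarchyResult(
        final_pose=final, ranked_poses=ranked,
        tripeptide_representatives=reps,
        hexamer_pose_count=len(hex_poses),
        mean_pairwise_rmsd_top10=_mean_pairwise_rmsd(ranked[:10]),
        salt_bridges=bridges, tripeptide_poses=raw,
        full_templates=templates, notices=notices)
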