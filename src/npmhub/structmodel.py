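"""Structure I/O and the coarse-grained charged-bead receptor representation.

The analyses in this package are electrostatics-driven: what matters about
the receptor is where its charged side chains sit, not its all-atom detail.
Structures are therefore reduced to two beads per residue: a backbone bead
at the C-alpha and a sidechain bead at the sidechain heavy-atom centroid,
carrying the formal sidechain charge (K/R +1, D/E -1, others 0).

The electrostatic potential uses a screened Coulomb form with a
distance-dependent dielectric eps(r) = 4r and a 40 A cutoff,

    phi(p) = sum_i 332 * q_i / (4 r_i * r_i)   [kcal/mol per unit probe charge]

which reproduces the qualitative negative-patch topography (external surface
funnelling into the central cavity of the pentamer) without solving
Poisson-Boltzmann.  Cavity detection is grid-based: probe points occluded by
receptor beads in at least 11 of 14 scan directions are buried; the largest
connected buried component (above a solvent-probe-sized minimum volume) is
the cavity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "Atom",
    "Structure",
    "ReceptorModel",
    "GridSpec",
    "PotentialMap",
    "PatchResult",
    "CavityResult",
    "read_pdb",
    "write_pdb",
    "coarse_grain",
    "surface_potential",
    "acidic_patch",
    "find_cavity",
    "RESIDUE_CHARGE",
    "SIDECHAIN_RADIUS",
]

COULOMB = 332.0          # kcal*A/(mol*e^2)
DIELECTRIC_SLOPE = 4.0   # eps(r) = 4r
CUTOFF = 40.0            # A
PROBE_RADIUS = 1.4       # A, solvent-sized probe for potential/cavity grids

RESIDUE_CHARGE = {"LYS": 1, "ARG": 1, "ASP": -1, "GLU": -1}

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# effective sidechain bead radii (A); coarse values, default 2.0
SIDECHAIN_RADIUS = {
    "GLY": 1.0, "ALA": 1.5, "SER": 1.6, "CYS": 1.7, "THR": 1.7, "VAL": 1.8,
    "PRO": 1.8, "ASP": 1.8, "ASN": 1.8, "ILE": 2.0, "LEU": 2.0, "GLU": 2.0,
    "GLN": 2.0, "MET": 2.1, "HIS": 2.0, "LYS": 2.2, "ARG": 2.3, "PHE": 2.2,
    "TYR": 2.3, "TRP": 2.4,
}
BACKBONE_RADIUS = 2.0
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Atom:
    name: str
    resname: str
    resseq: int
    icode: str
    chain: str
    xyz: np.ndarray
    element: str = ""
    bfactor: float = 0.0


@dataclass
class Structure:
    """Parsed structure: one atom list per model."""

    models: list  # list[list[Atom]]

    @property
    def n_models(self) -> int:
        return len(self.models)

    def atoms(self, model: int = 0) -> list:
        return self.models[model]


def _validate_pdb_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(
                    f"{path}: truncated coordinate record at line {lineno}")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed coordinate field at line {lineno}"
                ) from None


def read_pdb(path) -> Structure:
    """Read a (possibly multi-model) PDB file.

    Coordinate records are pre-validated so malformed lines raise an error
    naming the offending line number; parsing proper is done with Bio.PDB.
    """
    from Bio.PDB import PDBParser

    _validate_pdb_lines(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = PDBParser(QUIET=True).get_structure("s", path)
    models = []
    for model in bio:
        atoms = []
        for chain in model:
            for res in chain:
                _, resseq, icode = res.id
                for atom in res:
                    atoms.append(Atom(
                        name=atom.get_name(),
                        resname=res.get_resname(),
                        resseq=resseq,
                        icode=icode.strip(),
                        chain=chain.id,
                        xyz=np.array(atom.coord, dtype=float),
                        element=(atom.element or "").strip(),
                        bfactor=float(atom.get_bfactor() or 0.0),
                    ))
        models.append(atoms)
    if not models:
        raise ValueError(f"{path}: no models found")
    return Structure(models=models)


def _format_atom(serial, name, resname, chain, resseq, xyz, bfactor, element):
    return (
        f"ATOM  {serial:>5d} {name:<4.4s} {resname:<3.3s}{chain:>2.1s}"
        f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{bfactor:6.2f}          {element:>2.2s}"
    )


def write_pdb(path, models, remark: str | None = None) -> None:
    """Write lists of Atom records as a (multi-model) PDB file."""
    multi = len(models) > 1
    with open(path, "w") as fh:
        if remark:
            for ln in remark.splitlines():
                fh.write(f"REMARK   3 {ln}\n")
        for i, atoms in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {i:>4d}\n")
            for serial, at in enumerate(atoms, start=1):
                fh.write(_format_atom(
                    serial, at.name, at.resname, at.chain, at.resseq,
                    at.xyz, at.bfactor, at.element) + "\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


@dataclass
class ReceptorModel:
    """Coarse-grained receptor: parallel arrays over beads.

    roles are "backbone" or "sidechain"; charges are formal (-1, 0, +1).
    """

    positions: np.ndarray          # (N, 3) A
    charges: np.ndarray            # (N,) e
    radii: np.ndarray              # (N,) A
    resids: list                   # per-bead residue number
    chains: list
    roles: list
    resnames: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.positions)
        for name in ("charges", "radii"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if not np.all(np.isin(np.abs(self.charges), (0.0, 1.0))):
            raise ValueError("bead charges must be -1, 0 or +1")
        if np.any(self.radii <= 0):
            raise ValueError("bead radii must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("bead positions must be finite")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def charged_mask(self, sign: int | None = None) -> np.ndarray:
        if sign is None:
            return self.charges != 0
        return np.sign(self.charges) == sign

    def check_overlaps(self, tol: float = 1e-9) -> None:
        """Raise if any two beads overlap (distance < sum of radii)."""
        if self.n_beads < 2:
            return
        d = pdist(self.positions)
        rsum = self.radii[:, None] + self.radii[None, :]
        iu = np.triu_indices(self.n_beads, k=1)
        bad = d < rsum[iu] - tol
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"overlapping beads {iu[0][i]} and {iu[1][i]} "
                f"(distance {d[i]:.3f} < {rsum[iu][i]:.3f})")

    def to_atoms(self) -> list:
        atoms = []
        for i in range(self.n_beads):
            atoms.append(Atom(
                name="CA" if self.roles[i] == "backbone" else "SC",
                resname=self.resnames[i], resseq=int(self.resids[i]),
                icode="", chain=str(self.chains[i]),
                xyz=self.positions[i], element="C",
                bfactor=float(self.charges[i]),  # charge stored in B-factor
            ))
        return atoms


def coarse_grain(structure: Structure, charge_rules: dict | None = None,
                 model: int = 0) -> ReceptorModel:
    """Reduce a structure to two beads per residue (backbone CA + sidechain).

    Glycine's sidechain bead is co-located with its C-alpha.  Residues with
    no C-alpha are skipped with a warning.
    """
    rules = RESIDUE_CHARGE if charge_rules is None else charge_rules
    groups: dict = {}
    order = []
    for at in structure.atoms(model):
        key = (at.chain, at.resseq, at.icode)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(at)

    pos, chg, rad, resids, chains, roles, resnames = [], [], [], [], [], [], []
    for key in order:
        atoms = groups[key]
        resname = atoms[0].resname
        ca = [a for a in atoms if a.name == "CA"]
        if not ca:
            warnings.warn(
                f"residue {resname} {key[0]}{key[1]} has no CA; skipped")
            continue
        ca_xyz = ca[0].xyz
        side = [a.xyz for a in atoms
                if a.name not in BACKBONE_ATOMS and not a.element.startswith("H")
                and not a.name.startswith("H")]
        sc_xyz = np.mean(side, axis=0) if side else ca_xyz.copy()
        sc_rad = SIDECHAIN_RADIUS.get(resname, 2.0)
        for xyz, role, q, r in (
            (ca_xyz, "backbone", 0.0, BACKBONE_RADIUS),
            (sc_xyz, "sidechain", float(rules.get(resname, 0)), sc_rad),
        ):
            pos.append(xyz)
            chg.append(q)
            rad.append(r)
            resids.append(key[1])
            chains.append(key[0])
            roles.append(role)
            resnames.append(resname)
    return ReceptorModel(np.array(pos), np.array(chg), np.array(rad),
                         resids, chains, roles, resnames)


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned cubic probe grid."""

    center: tuple = (0.0, 0.0, 0.0)
    half_extent: float = 10.0
    spacing: float = 1.0

    def points(self) -> np.ndarray:
        ax = np.arange(-self.half_extent, self.half_extent + 0.5 * self.spacing,
                       self.spacing)
        g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        return g.reshape(-1, 3) + np.asarray(self.center, dtype=float)


@dataclass
class PotentialMap:
    points: np.ndarray   # (M, 3)
    values: np.ndarray   # (M,) kcal/mol per unit probe charge
    params: dict = field(default_factory=dict)


def potential_at(receptor: ReceptorModel, points: np.ndarray,
                 cutoff: float = CUTOFF) -> np.ndarray:
    """Screened-Coulomb potential of the receptor charges at given points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    mask = receptor.charges != 0
    if not np.any(mask):
        return np.zeros(len(points))
    q = receptor.charges[mask]
    d = cdist(points, receptor.positions[mask])
    d = np.maximum(d, 1e-6)
    contrib = np.where(d < cutoff, COULOMB * q / (DIELECTRIC_SLOPE * d * d), 0.0)
    return contrib.sum(axis=1)


def surface_potential(receptor: ReceptorModel,
                      grid: GridSpec | np.ndarray,
                      probe_radius: float = PROBE_RADIUS) -> PotentialMap:
    """Potential map on a probe grid, excluding probes inside beads.

    A probe counts as inside a bead when closer than bead radius plus the
    probe radius (solvent-sized, 1.4 A by default).
    """
    if not np.any(receptor.charges != 0):
        raise ValueError("receptor has no charged beads")
    pts = grid.points() if isinstance(grid, GridSpec) else np.atleast_2d(grid)
    d = cdist(pts, receptor.positions)
    outside = np.all(d >= receptor.radii[None, :] + probe_radius, axis=1)
    pts = pts[outside]
    vals = potential_at(receptor, pts)
    return PotentialMap(points=pts, values=vals,
                        params={"dielectric": "4r", "cutoff": CUTOFF,
                                "probe_radius": probe_radius})


@dataclass
class PatchResult:
    residues: list          # (chain, resid, resname) of patch residues
    centroid: np.ndarray | None
    n_probes: int = 0


def acidic_patch(pmap: PotentialMap, receptor: ReceptorModel,
                 quantile: float = 0.05, link_cutoff: float = 3.0,
                 residue_cutoff: float = 6.0) -> PatchResult:
    """Locate the dominant negative surface patch.

    Probes in the lowest-potential quantile (and strictly negative) are
    single-linkage clustered at ``link_cutoff``; charged-bead residues within
    ``residue_cutoff`` of the largest cluster are reported.
    """
    neg = pmap.values < 0
    if not np.any(neg):
        return PatchResult(residues=[], centroid=None)
    thresh = np.quantile(pmap.values, quantile)
    sel = neg & (pmap.values <= thresh)
    pts = pmap.points[sel]
    if len(pts) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(linkage(pts, method="single"), t=link_cutoff,
                          criterion="distance")
    best = np.argmax(np.bincount(labels))
    cluster = pts[labels == best]
    centroid = cluster.mean(axis=0)
    charged = np.flatnonzero(receptor.charges != 0)
    d = cdist(receptor.positions[charged], cluster).min(axis=1)
    residues = []
    seen = set()
    for idx in charged[d <= residue_cutoff]:
        key = (receptor.chains[idx], receptor.resids[idx],
               receptor.resnames[idx])
        if key not in seen:
            seen.add(key)
            residues.append(key)
    return PatchResult(residues=residues, centroid=centroid,
                       n_probes=len(cluster))


@dataclass
class CavityResult:
    center: np.ndarray | None
    volume: float            # A^3
    n_points: int
    points: np.ndarray | None = None   # member grid points (N, 3)

    @property
    def found(self) -> bool:
        return self.n_points > 0


# 14 scan directions: 6 axes + 8 cube diagonals (integer voxel steps)
_DIRECTIONS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    (-1, 1, 1), (-1, 1, -1), (-1, -1, 1), (-1, -1, -1),
]


def _shift(arr: np.ndarray, d) -> np.ndarray:
    """Shift a boolean grid by voxel step d, padding with False."""
    out = np.zeros_like(arr)
    src, dst = [], []
    for step in d:
        if step == 1:
            src.append(slice(1, None)); dst.append(slice(None, -1))
        elif step == -1:
            src.append(slice(None, -1)); dst.append(slice(1, None))
        else:
            src.append(slice(None)); dst.append(slice(None))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def find_cavity(receptor: ReceptorModel, spacing: float = 1.0,
                min_occlusion: int = 11, margin: float = 2.0,
                probe_radius: float = PROBE_RADIUS,
                min_volume: float = 12.0) -> CavityResult:
    """Grid-based cavity detection.

    Free grid points occluded by receptor beads in >= ``min_occlusion`` of 14
    scan directions are buried; the largest connected buried component is
    returned with its point count times the voxel volume and its centroid.
    Components smaller than ``min_volume`` (A^3; default roughly one solvent
    probe) are voxel-scale dimples, not cavities, and are discarded.
    """
    if receptor.n_beads == 0:
        raise ValueError("empty receptor")
    lo = receptor.positions.min(axis=0) - receptor.radii.max() - margin
    hi = receptor.positions.max(axis=0) + receptor.radii.max() + margin
    axes = [np.arange(lo[i], hi[i] + 0.5 * spacing, spacing) for i in range(3)]
    shape = tuple(len(ax) for ax in axes)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = cdist(grid, receptor.positions)
    occ = np.any(d < receptor.radii[None, :] + probe_radius, axis=1)
    occ = occ.reshape(shape)

    n_blocked = np.zeros(shape, dtype=np.int8)
    n_iter = max(shape)
    for direction in _DIRECTIONS:
        blocked = np.zeros(shape, dtype=bool)
        for _ in range(n_iter):
            new = _shift(occ | blocked, direction)
            if np.array_equal(new, blocked):
                break
            blocked = new
        n_blocked += blocked
    buried = (~occ) & (n_blocked >= min_occlusion)
    labels, n_comp = ndimage.label(buried)
    if n_comp == 0:
        return CavityResult(center=None, volume=0.0, n_points=0)
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    if counts[best - 1] * spacing ** 3 < min_volume:
        return CavityResult(center=None, volume=0.0, n_points=0)
    idx = np.argwhere(labels == best)
    coords = np.stack([axes[i][idx[:, i]] for i in range(3)], axis=1)
    return CavityResult(center=coords.mean(axis=0),
                        volume=float(len(idx) * spacing ** 3),
                        n_points=int(len(idx)), points=coords)
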