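"""Trajectory post-processing: Kabsch superposition and C-alpha RMSD analytics.

Operators reproduce the standard convergence/drift diagnostics of
peptide-receptor simulations: an RMSD time series after rigid superposition
on a fit selection (receptor C-alphas, so peptide motion is isolated), and a
per-residue profile of peptide displacement from the starting structure.

The per-residue profile is the RMS over time of each C-alpha displacement
from its reference position.  With that convention the residue-averaged
profile and the time-averaged trajectory RMSD agree exactly in quadrature:
mean_i profile_i^2 == mean_t RMSD_t^2 over the same selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "kabsch_superpose",
    "rmsd_timeseries",
    "per_residue_rmsd",
]


@dataclass
class Trajectory:
    """Time-ordered coordinate frames over a fixed bead/atom topology.

    frames : (T, N, 3) coordinates in A
    times  : (T,) strictly increasing, nominal ns
    groups : per-atom selection label, e.g. "receptor" / "peptide"
    resids : per-atom residue id
    names  : per-atom name ("CA" for backbone beads)
    """

    frames: np.ndarray
    times: np.ndarray
    groups: list
    resids: list
    names: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (T, N, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        n = self.frames.shape[1]
        for name in ("groups", "resids", "names"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def select(self, group: str | None = None, names=("CA",)) -> np.ndarray:
        """Boolean atom mask by group label and atom name."""
        mask = np.ones(self.frames.shape[1], dtype=bool)
        if group is not None:
            mask &= np.array([g == group for g in self.groups])
        if names is not None:
            mask &= np.array([nm in names for nm in self.names])
        return mask


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation (3,3), translation (3,), rmsd).  The transform maps a
    point x to rotation @ x + translation; a proper rotation (det +1) is
    enforced.  Fewer than 3 points or a collinear reference raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("point sets must share shape (N, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    m0, r0 = mobile - mc, reference - rc
    if np.linalg.matrix_rank(r0 * np.sqrt(w)[:, None], tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference points")
    h = (w[:, None] * m0).T @ r0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    diff = (rot @ mobile.T).T + trans - reference
    rmsd = float(np.sqrt((w * np.sum(diff * diff, axis=1)).sum()))
    return rot, trans, rmsd


def _superpose_frame(frame, ref, fit_mask):
    rot, trans, _ = kabsch_superpose(frame[fit_mask], ref[fit_mask])
    return (rot @ frame.T).T + trans


def rmsd_timeseries(traj: Trajectory, reference_frame: int = 0,
                    fit_group: str | None = "receptor",
                    measure_group: str | None = None) -> pd.DataFrame:
    """RMSD of each frame to the reference after fit-selection superposition.

    ``measure_group`` None measures over all C-alpha beads (the complex).
    Returns a DataFrame with columns time_ns, rmsd_A.
    """
    fit_mask = traj.select(group=fit_group)
    measure_mask = traj.select(group=measure_group)
    if not fit_mask.any():
        raise ValueError("empty fit selection")
    if not measure_mask.any():
        raise ValueError("empty measure selection")
    ref = traj.frames[reference_frame]
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        moved = _superpose_frame(traj.frames[t], ref, fit_mask)
        diff = moved[measure_mask] - ref[measure_mask]
        out[t] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    return pd.DataFrame({"time_ns": traj.times, "rmsd_A": out})


def per_residue_rmsd(traj: Trajectory, reference_frame: int = 0,
                     fit_group: str | None = "receptor",
                     measure_group: str = "peptide",
                     burn_in: int = 0) -> pd.DataFrame:
    """Per-residue RMS displacement from the reference position.

    Frames are superposed on the fit selection; each measured C-alpha's
    displacement from its reference position is averaged (RMS) over frames
    ``burn_in`` onward.  Returns columns residue, mean_rmsd_A.
    """
    fit_mask = traj.select(group=fit_group)
    measure_mask = traj.select(group=measure_group)
    if not fit_mask.any():
        raise ValueError("empty fit selection")
    if not measure_mask.any():
        raise ValueError("empty measure selection")
    if not (0 <= burn_in < traj.n_frames):
        raise ValueError("burn_in outside trajectory")
    ref = traj.frames[reference_frame]
    idx = np.flatnonzero(measure_mask)
    acc = np.zeros(len(idx))
    count = 0
    for t in range(burn_in, traj.n_frames):
        moved = _superpose_frame(traj.frames[t], ref, fit_mask)
        diff = moved[idx] - ref[idx]
        acc += np.sum(diff * diff, axis=1)
        count += 1
    rms = np.sqrt(acc / count)
    residues = [traj.resids[i] for i in idx]
    return pd.DataFrame({"residue": residues, "mean_rmsd_A": rms})
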