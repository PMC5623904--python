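"""End-to-end orchestration: scan -> fit -> dock -> trajectory analytics.

A run is driven by a flat key-value config (YAML mapping of scalars) and a
single global seed.  Per-stage seeds are derived by hashing the stage name
into the global seed so any stage can be re-run in isolation with the same
stream.  Outputs land in the run directory under fixed names, together with
a machine-readable manifest (config hash, seed, package version); summary
tables are byte-identical across reruns of the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding import fit_titration, fold_change
from .docking import DockingConfig, PeptideModel, Pose, run_hierarchy
from .seqscan import ScanConfig, scan_nols
from .structmodel import coarse_grain, read_pdb
from .synthetic_data import (PEPTIDES, TitrationDesign, ToyReceptorSpec,
                             TrajectorySpec, make_titration,
                             make_toy_receptor, make_toy_trajectory, presets)
from .trajanalysis import per_residue_rmsd, rmsd_timeseries

__all__ = ["RunConfig", "validate_config", "run_all", "demo_config",
           "stage_seed", "RunReport"]

_STAGES = ("scan", "fit", "dock", "traj")


def _version() -> str:
    import npmhub

    return npmhub.__version__


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys are rejected at validation."""

    outdir: str = "run"
    seed: int = 0
    stages: tuple = _STAGES
    # scan
    scan_window: int = 13
    scan_threshold: float = 0.8
    scan_smax: int = 6
    sequences_fasta: str | None = None   # default: built-in peptide panel
    # fit
    fit_presets: str = "all"             # "all" or comma-separated names
    fit_noise_cv: float = 0.02
    fit_points: int = 25
    fit_amax: float = 400.0
    fit_replicates: int = 3
    # dock
    receptor: str = "toy"                # "toy" or a PDB path
    dock_peptide: str = PEPTIDES["fbw7g"][0][1:]   # 13-mer docked peptide
    dock_parent_start: int = PEPTIDES["fbw7g"][1] + 1
    dock_radius: float = 20.0
    dock_runs: int = 10
    dock_steps: int = 300
    dock_max_combos: int = 25
    dock_templates: int = 100
    # traj
    traj_frames: int = 200
    traj_sigma_free: float = 3.0
    traj_sigma_anchor: float = 0.5

    @staticmethod
    def from_file(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        known = set(RunConfig.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw and isinstance(raw["stages"], str):
            raw["stages"] = tuple(s.strip() for s in raw["stages"].split(","))
        elif "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return RunConfig(**raw)

    def canonical(self) -> str:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return json.dumps(d, sort_keys=True)


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; returns a list of error strings."""
    errors = []
    for st in config.stages:
        if st not in _STAGES:
            errors.append(f"unknown stage {st!r}")
    if config.scan_window < 1:
        errors.append("scan_window must be >= 1")
    if not (0 < config.scan_threshold <= 1):
        errors.append("scan_threshold must be in (0, 1]")
    if config.scan_smax < 1:
        errors.append("scan_smax must be >= 1")
    if config.fit_noise_cv < 0:
        errors.append("fit_noise_cv must be >= 0")
    if config.fit_points < 5:
        errors.append("fit_points must be >= 5")
    if config.fit_replicates < 1:
        errors.append("fit_replicates must be >= 1")
    if config.dock_radius <= 0:
        errors.append("dock_radius must be positive")
    if config.dock_runs < 1:
        errors.append("dock_runs must be >= 1")
    if "dock" in config.stages:
        if config.receptor != "toy" and not Path(config.receptor).exists():
            errors.append(f"receptor file not found: {config.receptor}")
        if len(config.dock_peptide) < 3:
            errors.append("dock_peptide must have >= 3 residues")
    if config.sequences_fasta and not Path(config.sequences_fasta).exists():
        errors.append(f"sequences_fasta not found: {config.sequences_fasta}")
    if config.traj_frames < 2:
        errors.append("traj_frames must be >= 2")
    if config.traj_sigma_anchor > config.traj_sigma_free:
        errors.append("traj_sigma_anchor must be <= traj_sigma_free")
    return errors


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (global seed hashed with the stage name)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


def _log(msg: str) -> None:
    sys.stderr.write(f"[{time.strftime('%H:%M:%S')}] {msg}\n")


@dataclass
class RunReport:
    outdir: Path
    completed: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _load_sequences(config: RunConfig) -> dict:
    if config.sequences_fasta:
        from Bio import SeqIO

        return {rec.id: str(rec.seq)
                for rec in SeqIO.parse(config.sequences_fasta, "fasta")}
    return {name: seq for name, (seq, _) in PEPTIDES.items()}


def _run_scan(config: RunConfig, outdir: Path) -> pd.DataFrame:
    cfg = ScanConfig(window=config.scan_window,
                     threshold=config.scan_threshold, s_max=config.scan_smax)
    prof_rows, seg_rows = [], []
    for name, seq in _load_sequences(config).items():
        profile, segments = scan_nols(seq, cfg, sequence_id=name)
        for s, e, sc in zip(profile.starts, profile.ends, profile.scores):
            prof_rows.append({"id": name, "start": s, "end": e,
                              "score": round(sc, 6),
                              "truncated": profile.truncated})
        for seg in segments:
            # BED-like: 0-based half-open
            seg_rows.append({"id": name, "bed_start": seg.start - 1,
                             "bed_end": seg.end, "peak_score": seg.peak_score})
    prof = pd.DataFrame(prof_rows)
    prof.to_csv(outdir / "scan_profile.csv", index=False)
    pd.DataFrame(seg_rows).to_csv(outdir / "nols_segments.csv", index=False)
    return prof


def _run_fit(config: RunConfig, outdir: Path) -> pd.DataFrame:
    all_presets = presets()
    if config.fit_presets == "all":
        from .synthetic_data import canonical_preset_names

        names = canonical_preset_names()
    else:
        names = [s.strip() for s in config.fit_presets.split(",")]
    seed0 = stage_seed(config.seed, "fit")
    results = {}
    rows = []
    for i, name in enumerate(sorted(set(names))):
        preset = all_presets[name]
        design = TitrationDesign.linear(
            a_max=config.fit_amax, n_points=config.fit_points,
            replicates=config.fit_replicates, noise_cv=config.fit_noise_cv,
            seed=(seed0 + i) % (2 ** 31))
        fit = fit_titration(make_titration(preset, design))
        results[name] = fit
        rows.append({"complex": name, "peptide": preset.peptide,
                     "kd_true_uM": preset.kd, "kd_uM": round(fit.kd, 4),
                     "kd_sd_uM": round(fit.kd_sd, 4),
                     "converged": fit.converged})
    for row in rows:
        pep = all_presets[row["complex"]].peptide
        wt_name = next((n for n in results
                        if n.startswith("wt_")
                        and all_presets[n].peptide == pep), None)
        if wt_name and results[row["complex"]].converged:
            fc = fold_change(results[row["complex"]], results[wt_name])
            row["fold_vs_wt"] = round(fc.ratio, 3)
            row["fold_1sig"] = fc.one_sig_fig
        else:
            row["fold_vs_wt"] = float("nan")
            row["fold_1sig"] = float("nan")
    df = pd.DataFrame(rows).sort_values("complex").reset_index(drop=True)
    df.to_csv(outdir / "fit_summary.csv", index=False)
    return df


def _get_receptor(config: RunConfig):
    if config.receptor == "toy":
        return make_toy_receptor(ToyReceptorSpec())
    return coarse_grain(read_pdb(config.receptor))


def _run_dock(config: RunConfig, outdir: Path) -> pd.DataFrame:
    receptor = _get_receptor(config)
    dcfg = DockingConfig(radius=config.dock_radius, runs=config.dock_runs,
                         anneal_steps=config.dock_steps,
                         template_anneal_steps=min(150, config.dock_steps),
                         max_combos=config.dock_max_combos,
                         full_template_count=config.dock_templates,
                         seed=stage_seed(config.seed, "dock"))
    result = run_hierarchy(receptor, config.dock_peptide, dcfg,
                           parent_start=config.dock_parent_start)
    pose_rows = []
    for rank, pose in enumerate(result.ranked_poses, start=1):
        pose_rows.append({
            "rank": rank, "stage": pose.provenance.get("stage", ""),
            "electrostatic": round(pose.energy.electrostatic, 4),
            "steric": round(pose.energy.steric, 4),
            "total": round(pose.total_energy, 4)})
    poses_df = pd.DataFrame(pose_rows)
    poses_df.to_csv(outdir / "dock_poses.csv", index=False)
    sb_rows = [{"receptor_residue": b.receptor_residue,
                "peptide_residue": b.peptide_residue,
                "distance_A": round(b.distance, 3)}
               for b in result.salt_bridges]
    pd.DataFrame(sb_rows,
                 columns=["receptor_residue", "peptide_residue",
                          "distance_A"]).to_csv(
        outdir / "salt_bridges.csv", index=False)
    return poses_df


def _run_traj(config: RunConfig, outdir: Path) -> pd.DataFrame:
    receptor = _get_receptor(config)
    model = PeptideModel(config.dock_peptide, config.dock_parent_start)
    center = np.asarray(receptor.metadata.get("planted_center", (0, 0, 0)),
                        dtype=float)
    dofs = np.zeros(model.n_dof)
    dofs[:3] = center - model.reference.mean(axis=0)
    from .docking import EnergyBreakdown

    start = Pose(model=model, dofs=dofs, coords=model.coordinates(dofs),
                 energy=EnergyBreakdown(0.0, 0.0),
                 provenance={"stage": "start"})
    spec = TrajectorySpec(n_frames=config.traj_frames,
                          sigma_free=config.traj_sigma_free,
                          sigma_anchor=config.traj_sigma_anchor,
                          seed=stage_seed(config.seed, "traj"))
    traj = make_toy_trajectory(start, spec, receptor=receptor)
    ts = rmsd_timeseries(traj, fit_group="receptor", measure_group=None)
    ts.to_csv(outdir / "traj_rmsd.csv", index=False)
    prof = per_residue_rmsd(traj, fit_group="receptor",
                            measure_group="peptide")
    prof.to_csv(outdir / "per_residue_rmsd.csv", index=False)
    return prof


def run_all(config: RunConfig) -> RunReport:
    """Execute requested stages in order; fail per-stage, not globally."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=outdir)
    runners = {"scan": _run_scan, "fit": _run_fit, "dock": _run_dock,
               "traj": _run_traj}
    for st in config.stages:
        _log(f"stage {st} starting")
        try:
            report.summaries[st] = runners[st](config, outdir)
            report.completed.append(st)
            _log(f"stage {st} done")
        except Exception as exc:  # partial bundle on stage failure
            report.errors[st] = f"{type(exc).__name__}: {exc}"
            _log(f"stage {st} FAILED: {exc}")
    manifest = {
        "config_hash": hashlib.sha256(
            config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {st: stage_seed(config.seed, st)
                        for st in config.stages},
        "version": _version(),
        "stages_completed": report.completed,
        "errors": report.errors,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return report


def demo_config(outdir: str = "run_demo", seed: int = 0) -> RunConfig:
    """Fixtures-only demo: every stage on synthetic inputs, desk-scale."""
    return RunConfig(outdir=outdir, seed=seed,
                     dock_runs=3, dock_steps=80, dock_max_combos=4,
                     dock_templates=10, traj_frames=60)
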