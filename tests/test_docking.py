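"""Hierarchical coarse-grained docking: fragments, scoring, search,
clustering, templates, minimization, salt bridges."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist

from npmhub.docking import (DockingConfig, PeptideModel, Pose, PoseSet,
                            Template, cluster_poses, dock_fragment,
                            enumerate_fragments, minimize_pose, pose_rmsd,
                            run_hierarchy, salt_bridges, score_pose,
                            template_dock)
from npmhub.structmodel import ReceptorModel
from conftest import make_pose


def bead_receptor(positions, charges, radius=1.5, resnames=None):
    n = len(positions)
    return ReceptorModel(np.asarray(positions, float),
                         np.asarray(charges, float), np.full(n, radius),
                         list(range(1, n + 1)), ["A"] * n,
                         ["sidechain"] * n,
                         resnames or ["GLU" if q < 0 else "LYS" if q > 0
                                      else "ALA" for q in charges])


class TestFragments:
    def test_thirteen_mer_tripeptides(self):
        frags = enumerate_fragments("PFCRRRMKRKLDH", 3)
        assert len(frags) == 11
        assert frags[0].sequence == "PFC" and frags[0].start == 1
        assert frags[-1].sequence == "LDH" and frags[-1].start == 11

    def test_single_fragment_when_k_equals_length(self):
        frags = enumerate_fragments("KRK", 3)
        assert len(frags) == 1

    def test_hexamers_of_thirteen_mer(self):
        assert len(enumerate_fragments("PFCRRRMKRKLDH", 6)) == 8

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            enumerate_fragments("KR", 3)


class TestScore:
    def test_screened_coulomb_pair_value(self):
        # +1/-1 at 5 A with negligible steric: -332/(4*25) = -3.32 kcal/mol
        rec = bead_receptor([[0, 0, 0]], [-1], radius=0.1)
        coords = np.array([[5.0, 0, 0]])
        e = score_pose(rec, coords, np.array([1.0]), np.array([0.1]),
                       DockingConfig())
        assert e.electrostatic == pytest.approx(-3.32)
        assert e.steric < 1e-6

    def test_cutoff_beyond_40A(self):
        rec = bead_receptor([[0, 0, 0]], [-1])
        e = score_pose(rec, np.array([[41.0, 0, 0]]), np.array([1.0]),
                       np.array([1.0]), DockingConfig())
        assert e.electrostatic == 0.0

    def test_symmetric_under_global_charge_swap(self):
        rec_m = bead_receptor([[0, 0, 0]], [-1])
        rec_p = bead_receptor([[0, 0, 0]], [+1])
        c = np.array([[4.0, 0, 0]])
        em = score_pose(rec_m, c, np.array([1.0]), np.array([1.0]),
                        DockingConfig())
        ep = score_pose(rec_p, c, np.array([-1.0]), np.array([1.0]),
                        DockingConfig())
        assert em.electrostatic == pytest.approx(ep.electrostatic)

    def test_coincident_beads_capped_and_flagged(self):
        rec = bead_receptor([[0, 0, 0]], [-1])
        e = score_pose(rec, np.array([[0.0, 0, 0]]), np.array([1.0]),
                       np.array([1.0]), DockingConfig())
        assert e.capped and np.isfinite(e.total)

    def test_invariant_under_joint_rigid_motion(self, toy_receptor):
        model = PeptideModel("KRK")
        dofs = np.zeros(model.n_dof)
        dofs[:3] = (2.0, 1.0, -1.0)
        coords = model.coordinates(dofs)
        cfg = DockingConfig()
        base = score_pose(toy_receptor, coords, model.charges, model.radii,
                          cfg)
        ang = 1.2
        rot = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0],
                        [-np.sin(ang), 0, np.cos(ang)]])
        shift = np.array([5.0, -3.0, 8.0])
        moved_rec = ReceptorModel(
            toy_receptor.positions @ rot.T + shift, toy_receptor.charges,
            toy_receptor.radii, toy_receptor.resids, toy_receptor.chains,
            toy_receptor.roles, toy_receptor.resnames)
        moved = score_pose(moved_rec, coords @ rot.T + shift, model.charges,
                           model.radii, cfg)
        assert moved.total == pytest.approx(base.total, abs=1e-9)


class TestPeptideModel:
    def test_fixed_virtual_bond_under_any_dofs(self):
        model = PeptideModel("PFCRRRMKRKLDH")
        rng = np.random.default_rng(0)
        for _ in range(5):
            dofs = rng.normal(size=model.n_dof)
            ca = model.coordinates(dofs)[0::2]
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            assert np.allclose(d, 3.8, atol=1e-9)

    def test_charges_follow_residue_rules(self):
        model = PeptideModel("KRDEA")
        assert list(model.charges[1::2]) == [1, 1, -1, -1, 0]
        assert np.all(model.charges[0::2] == 0)


class TestDockFragment:
    def test_basic_tripeptide_finds_acidic_pore(self, toy_receptor):
        acid = toy_receptor.positions[toy_receptor.charges < 0]
        poses = dock_fragment(toy_receptor, PeptideModel("RRR"),
                              DockingConfig(seed=0), stage="t")
        good = sum(1 for p in poses
                   if (cdist(p.coords[1::2], acid).min(axis=1) < 4.0).sum()
                   >= 2)
        assert good >= 9

    def test_neutral_tripeptide_finds_nothing(self, toy_receptor):
        poses = dock_fragment(toy_receptor, PeptideModel("AAA"),
                              DockingConfig(seed=0), stage="t")
        for p in poses:
            assert abs(p.total_energy) < 1.0

    def test_same_seed_is_bit_identical(self, toy_receptor):
        cfg = DockingConfig(seed=3, runs=3, anneal_steps=60)
        p1 = dock_fragment(toy_receptor, PeptideModel("KRK"), cfg, stage="t")
        p2 = dock_fragment(toy_receptor, PeptideModel("KRK"), cfg, stage="t")
        for a, b in zip(p1, p2):
            assert np.array_equal(a.coords, b.coords)
            assert a.total_energy == b.total_energy

    def test_zero_runs_rejected(self, toy_receptor):
        with pytest.raises(ValueError):
            DockingConfig(runs=0)


class TestClustering:
    def test_identical_poses_collapse_to_one(self):
        pose = make_pose("KRK")
        poses = PoseSet()
        for i in range(5):
            p = make_pose("KRK")
            p.provenance["id"] = i
            poses.append(p)
        reps = cluster_poses(poses, cutoff=1.2)
        assert len(reps) == 1

    def test_distant_poses_stay_separate(self):
        p1 = make_pose("KRK")
        p2 = make_pose("KRK", dofs=[10.0, 0, 0, 0, 0, 0, 0, 0])
        assert len(cluster_poses([p1, p2], cutoff=1.2)) == 2

    def test_cluster_partition_properties(self):
        rng = np.random.default_rng(1)
        poses = PoseSet()
        for i in range(40):
            dofs = np.zeros(8)
            dofs[:3] = rng.normal(scale=1.5, size=3)
            p = make_pose("KRK", dofs=dofs)
            p.energy.electrostatic = float(rng.normal())
            p.provenance["id"] = i
            poses.append(p)
        cutoff = 1.2
        reps = cluster_poses(poses, cutoff)
        # representatives pairwise at least the cutoff apart
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert pose_rmsd(reps[i], reps[j]) >= cutoff
        # every pose within the cutoff of at least one representative
        # (cross-checked against brute-force all-pairs RMSD)
        for p in poses:
            assert min(pose_rmsd(p, r) for r in reps) < cutoff


class TestTemplateDock:
    def test_stiff_spring_limit_reproduces_template(self, toy_receptor):
        model = PeptideModel("KRKRKR")
        rng = np.random.default_rng(4)
        dofs = np.zeros(model.n_dof)
        dofs[:3] = (0.0, 0.0, 9.0)
        dofs[6:] = rng.uniform(-1, 1, size=model.n_torsions)
        target = model.coordinates(dofs)
        template = Template(residue_indices=np.arange(6), coords=target)
        cfg = DockingConfig(seed=0, k_bias=1e4, template_anneal_steps=120)
        poses = template_dock(toy_receptor, model, [template], cfg,
                              stage="hx")
        assert len(poses) == 1
        assert np.abs(poses[0].coords - target).max() < 0.5

    def test_bias_excluded_from_reported_energy(self, toy_receptor):
        model = PeptideModel("KRK")
        template = Template(residue_indices=np.arange(3),
                            coords=model.coordinates(np.zeros(8)) +
                            np.array([0, 0, 9.0]))
        cfg = DockingConfig(seed=1, k_bias=50.0, template_anneal_steps=60)
        pose = template_dock(toy_receptor, model, [template], cfg,
                             stage="hx")[0]
        recomputed = score_pose(toy_receptor, pose.coords, model.charges,
                                model.radii, cfg)
        assert pose.total_energy == pytest.approx(recomputed.total)

    def test_template_residue_mismatch_rejected(self, toy_receptor):
        model = PeptideModel("KRK")
        bad = Template(residue_indices=np.array([5]), coords=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="outside"):
            template_dock(toy_receptor, model, [bad], DockingConfig(seed=0),
                          stage="hx")

    def test_hexamer_guided_by_planted_tripeptide_template(self,
                                                           toy_receptor):
        # mapped residues stay near a realizable planted template
        model = PeptideModel("RRRAAA")
        tri = PeptideModel("RRR")
        dofs = np.zeros(tri.n_dof)
        dofs[:3] = (0.0, 0.0, 2.0)
        tricoords = tri.coordinates(dofs)
        template = Template(residue_indices=np.arange(3), coords=tricoords)
        cfg = DockingConfig(seed=2, k_bias=20.0, template_anneal_steps=150)
        pose = template_dock(toy_receptor, model, [template], cfg,
                             stage="hx").sorted_by_energy()[0]
        overlap = pose.coords[:6]
        assert np.abs(overlap - tricoords).max() < 2.0


class TestMinimize:
    def _single_bead_system(self):
        rec = bead_receptor([[0.0, 0, 0]], [-1], radius=1.7)
        return rec, PeptideModel("R"), DockingConfig(center=(0, 0, 0))

    def _radial_oracle(self):
        # 1-D energy along the optimal (collinear) arrangement:
        # SC bead at distance d, CA bead 2.5 A further out
        def energy(d):
            return (-332.0 / (4 * d * d) + ((1.7 + 2.3) / d) ** 8
                    + ((1.7 + 2.0) / (d + 2.5)) ** 8)

        res = minimize_scalar(energy, bounds=(2.0, 8.0), method="bounded",
                              options={"xatol": 1e-10})
        return res.x

    def test_perturbed_pose_returns_to_basin(self):
        rec, model, cfg = self._single_bead_system()
        d_star = self._radial_oracle()
        dofs = np.zeros(model.n_dof)
        # SC sits at (d*+0.5, 0, 0); reference puts SC 2.5 A from CA in +y
        dofs[:3] = (d_star + 0.5, -2.5, 0.0)
        pose = make_pose("R", dofs=dofs)
        pose.energy = score_pose(rec, pose.coords, model.charges,
                                 model.radii, cfg)
        out = minimize_pose(rec, pose, cfg)
        d_sc = np.linalg.norm(out.coords[1])
        assert abs(d_sc - d_star) < 0.05

    def test_pose_at_minimum_stays_put(self):
        rec, model, cfg = self._single_bead_system()
        dofs = np.zeros(model.n_dof)
        dofs[:3] = (4.0, -2.0, 0.5)
        pose = make_pose("R", dofs=dofs)
        once = minimize_pose(rec, pose, cfg)
        twice = minimize_pose(rec, once, cfg)
        assert np.abs(twice.coords - once.coords).max() < 1e-6

    def test_energy_trace_monotone_non_increasing(self, toy_receptor):
        cfg = DockingConfig(seed=5, anneal_steps=80)
        pose = dock_fragment(toy_receptor, PeptideModel("KRK"), cfg,
                             stage="t").sorted_by_energy()[0]
        out = minimize_pose(toy_receptor, pose, cfg)
        trace = out.provenance["energy_trace"]
        assert all(trace[i + 1] <= trace[i] + 1e-9
                   for i in range(len(trace) - 1))
        assert out.total_energy <= pose.total_energy + 1e-9


class TestSaltBridges:
    def test_within_cutoff_reported_beyond_absent(self):
        rec = bead_receptor([[0, 0, 0], [20, 0, 0]], [-1, -1],
                            resnames=["ASP", "GLU"])
        # reference puts the R sidechain bead 2.5 A above its CA in +z
        pose = make_pose("R", dofs=[3.5, 0, -2.5, 0, 0, 0], parent_start=47)
        bridges = salt_bridges(rec, pose, cutoff=4.0)
        assert len(bridges) == 1
        assert bridges[0].peptide_residue == "R47"
        assert bridges[0].distance == pytest.approx(3.5)
        far = make_pose("R", dofs=[4.5, 0, -2.5, 0, 0, 0])
        assert salt_bridges(rec, far, cutoff=4.0) == []

    def test_one_acidic_bead_bridging_two_basics(self):
        rec = bead_receptor([[0, 0, 0]], [-1], resnames=["GLU"])
        # place K and R side chains symmetrically within 4 A of the bead
        pose = make_pose("KAR", parent_start=51)
        mid = 0.5 * (pose.coords[1] + pose.coords[5])
        pose.coords = pose.coords - mid
        sep = np.linalg.norm(pose.coords[5] - pose.coords[1])
        assert sep < 8.0            # both side chains end up under 4 A away
        bridges = salt_bridges(rec, pose, cutoff=4.0)
        assert {b.peptide_residue for b in bridges} == {"K51", "R53"}


class TestHierarchy:
    def test_short_peptide_stops_after_stage_one(self, toy_receptor,
                                                  small_dock_config):
        res = run_hierarchy(toy_receptor, "KRKA", small_dock_config)
        assert res.final_pose is None
        assert len(res.tripeptide_representatives) == 2
        assert any("tripeptide" in n for n in res.notices)

    def test_hexamer_peptide_runs_all_stages(self, toy_receptor,
                                             small_dock_config):
        res = run_hierarchy(toy_receptor, "KRKRKR", small_dock_config)
        assert res.final_pose is not None
        assert res.final_pose.model.n_residues == 6
        assert res.hexamer_pose_count > 0

    def test_full_protocol_contacts_planted_pore(self, toy_receptor):
        cfg = DockingConfig(seed=11)
        res = run_hierarchy(toy_receptor, "PFCRRRMKRKLDH", cfg,
                            parent_start=44)
        assert len(res.salt_bridges) >= 4
        # peptide residue labels use parent numbering (44..56)
        nums = {int(b.peptide_residue[1:]) for b in res.salt_bridges}
        assert nums <= set(range(44, 57))
        # window-restricted top pose stays near a guiding hexamer template
        top = res.ranked_poses[0]
        best = min(
            float(np.sqrt(np.mean(np.sum(
                (top.coords[t.bead_indices(top.model)] - t.coords) ** 2,
                axis=1))))
            for t in res.full_templates)
        assert best < 3.0
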