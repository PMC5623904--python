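"""PDB I/O, coarse-graining, surface potential, patch and cavity detection."""

import numpy as np
import pytest

from npmhub.structmodel import (Atom, GridSpec, ReceptorModel, acidic_patch,
                                coarse_grain, find_cavity, potential_at,
                                read_pdb, surface_potential, write_pdb)
from npmhub.synthetic_data import (ToyReceptorSpec, make_toy_receptor,
                                   write_receptor_pdb)

TWO_RESIDUE_PDB = """\
ATOM      1  N   GLU A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLU A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLU A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLU A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB  GLU A   1       2.000  -0.800  -1.200  1.00  0.00           C
ATOM      6  CG  GLU A   1       3.500  -0.900  -1.300  1.00  0.00           C
ATOM      7  CD  GLU A   1       4.000  -1.900  -2.300  1.00  0.00           C
ATOM      8  OE1 GLU A   1       3.300  -2.900  -2.500  1.00  0.00           O
ATOM      9  OE2 GLU A   1       5.100  -1.700  -2.900  1.00  0.00           O
ATOM     10  N   GLY A   2       3.300   1.500   0.100  1.00  0.00           N
ATOM     11  CA  GLY A   2       4.000   2.800   0.200  1.00  0.00           C
ATOM     12  C   GLY A   2       5.500   2.700   0.300  1.00  0.00           C
ATOM     13  O   GLY A   2       6.100   1.600   0.300  1.00  0.00           O
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "dipeptide.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


class TestReadPdb:
    def test_two_residue_fixture(self, two_residue_pdb):
        s = read_pdb(two_residue_pdb)
        assert s.n_models == 1
        atoms = s.atoms()
        assert len(atoms) == 13
        assert {(a.resname, a.resseq) for a in atoms} == {("GLU", 1),
                                                          ("GLY", 2)}

    def test_multi_model_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        base = [Atom("CA", "ALA", i + 1, "", "A", rng.normal(size=3) * 5)
                for i in range(4)]
        models = [[Atom(a.name, a.resname, a.resseq, a.icode, a.chain,
                        a.xyz + m) for a in base] for m in range(3)]
        path = tmp_path / "traj.pdb"
        write_pdb(path, models)
        s = read_pdb(path)
        assert s.n_models == 3
        for m in range(3):
            assert len(s.atoms(m)) == 4
            got = np.array([a.xyz for a in s.atoms(m)])
            want = np.array([a.xyz for a in models[m]])
            assert np.allclose(got, want, atol=1e-3)   # PDB prints 3 decimals

    def test_truncated_line_reports_line_number(self, tmp_path):
        bad = TWO_RESIDUE_PDB.splitlines()
        bad[4] = bad[4][:40]                           # cut inside the coords
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(bad) + "\n")
        with pytest.raises(ValueError, match="line 5"):
            read_pdb(path)

    def test_malformed_float_reports_line_number(self, tmp_path):
        bad = TWO_RESIDUE_PDB.splitlines()
        bad[1] = bad[1][:30] + "  xx.yyy" + bad[1][38:]
        path = tmp_path / "bad2.pdb"
        path.write_text("\n".join(bad) + "\n")
        with pytest.raises(ValueError, match="line 2"):
            read_pdb(path)


class TestCoarseGrain:
    def test_glu_sidechain_charge_and_gly_colocation(self, two_residue_pdb):
        model = coarse_grain(read_pdb(two_residue_pdb))
        assert model.n_beads == 4                       # 2 residues x 2 beads
        glu_sc = [i for i in range(4) if model.resnames[i] == "GLU"
                  and model.roles[i] == "sidechain"][0]
        assert model.charges[glu_sc] == -1
        gly = [i for i in range(4) if model.resnames[i] == "GLY"]
        assert np.allclose(model.positions[gly[0]], model.positions[gly[1]])

    def test_missing_ca_skipped_with_warning(self, tmp_path):
        lines = [ln for ln in TWO_RESIDUE_PDB.splitlines()
                 if not ("CA" in ln and "GLY" in ln)]
        path = tmp_path / "noca.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="no CA"):
            model = coarse_grain(read_pdb(path))
        assert model.n_beads == 2                       # only GLU survives

    def test_net_formal_charge_preserved(self, two_residue_pdb):
        model = coarse_grain(read_pdb(two_residue_pdb))
        assert model.total_charge == -1                 # one GLU

    def test_toy_receptor_pdb_roundtrip(self, tmp_path, toy_receptor):
        path = tmp_path / "toy.pdb"
        write_receptor_pdb(path, toy_receptor)
        s = read_pdb(path)
        assert len(s.atoms()) == toy_receptor.n_beads
        charges = [a.bfactor for a in s.atoms()]        # charge in B-factor
        assert sum(charges) == toy_receptor.total_charge


class TestPotential:
    def _single_bead(self, charge):
        return ReceptorModel(np.zeros((1, 3)), np.array([float(charge)]),
                             np.array([1.5]), [1], ["A"], ["sidechain"],
                             ["LYS" if charge > 0 else "GLU"])

    def test_single_positive_bead_everywhere_positive(self):
        pmap = surface_potential(self._single_bead(+1),
                                 GridSpec(half_extent=6, spacing=2.0))
        assert np.all(pmap.values > 0)

    def test_antisymmetric_under_charge_swap(self):
        plus = surface_potential(self._single_bead(+1),
                                 GridSpec(half_extent=6, spacing=2.0))
        minus = surface_potential(self._single_bead(-1),
                                  GridSpec(half_extent=6, spacing=2.0))
        assert np.allclose(plus.values, -minus.values)

    def test_rigid_motion_equivariance(self, toy_receptor):
        rng = np.random.default_rng(2)
        probes = rng.normal(size=(40, 3)) * 8.0
        base = potential_at(toy_receptor, probes)
        ang = 0.9
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        shift = np.array([3.0, -2.0, 5.0])
        moved = ReceptorModel(toy_receptor.positions @ rot.T + shift,
                              toy_receptor.charges, toy_receptor.radii,
                              toy_receptor.resids, toy_receptor.chains,
                              toy_receptor.roles, toy_receptor.resnames)
        assert np.allclose(potential_at(moved, probes @ rot.T + shift),
                           base, atol=1e-9)

    def test_pairwise_pair_value(self):
        # single -1 bead probed at 5 A: 332/(4*25) per unit probe charge
        val = potential_at(self._single_bead(-1), np.array([[5.0, 0, 0]]))
        assert val[0] == pytest.approx(-3.32)


class TestPatch:
    def test_toy_pentamer_patch_contains_all_acidic_residues(self,
                                                             toy_receptor):
        pmap = surface_potential(toy_receptor, GridSpec(half_extent=10.0))
        patch = acidic_patch(pmap, toy_receptor, quantile=0.05)
        acidic = {(toy_receptor.chains[i], toy_receptor.resids[i])
                  for i in range(toy_receptor.n_beads)
                  if toy_receptor.charges[i] < 0}
        got = {(c, r) for c, r, _ in patch.residues}
        assert acidic <= got
        assert np.linalg.norm(patch.centroid[:2]) < 3.0

    def test_no_negative_probes_gives_empty_result(self):
        rec = ReceptorModel(np.zeros((1, 3)), np.array([1.0]),
                            np.array([1.5]), [1], ["A"], ["sidechain"],
                            ["LYS"])
        pmap = surface_potential(rec, GridSpec(half_extent=5, spacing=2.5))
        patch = acidic_patch(pmap, rec)
        assert patch.residues == [] and patch.centroid is None


class TestCavity:
    def test_solid_slab_has_no_cavity(self):
        xs, ys = np.meshgrid(np.arange(5) * 4.0, np.arange(5) * 4.0)
        pos = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(25)])
        rec = ReceptorModel(pos, np.zeros(25), np.full(25, 2.0),
                            list(range(25)), ["A"] * 25, ["sidechain"] * 25,
                            ["ALA"] * 25)
        assert not find_cavity(rec).found

    def test_toy_pentamer_cavity_centered_on_pore(self, toy_receptor):
        cav = find_cavity(toy_receptor)
        assert cav.found
        assert np.linalg.norm(cav.center - np.zeros(3)) < 2.0

    def test_wider_pore_gives_larger_cavity(self):
        # scale the body with the pore so only the pore width changes
        small = make_toy_receptor(ToyReceptorSpec(ring_radius=4.0,
                                                  neutral_radius=9.0))
        large = make_toy_receptor(ToyReceptorSpec(ring_radius=6.0,
                                                  neutral_radius=11.0))
        assert find_cavity(large).volume > find_cavity(small).volume

    def test_invariant_under_rigid_motion(self, toy_receptor):
        base = find_cavity(toy_receptor)
        shift = np.array([7.3, -4.1, 2.9])
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])  # 90 deg
        moved = ReceptorModel(toy_receptor.positions @ rot.T + shift,
                              toy_receptor.charges, toy_receptor.radii,
                              toy_receptor.resids, toy_receptor.chains,
                              toy_receptor.roles, toy_receptor.resnames)
        cav = find_cavity(moved)
        assert cav.n_points == base.n_points
        # centroid matches up to the grid registration (half a voxel)
        assert np.allclose(cav.center, rot @ base.center + shift, atol=0.6)
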