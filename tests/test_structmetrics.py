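"""Trajectory I/O, Kabsch RMSD, RMSF, hydrogen bonds and contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import aptamelt as am
from aptamelt.structmetrics import Trajectory

from oracles import (
    brute_force_contacts,
    brute_force_hbonds,
    grid_search_rmsd,
    make_atoms,
    random_complex,
    rigid_transform,
    two_pass_rmsf,
)


def tiny_traj(coords, names=None, with_h=False):
    """A toy single-chain trajectory with generic heavy atoms."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[-2]
    names = names or [("C" + str(i), "C") for i in range(n)]
    spec = [(nm, el, "GLY", i + 1, "A") for i, (nm, el) in enumerate(names)]
    return Trajectory(coords=coords, atoms=make_atoms(spec))


class TestReadWriteFrames:
    def test_single_model_file(self, tmp_path):
        traj = random_complex(seed=0)
        path = tmp_path / "one.pdb"
        am.write_frames(traj, path)
        back = am.read_frames(path)
        assert back.n_frames == 1

    def test_five_models_identical_atom_tables(self, tmp_path):
        base = random_complex(seed=1)
        rng = np.random.default_rng(2)
        coords = np.array([base.coords[0] + 0.1 * m * rng.normal(size=base.coords[0].shape) for m in range(5)])
        traj = Trajectory(coords=coords, atoms=base.atoms)
        path = tmp_path / "five.pdb"
        am.write_frames(traj, path)
        back = am.read_frames(path)
        assert back.n_frames == 5
        assert list(back.atoms["name"]) == list(base.atoms["name"])
        assert list(back.atoms["resnum"]) == list(base.atoms["resnum"])

    def test_roundtrip_coordinates_to_pdb_precision(self, tmp_path):
        traj = random_complex(seed=3)
        path = tmp_path / "rt.pdb"
        am.write_frames(traj, path)
        back = am.read_frames(path)
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)

    def test_malformed_atom_record_raises(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "MODEL     1\n"
            "ATOM      1  N   GLY A   1      bad_coord   2.000   3.000  1.00  0.00           N\n"
            "ENDMDL\nEND\n"
        )
        with pytest.raises(ValueError, match="malformed"):
            am.read_frames(path)

    def test_inconsistent_atom_counts_raise(self, tmp_path):
        traj = random_complex(seed=4)
        path = tmp_path / "in.pdb"
        am.write_frames(Trajectory(np.repeat(traj.coords, 2, axis=0), traj.atoms), path)
        text = path.read_text().splitlines(keepends=True)
        # drop one ATOM line from the second model
        second_model = [i for i, ln in enumerate(text) if ln.startswith("MODEL")][1]
        del text[second_model + 1]
        path.write_text("".join(text))
        with pytest.raises(ValueError, match="atoms"):
            am.read_frames(path)


class TestKabschRmsd:
    def test_identical_frames(self):
        a = np.random.default_rng(0).normal(size=(10, 3))
        assert am.kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        a = np.random.default_rng(1).normal(size=(12, 3)) * 5
        b = rigid_transform(a, seed=9)
        assert am.kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, rng):
        a = rng.normal(size=(8, 3)) * 3
        b = a + rng.normal(size=(8, 3))
        assert am.kabsch_rmsd(a, b) == pytest.approx(am.kabsch_rmsd(b, a), abs=1e-9)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            am.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_four_atom_pair_matches_grid_search_oracle(self, rng):
        a = rng.normal(size=(4, 3)) * 2
        b = a + rng.normal(size=(4, 3)) * 0.8
        ours = am.kabsch_rmsd(a, b)
        oracle = grid_search_rmsd(a, b)
        assert ours == pytest.approx(oracle, abs=0.01)
        assert ours <= oracle + 1e-9  # Kabsch is the true minimum

    def test_matches_scipy_align_vectors(self, rng):
        a = rng.normal(size=(15, 3)) * 4
        b = a + rng.normal(size=(15, 3)) * 0.5
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        _rot, rssd = Rotation.align_vectors(bc, ac)
        assert am.kabsch_rmsd(a, b) == pytest.approx(rssd / np.sqrt(len(a)), rel=1e-6)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        frame = np.random.default_rng(0).normal(size=(9, 3))
        traj = tiny_traj(np.repeat(frame[None], 4, axis=0))
        out = am.rmsf(traj)
        assert np.allclose(out["rmsf_A"], 0.0, atol=1e-12)

    def test_oscillating_atom_closed_form(self):
        # one atom moving +/-d along x in otherwise static frames: RMSF = d
        frame = np.arange(27, dtype=float).reshape(9, 3)
        d = 0.7
        plus, minus = frame.copy(), frame.copy()
        plus[4, 0] += d
        minus[4, 0] -= d
        traj = tiny_traj(np.array([plus, minus, plus, minus]))
        out = am.rmsf(traj, superpose_frames=False)
        vals = out.sort_values("resnum")["rmsf_A"].to_numpy()
        assert vals[4] == pytest.approx(d, rel=1e-12)
        others = np.delete(vals, 4)
        assert np.allclose(others, 0.0, atol=1e-12)

    def test_matches_two_pass_loop_oracle(self, rng):
        frames = np.cumsum(rng.normal(scale=0.1, size=(6, 7, 3)), axis=0) + rng.normal(size=(1, 7, 3))
        traj = tiny_traj(frames)
        out = am.rmsf(traj, superpose_frames=False).sort_values("resnum")["rmsf_A"].to_numpy()
        np.testing.assert_allclose(out, two_pass_rmsf(frames), rtol=1e-10)

    def test_single_frame_rejected(self):
        traj = tiny_traj(np.zeros((1, 5, 3)))
        with pytest.raises(ValueError):
            am.rmsf(traj)

    def test_nonnegative_and_zero_iff_static(self, rng):
        frames = rng.normal(size=(5, 8, 3))
        traj = tiny_traj(frames)
        out = am.rmsf(traj)
        assert (out["rmsf_A"] >= 0).all()
        assert (out["rmsf_A"] > 0).any()


class TestDetectHbonds:
    def test_textbook_colinear_nho(self):
        # N-H...O colinear, N-O distance 2.9 A
        spec = [("N", "N", "GLY", 1, "A"), ("H", "H", "GLY", 1, "A"), ("O", "O", "HOH", 2, "A")]
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        bonds = am.detect_hbonds(coords, make_atoms(spec))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].angle == pytest.approx(180.0)

    def test_distance_beyond_cutoff_not_detected(self):
        spec = [("N", "N", "GLY", 1, "A"), ("H", "H", "GLY", 1, "A"), ("O", "O", "HOH", 2, "A")]
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [4.2, 0, 0]])
        assert am.detect_hbonds(coords, make_atoms(spec)) == []

    def test_bent_geometry_fails_angle_cutoff(self):
        spec = [("N", "N", "GLY", 1, "A"), ("H", "H", "GLY", 1, "A"), ("O", "O", "HOH", 2, "A")]
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 2.5, 0]])  # ~90 deg at H
        assert am.detect_hbonds(coords, make_atoms(spec)) == []

    def test_heavy_atom_only_mode_skips_angle(self):
        spec = [("N", "N", "GLY", 1, "A"), ("O", "O", "HOH", 2, "A")]
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        bonds = am.detect_hbonds(coords, make_atoms(spec))
        assert {(b.donor, b.acceptor) for b in bonds} == {(0, 1), (1, 0)}

    @pytest.mark.parametrize("with_h", [True, False])
    def test_matches_brute_force_oracle_over_seeds(self, with_h):
        for seed in range(100):
            traj = random_complex(seed=seed, with_h=with_h)
            ours = {
                (b.donor, b.acceptor)
                for b in am.detect_hbonds(traj.coords[0], traj.atoms)
            }
            oracle = brute_force_hbonds(traj.coords[0], traj.atoms, 3.5, 120.0)
            assert ours == oracle

    def test_invariant_under_rigid_motion(self):
        traj = random_complex(seed=11)
        before = {(b.donor, b.acceptor) for b in am.detect_hbonds(traj.coords[0], traj.atoms)}
        moved = rigid_transform(traj.coords[0], seed=5)
        after = {(b.donor, b.acceptor) for b in am.detect_hbonds(moved, traj.atoms)}
        assert before == after


class TestHbondStatistics:
    def _pattern_traj(self, present_frames, total=10):
        """Donor/acceptor pair present (2.9 A) or broken (6 A) per frame."""
        spec = [("N", "N", "GLY", 1, "A"), ("H", "H", "GLY", 1, "A"), ("O", "O", "HOH", 2, "A")]
        frames = []
        for m in range(total):
            d = 2.9 if m in present_frames else 6.0
            frames.append([[0.0, 0, 0], [1.0, 0, 0], [d, 0, 0]])
        return Trajectory(coords=np.array(frames), atoms=make_atoms(spec))

    def test_always_present_occupancy_one(self):
        stats = am.hbond_statistics(self._pattern_traj(set(range(10))))
        assert len(stats) == 1
        assert stats["occupancy"].iloc[0] == 1.0

    def test_half_present_occupancy_half(self):
        stats = am.hbond_statistics(self._pattern_traj({0, 2, 4, 6, 8}))
        assert stats["occupancy"].iloc[0] == 0.5
        assert stats["mean_distance_A"].iloc[0] == pytest.approx(2.9)

    def test_scripted_pattern_matches_frame_recount(self, rng):
        base = random_complex(seed=21)
        frames = np.array([base.coords[0] + rng.normal(scale=0.4, size=base.coords[0].shape) for _ in range(6)])
        traj = Trajectory(coords=frames, atoms=base.atoms)
        stats = am.hbond_statistics(traj)
        # independent recount, frame by frame, with the brute-force detector
        counts, dists = {}, {}
        for m in range(6):
            for pair in brute_force_hbonds(frames[m], base.atoms, 3.5, 120.0):
                counts[pair] = counts.get(pair, 0) + 1
                d = np.linalg.norm(frames[m][pair[0]] - frames[m][pair[1]])
                dists.setdefault(pair, []).append(d)
        assert len(stats) == len(counts)
        for _, row in stats.iterrows():
            pair = (row["donor_index"], row["acceptor_index"])
            assert row["occupancy"] == pytest.approx(counts[pair] / 6)
            assert row["mean_distance_A"] == pytest.approx(np.mean(dists[pair]))
        assert list(stats["occupancy"]) == sorted(stats["occupancy"], reverse=True)


class TestBindingSites:
    def test_single_close_pair(self):
        spec = [("CA", "C", "GLY", 1, "A"), ("P", "P", "DT", 1, "B")]
        traj = Trajectory(coords=np.array([[[0.0, 0, 0], [3.0, 0, 0]]]), atoms=make_atoms(spec))
        df = am.binding_sites(traj, traj.select_chain("A"), traj.select_chain("B"))
        assert len(df) == 1

    def test_far_apart_no_pairs(self):
        spec = [("CA", "C", "GLY", 1, "A"), ("P", "P", "DT", 1, "B")]
        traj = Trajectory(coords=np.array([[[0.0, 0, 0], [30.0, 0, 0]]]), atoms=make_atoms(spec))
        df = am.binding_sites(traj, traj.select_chain("A"), traj.select_chain("B"))
        assert len(df) == 0

    def test_overlapping_selections_rejected(self):
        traj = random_complex(seed=0)
        sel = traj.select_chain("A")
        with pytest.raises(ValueError):
            am.binding_sites(traj, sel, sel)

    def test_matches_brute_force_oracle_over_seeds(self):
        for seed in range(100):
            traj = random_complex(seed=seed)
            sel_a, sel_b = traj.select_chain("A"), traj.select_chain("B")
            df = am.binding_sites(traj, sel_a, sel_b)
            ours = {
                (("A", ra), ("B", rb))
                for ra, rb in zip(df["resnum_a"], df["resnum_b"])
            }
            oracle = brute_force_contacts(traj.coords[0], traj.atoms, sel_a, sel_b, 4.0)
            assert ours == oracle

    def test_occupancy_threshold_over_trajectory(self):
        spec = [("CA", "C", "GLY", 1, "A"), ("P", "P", "DT", 1, "B")]
        close = [[0.0, 0, 0], [3.0, 0, 0]]
        far = [[0.0, 0, 0], [30.0, 0, 0]]
        traj = Trajectory(coords=np.array([close, close, close, far]), atoms=make_atoms(spec))
        present = am.binding_sites(traj, [0], [1], occupancy_threshold=0.5)
        assert len(present) == 1
        assert present["occupancy"].iloc[0] == pytest.approx(0.75)
        absent = am.binding_sites(traj, [0], [1], occupancy_threshold=0.9)
        assert len(absent) == 0
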