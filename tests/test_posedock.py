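import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from offpipe import posedock as pdk, structio as st
from offpipe.errors import NormalizationError


@pytest.fixture()
def pose(small_complex):
    return pdk.transfer_pose(small_complex.ligand, np.eye(3), np.zeros(3))


class TestTransferPose:
    def test_identity_transform_keeps_coordinates(self, small_complex):
        p = pdk.transfer_pose(small_complex.ligand, np.eye(3), np.zeros(3))
        np.testing.assert_array_equal(p.coords, small_complex.ligand.coords)

    def test_translation_moves_centroid_exactly(self, small_complex):
        t = np.array([1.0, 0.0, 0.0])
        p = pdk.transfer_pose(small_complex.ligand, np.eye(3), t)
        np.testing.assert_allclose(
            p.coords.mean(axis=0),
            small_complex.ligand.coords.mean(axis=0) + t,
            atol=1e-12,
        )

    def test_rotation_preserves_intra_ligand_distances(self, small_complex, rng):
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        p = pdk.transfer_pose(small_complex.ligand, R, rng.normal(size=3))
        d0 = np.linalg.norm(
            small_complex.ligand.coords[:, None] - small_complex.ligand.coords[None],
            axis=2,
        )
        d1 = np.linalg.norm(p.coords[:, None] - p.coords[None], axis=2)
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_improper_rotation_rejected(self, small_complex):
        mirror = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            pdk.transfer_pose(small_complex.ligand, mirror, np.zeros(3))


class TestClashes:
    def test_overlapping_atom_counts_as_severe(self, small_complex):
        near = small_complex.receptor.coords[0] + np.array([0.8, 0.0, 0.0])
        p = pdk.Pose(list(small_complex.ligand.atoms[:1]), near[None])
        assert pdk.clash_report(small_complex.receptor, p) >= 1

    def test_well_separated_pose_has_zero_clashes(self, small_complex, pose):
        assert pdk.clash_report(small_complex.receptor, pose) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_count_matches_brute_force_tally(self, seed):
        rng = np.random.default_rng(300 + seed)
        rec_xyz = rng.uniform(-5, 5, (30, 3))
        lig_xyz = rng.uniform(-5, 5, (8, 3))
        rec = st.Structure(
            [st.Atom(i + 1, "CA", "C", "A", i + 1, "ALA", "protein") for i in range(30)],
            rec_xyz,
        )
        p = pdk.Pose(
            [st.Atom(50 + j, f"C{j+1}", "C", "L", 1, "LIG", "hetero") for j in range(8)],
            lig_xyz,
        )
        expected = sum(
            1
            for r in rec_xyz
            for l in lig_xyz
            if np.linalg.norm(r - l) < 1.5
        )
        assert pdk.clash_report(rec, p, d_clash=1.5) == expected


class TestInteractionScore:
    def _dimer(self, r, charges=(0.0, 0.0)):
        rec = st.Structure(
            [st.Atom(1, "CA", "C", "A", 1, "ALA", "protein")], [[0.0, 0.0, 0.0]]
        )
        pose = pdk.Pose(
            [st.Atom(2, "C1", "C", "L", 1, "LIG", "hetero")], [[r, 0.0, 0.0]]
        )
        block = {
            "atom_types": {
                "CAB": {"charge": charges[0], "epsilon": 0.2, "rmin_half": 1.8,
                        "mass": 12.0},
                "LIG": {"charge": charges[1], "epsilon": 0.2, "rmin_half": 1.8,
                        "mass": 12.0},
            },
            "type_rules": [
                {"residue": "LIG", "type": "LIG"},
                {"residue": "*", "type": "CAB"},
            ],
        }
        from offpipe.energetics import load_forcefield

        return rec, pose, load_forcefield(block)

    def test_lj_zero_crossing_at_sigma(self):
        rmin = 3.6
        sigma = rmin / 2 ** (1 / 6)
        rec, pose, ff = self._dimer(sigma)
        assert pdk.raw_interaction_score(rec, pose, ff) == pytest.approx(0.0, abs=1e-9)

    def test_lj_well_depth_at_rmin(self):
        rec, pose, ff = self._dimer(3.6)
        assert pdk.raw_interaction_score(rec, pose, ff) == pytest.approx(-0.2, abs=1e-9)

    def test_resolving_clash_lowers_score(self, small_complex, small_ff, pose):
        clashed = pdk.Pose(
            pose.atoms, pose.coords + (small_complex.receptor.coords[0] - pose.coords[0])
        )
        relaxed = pdk.Pose(clashed.atoms, clashed.coords + 2.0)
        s_clash = pdk.raw_interaction_score(small_complex.receptor, clashed, small_ff)
        s_relax = pdk.raw_interaction_score(small_complex.receptor, relaxed, small_ff)
        assert s_relax < s_clash


class TestLocalOptimization:
    def test_score_never_increases(self, small_complex, small_ff, pose):
        s0 = pdk.raw_interaction_score(small_complex.receptor, pose, small_ff)
        _, s1 = pdk.local_optimize_pose(small_complex.receptor, pose, small_ff)
        assert s1 <= s0

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_over_random_starting_poses(self, seed, small_complex, small_ff):
        rng = np.random.default_rng(400 + seed)
        shift = rng.uniform(-2, 2, 3)
        p = pdk.Pose(list(small_complex.ligand.atoms), small_complex.ligand.coords + shift)
        s0 = pdk.raw_interaction_score(small_complex.receptor, p, small_ff)
        out, s1 = pdk.local_optimize_pose(small_complex.receptor, p, small_ff)
        assert s1 <= s0
        assert np.linalg.norm(out.coords.mean(axis=0) - p.coords.mean(axis=0)) <= 5.0 + 1e-6

    def test_clash_count_does_not_grow(self, small_complex, small_ff):
        clashed = pdk.Pose(
            list(small_complex.ligand.atoms),
            small_complex.ligand.coords
            + (small_complex.receptor.coords[5] - small_complex.ligand.coords[0]),
        )
        c0 = pdk.clash_report(small_complex.receptor, clashed)
        out, _ = pdk.local_optimize_pose(small_complex.receptor, clashed, small_ff)
        assert pdk.clash_report(small_complex.receptor, out) <= c0


class TestNDS:
    def test_score_at_background_mean_is_zero(self, rng):
        bg = rng.normal(-3.0, 1.5, 100)
        assert pdk.normalized_docking_score(bg.mean(), bg) == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_below_mean_is_minus_one(self, rng):
        bg = rng.normal(-3.0, 1.5, 100)
        s = bg.mean() - bg.std(ddof=1)
        assert pdk.normalized_docking_score(s, bg) == pytest.approx(-1.0, abs=1e-9)

    def test_affine_invariance(self, rng):
        bg = rng.normal(0.0, 2.0, 60)
        s = -4.2
        base = pdk.normalized_docking_score(s, bg)
        for a, b in [(1.0, 7.0), (3.5, -2.0), (0.1, 100.0)]:
            recal = pdk.normalized_docking_score(a * s + b, a * bg + b)
            assert recal == pytest.approx(base, abs=1e-9)

    def test_constant_background_rejected(self):
        with pytest.raises(NormalizationError):
            pdk.normalized_docking_score(0.0, np.zeros(30))

    def test_filter_removes_positive_nds_and_clashes(self):
        panels = {
            "worse_than_random": pdk.ScorePanel(0.0, 0, nds=1.328),
            "good": pdk.ScorePanel(-5.0, 0, nds=-2.0),
            "good_but_clashed": pdk.ScorePanel(-5.0, 3, nds=-2.0, severe_clash=True),
        }
        assert pdk.nds_filter(panels) == ["good"]
        assert panels["worse_than_random"].retained is False


class TestContacts:
    def _pair(self, elem_r, elem_l, dist):
        rec = st.Structure(
            [st.Atom(1, elem_r + "1", elem_r, "A", 1, "ALA", "protein")],
            [[0.0, 0.0, 0.0]],
        )
        pose = pdk.Pose(
            [st.Atom(2, elem_l + "9", elem_l, "L", 1, "LIG", "hetero")],
            [[dist, 0.0, 0.0]],
        )
        return rec, pose

    def test_NO_pair_at_316_is_a_hydrogen_bond(self):
        rec, pose = self._pair("N", "O", 3.16)
        rep = pdk.analyze_contacts(rec, pose)
        assert len(rep.hbonds) == 1
        assert rep.hbonds[0][2] == pytest.approx(3.16)

    def test_NO_pair_beyond_cutoff_not_reported(self):
        rec, pose = self._pair("N", "O", 3.6)
        assert pdk.analyze_contacts(rec, pose).hbonds == []

    def test_CC_pair_within_45_is_hydrophobic(self):
        rec, pose = self._pair("C", "C", 4.4)
        rep = pdk.analyze_contacts(rec, pose)
        assert len(rep.hydrophobic) == 1
        assert rep.hbonds == []
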