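import numpy as np
import pytest

from offpipe import structio as st
from offpipe.errors import (
    DegenerateFitError,
    PDBParseError,
    RosterError,
    SelectionError,
)

SINGLE_ATOM = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
)


def test_single_atom_line_parses_coordinates():
    s = st.read_pdb(SINGLE_ATOM)
    assert isinstance(s, st.Structure)
    assert s.n_atoms == 1
    np.testing.assert_allclose(s.coords[0], [1.0, 2.0, 3.0])
    a = s.atoms[0]
    assert (a.name, a.element, a.chain, a.residue_number) == ("CA", "C", "A", 1)


def test_write_read_round_trip_preserves_atoms_to_3_decimals(small_complex):
    merged = small_complex.merged()
    again = st.read_pdb(st.write_pdb(merged))
    assert [(a.chain, a.residue_number, a.name) for a in again.atoms] == [
        (a.chain, a.residue_number, a.name) for a in merged.atoms
    ]
    np.testing.assert_allclose(again.coords, np.round(merged.coords, 3), atol=5e-4)


def test_multi_model_file_yields_ensemble_with_shared_roster(small_complex):
    traj = st.perturb_ensemble(small_complex, n=5, sigma=0.1, seed=0)
    again = st.read_pdb(st.write_pdb(traj))
    assert isinstance(again, st.TrajectoryEnsemble)
    assert again.n_snapshots == 5
    assert again.template.n_atoms == traj.template.n_atoms


@pytest.mark.parametrize(
    "text,err",
    [
        ("HEADER only\n", PDBParseError),
        ("ATOM      1  CA  ALA A   1     bad     2.000   3.000\n", PDBParseError),
        (SINGLE_ATOM.replace(" A   1 ", " A   1A"), PDBParseError),  # insertion code
    ],
)
def test_malformed_pdb_raises_parse_error(text, err):
    with pytest.raises(err):
        st.read_pdb(text)


def test_inconsistent_model_rosters_rejected():
    text = "MODEL 1\n" + SINGLE_ATOM + "ENDMDL\nMODEL 2\n" + SINGLE_ATOM.replace(
        " CA ", " CB "
    ) + "ENDMDL\n"
    with pytest.raises(RosterError):
        st.read_pdb(text)


class TestSplitComplex:
    def test_ligand_selector_extracts_hetero_residue(self, small_complex):
        merged = small_complex.merged()
        cm = st.split_complex(merged, "LIG")
        assert cm.ligand.n_atoms == small_complex.ligand.n_atoms
        assert all(a.record_kind == "protein" for a in cm.receptor.atoms)

    def test_absent_selector_raises(self, small_complex):
        with pytest.raises(SelectionError):
            st.split_complex(small_complex.merged(), "XYZ")

    def test_two_ligand_copies_demand_chain_disambiguation(self, small_complex):
        merged = small_complex.merged()
        extra = [
            st.Atom(900 + j, f"C{j+1}", "C", "M", 1, "LIG", "hetero")
            for j in range(3)
        ]
        atoms = list(merged.atoms) + extra
        coords = np.vstack([merged.coords, np.full((3, 3), 30.0) + np.arange(3)[:, None]])
        doubled = st.Structure(atoms, coords)
        with pytest.raises(SelectionError, match="disambiguate"):
            st.split_complex(doubled, "LIG")
        cm = st.split_complex(doubled, "LIG/M")
        assert cm.ligand.n_atoms == 3


class TestSyntheticComplex:
    def test_same_seed_bit_identical(self):
        a = st.make_synthetic_complex(7)
        b = st.make_synthetic_complex(7)
        assert (a.merged().coords == b.merged().coords).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_no_receptor_ligand_pair_below_contact_floor(self, seed):
        c = st.make_synthetic_complex(seed, n_residues=30, n_ligand_atoms=10)
        d = np.linalg.norm(
            c.receptor.coords[:, None] - c.ligand.coords[None], axis=2
        )
        assert d.min() >= 2.5

    def test_pocket_places_residues_within_site_cutoff(self):
        c = st.make_synthetic_complex(0, n_residues=30, n_ligand_atoms=10)
        d = np.linalg.norm(
            c.receptor.coords[:, None] - c.ligand.coords[None], axis=2
        )
        assert d.min() < 5.0  # at least one residue lines the pocket


class TestPerturbEnsemble:
    def test_zero_noise_zero_drift_reproduces_input(self, small_complex):
        traj = st.perturb_ensemble(small_complex, n=4, sigma=0.0, drift=0.0, seed=1)
        base = small_complex.merged().coords
        for k in range(4):
            np.testing.assert_array_equal(traj.coords[k], base)

    def test_drift_displaces_ligand_centroid_linearly(self, small_complex):
        n, drift = 21, 0.5
        traj = st.perturb_ensemble(small_complex, n=n, sigma=0.0, drift=drift, seed=5)
        lig = small_complex.ligand_mask
        disp = np.linalg.norm(
            traj.coords[-1][lig].mean(axis=0) - traj.coords[0][lig].mean(axis=0)
        )
        assert disp == pytest.approx((n - 1) * drift, abs=1e-9)

    def test_seeded_reproducibility(self, small_complex):
        t1 = st.perturb_ensemble(small_complex, 5, 0.3, seed=9)
        t2 = st.perturb_ensemble(small_complex, 5, 0.3, seed=9)
        np.testing.assert_array_equal(t1.coords, t2.coords)


class TestSelectSnapshots:
    def _traj(self, n, interval, template):
        coords = np.repeat(template.coords[None], n, axis=0)
        coords += 1e-6 * np.arange(n)[:, None, None]
        return st.TrajectoryEnsemble(
            template, coords, interval * np.arange(1, n + 1)
        )

    def test_last_2ns_of_8ns_at_10ps_gives_200_frames(self, small_complex):
        traj = self._traj(800, 10.0, small_complex.merged())
        sel = st.select_snapshots(traj, (6000.0, 8000.0), 10.0)
        assert sel.n_snapshots == 200
        assert sel.times[0] == 6010.0 and sel.times[-1] == 8000.0

    def test_window_is_left_open_right_closed(self, small_complex):
        traj = self._traj(10, 10.0, small_complex.merged())
        sel = st.select_snapshots(traj, (0.0, 100.0), 10.0)
        assert sel.n_snapshots == 10

    def test_window_beyond_end_raises(self, small_complex):
        traj = self._traj(10, 10.0, small_complex.merged())
        with pytest.raises(SelectionError):
            st.select_snapshots(traj, (90.0, 300.0), 10.0)

    def test_selected_times_subset_and_ordered(self, small_complex):
        traj = self._traj(50, 10.0, small_complex.merged())
        sel = st.select_snapshots(traj, (200.0, 400.0), 20.0)
        assert set(sel.times) <= set(traj.times)
        assert (np.diff(sel.times) > 0).all()


class TestSuperposeAndRMSD:
    def test_translated_copies_align_exactly(self, small_complex):
        base = small_complex.merged()
        coords = np.stack([base.coords + k * np.array([1.0, -2.0, 0.5]) for k in range(4)])
        traj = st.TrajectoryEnsemble(base, coords, 10.0 * np.arange(1, 5))
        fitted = st.superpose_to_first(traj, selection=("CA",))
        series = st.rmsd_series(fitted, fitted.template.name_mask(("CA",)))
        assert max(r for _, r in series) < 1e-8

    def test_rotated_copy_aligns_exactly(self, small_complex):
        base = small_complex.merged()
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg z
        coords = np.stack([base.coords, base.coords @ R.T])
        traj = st.TrajectoryEnsemble(base, coords, np.array([10.0, 20.0]))
        fitted = st.superpose_to_first(traj, selection=("CA", "CB"))
        _, r = st.rmsd_series(fitted, np.ones(base.n_atoms, bool))[1]
        assert r < 1e-8

    def test_fit_never_increases_selection_rmsd(self, small_complex):
        traj = st.perturb_ensemble(small_complex, 10, 0.4, seed=2)
        mask = traj.template.name_mask(("CA", "CB"))
        before = [r for _, r in st.rmsd_series(traj, mask)]
        fitted = st.superpose_to_first(traj, selection=("CA", "CB"))
        after = [r for _, r in st.rmsd_series(fitted, mask)]
        assert all(a <= b + 1e-9 for a, b in zip(after, before))

    def test_single_displaced_atom_rmsd_is_pythagorean(self, small_complex):
        base = small_complex.merged()
        coords = np.stack([base.coords, base.coords.copy()])
        coords[1, 0] += np.array([3.0, 4.0, 0.0])
        traj = st.TrajectoryEnsemble(base, coords, np.array([10.0, 20.0]))
        mask = np.zeros(base.n_atoms, bool)
        mask[0] = True
        series = st.rmsd_series(traj, mask)
        assert series[0][1] == 0.0
        assert series[1][1] == pytest.approx(5.0)

    def test_gaussian_noise_rms_displacement_matches_sigma_sqrt3(self):
        # each snapshot is base + iid noise, so per-atom displacement from
        # the base has RMS sigma * sqrt(3)
        c = st.make_synthetic_complex(11, n_residues=500, n_ligand_atoms=4)
        sigma = 0.3
        traj = st.perturb_ensemble(c, 2, sigma, seed=8)
        d = traj.coords[1] - c.merged().coords
        r = np.sqrt((d**2).sum() / len(d))
        assert r == pytest.approx(sigma * np.sqrt(3.0), rel=0.10)

    def test_degenerate_selection_rejected(self, small_complex):
        traj = st.perturb_ensemble(small_complex, 3, 0.1, seed=1)
        with pytest.raises(DegenerateFitError):
            st.superpose_to_first(traj, selection=("NOPE",))
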