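import itertools

import numpy as np
import pytest

from offpipe import sitealign as sa, sitecore as sc
from offpipe.errors import DegenerateFitError, FitError, SubstitutionTableError

AA = list(sa._3TO1.keys())


def random_site(rng, n, parent="s", spread=4.0):
    return sc.BindingSite(
        parent,
        [("A", int(i)) for i in range(n)],
        [AA[int(rng.integers(0, 20))] for _ in range(n)],
        rng.normal(0, spread, (n, 3)),
        rng.uniform(0, 100, n),
    )


def brute_force_best_score(A, B, params):
    """Exhaustive search over injective, geometrically consistent mappings."""
    dA = np.linalg.norm(A.ca_coords[:, None] - A.ca_coords[None], axis=2)
    dB = np.linalg.norm(B.ca_coords[:, None] - B.ca_coords[None], axis=2)
    best = 0.0
    for k in range(1, min(len(A), len(B)) + 1):
        for sub_a in itertools.combinations(range(len(A)), k):
            for sub_b in itertools.permutations(range(len(B)), k):
                ws = []
                ok = True
                for a, b in zip(sub_a, sub_b):
                    w = sa.residue_pair_similarity(
                        (A.residue_names[a], A.gp[a]),
                        (B.residue_names[b], B.gp[b]),
                        params,
                    )
                    if w <= params.w_min:
                        ok = False
                        break
                    ws.append(w)
                if not ok:
                    continue
                for (a1, b1), (a2, b2) in itertools.combinations(
                    zip(sub_a, sub_b), 2
                ):
                    if abs(dA[a1, a2] - dB[b1, b2]) > params.epsilon:
                        ok = False
                        break
                if ok:
                    best = max(best, sum(ws))
    return best


class TestPairSimilarity:
    def test_identical_residue_and_gp_hits_formula_maximum(self):
        w = sa.residue_pair_similarity(("TRP", 40.0), ("TRP", 40.0))
        assert w == pytest.approx(11.0 / 11.0 + 1.0)  # BLOSUM62 W/W is the max diagonal

    def test_full_gp_difference_zeroes_environment_term(self):
        w = sa.residue_pair_similarity(("ALA", 0.0), ("ALA", 100.0))
        assert w == pytest.approx(4.0 / 11.0)

    def test_symmetry_over_random_pairs(self, rng):
        for _ in range(100):
            a = (AA[int(rng.integers(0, 20))], float(rng.uniform(0, 100)))
            b = (AA[int(rng.integers(0, 20))], float(rng.uniform(0, 100)))
            assert sa.residue_pair_similarity(a, b) == pytest.approx(
                sa.residue_pair_similarity(b, a), abs=1e-12
            )

    def test_unknown_residue_code_rejected(self):
        with pytest.raises(SubstitutionTableError):
            sa.residue_pair_similarity(("XXX", 50.0), ("ALA", 50.0))


class TestAlignSites:
    def test_self_alignment_is_identity_with_zero_rmsd(self, rng):
        site = random_site(rng, 8)
        res = sa.align_sites(site, site)
        assert res.pairs == [(rid, rid) for rid in site.residue_ids]
        expected = sum(
            sa.residue_pair_similarity(
                (site.residue_names[i], site.gp[i]),
                (site.residue_names[i], site.gp[i]),
            )
            for i in range(len(site))
        )
        assert res.score == pytest.approx(expected, abs=1e-9)
        assert res.rmsd < 1e-8

    def test_rigidly_rotated_copy_aligns_like_self(self, rng):
        site = random_site(rng, 8)
        theta = 0.8
        R = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        rotated = sc.BindingSite(
            site.parent_id,
            list(site.residue_ids),
            list(site.residue_names),
            site.ca_coords @ R.T + np.array([3.0, -1.0, 7.0]),
            site.gp.copy(),
        )
        res_self = sa.align_sites(site, site)
        res_rot = sa.align_sites(site, rotated)
        assert res_rot.pairs == res_self.pairs
        assert res_rot.rmsd <= 1e-6

    @pytest.mark.parametrize("case", range(20))
    def test_exact_solver_matches_exhaustive_search(self, case):
        rng = np.random.default_rng(100 + case)
        params = sa.AlignParams()
        A = random_site(rng, int(rng.integers(3, 7)), parent="a")
        B = random_site(rng, int(rng.integers(3, 7)), parent="b")
        got = sa.align_sites(A, B, params).score
        want = brute_force_best_score(A, B, params)
        assert got == pytest.approx(want, abs=1e-9)

    def test_score_symmetric_under_argument_swap(self, rng):
        A = random_site(rng, 6, parent="a")
        B = random_site(rng, 6, parent="b")
        assert sa.align_sites(A, B).score == pytest.approx(
            sa.align_sites(B, A).score, abs=1e-9
        )

    def test_sites_below_three_residues_rejected(self, rng):
        small = random_site(rng, 2)
        with pytest.raises(ValueError):
            sa.align_sites(small, small)


class TestSuperposePoints:
    def test_identical_point_sets_zero_rmsd(self, rng):
        P = rng.normal(0, 3, (10, 3))
        _, _, rmsd = sa.superpose_points(P, P)
        assert rmsd <= 1e-8

    def test_pure_translation_recovers_identity_rotation(self, rng):
        P = rng.normal(0, 3, (10, 3))
        R, t, rmsd = sa.superpose_points(P, P + np.array([4.0, 5.0, -6.0]))
        assert rmsd <= 1e-8
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rotation_determinant_is_plus_one(self, rng):
        # mirror-image clouds must not be matched by an improper rotation
        P = rng.normal(0, 3, (10, 3))
        Q = P.copy()
        Q[:, 0] *= -1
        R, _, _ = sa.superpose_points(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_copy_rmsd_tracks_sigma(self):
        sigma, hits = 0.1, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            P = rng.normal(0, 3, (10, 3))
            Q = P + rng.normal(0, sigma, P.shape)
            _, _, rmsd = sa.superpose_points(P, Q)
            if 0.5 * sigma * np.sqrt(3) <= rmsd <= 1.5 * sigma * np.sqrt(3):
                hits += 1
        assert hits >= 95

    def test_collinear_points_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateFitError):
            sa.superpose_points(P, P + 1.0)


class TestEVD:
    def test_fit_recovers_gumbel_parameters_within_2_percent(self):
        rng = np.random.default_rng(1)
        samples = rng.gumbel(5.0, 2.0, 10_000)
        m = sa.fit_evd(samples)
        assert m.mu == pytest.approx(5.0, rel=0.02)
        assert m.beta == pytest.approx(2.0, rel=0.02)

    def test_location_family_shift(self):
        rng = np.random.default_rng(2)
        x = rng.gumbel(3.0, 1.5, 5000)
        m0, m1 = sa.fit_evd(x), sa.fit_evd(x + 10.0)
        assert m1.mu - m0.mu == pytest.approx(10.0, abs=1e-6)
        assert m1.beta == pytest.approx(m0.beta, rel=1e-6)

    def test_scale_family(self):
        rng = np.random.default_rng(3)
        x = rng.gumbel(3.0, 1.5, 5000)
        m0, m2 = sa.fit_evd(x), sa.fit_evd(2.0 * x)
        assert m2.mu == pytest.approx(2.0 * m0.mu, rel=1e-6)
        assert m2.beta == pytest.approx(2.0 * m0.beta, rel=1e-6)

    def test_constant_scores_rejected(self):
        with pytest.raises(FitError):
            sa.fit_evd(np.full(100, 3.0))

    def test_pvalue_at_location_is_1_minus_inv_e(self):
        m = sa.EVDModel(mu=4.0, beta=1.3)
        assert sa.evd_pvalue(4.0, m) == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)

    def test_pvalue_at_median_is_half(self):
        m = sa.EVDModel(mu=4.0, beta=1.3)
        median = m.mu - m.beta * np.log(np.log(2.0))
        assert sa.evd_pvalue(median, m) == pytest.approx(0.5, abs=1e-9)

    def test_pvalue_strictly_decreasing_and_in_unit_interval(self):
        m = sa.EVDModel(mu=0.0, beta=2.0)
        scores = np.linspace(-10, 50, 200)
        ps = [sa.evd_pvalue(s, m) for s in scores]
        # strictly decreasing wherever the value is representable below 1
        assert all(
            p1 > p2 for p1, p2 in zip(ps, ps[1:]) if p1 < 1.0 - 1e-12
        )
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
        assert all(0.0 < p <= 1.0 for p in ps)


class TestScreening:
    def test_query_in_library_ranks_first(self, rng):
        query = random_site(rng, 7, parent="query")
        library = {"self": query}
        for k in range(10):
            library[f"decoy{k}"] = random_site(rng, 7, parent=f"d{k}")
        hits, _ = sa.screen_sites(query, library, n_background=60, seed=0)
        assert hits[0].target_id == "self"
        assert hits[0].p_value == min(h.p_value for h in hits)

    def test_all_decoy_library_rarely_significant(self):
        false_calls = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            query = random_site(rng, 7, parent="query")
            library = {
                f"d{k}": random_site(rng, 7, parent=f"d{k}") for k in range(50)
            }
            hits, _ = sa.screen_sites(query, library, n_background=60, seed=seed)
            false_calls += any(h.p_value < 1e-3 for h in hits)
        assert false_calls <= 1  # >= 90% of seeds clean

    def test_planted_similar_site_recovered_at_rank_one(self, rng):
        query = random_site(rng, 8, parent="query")
        names = list(query.residue_names)
        names[3] = "GLY" if names[3] != "GLY" else "TRP"  # one mutation
        planted = sc.BindingSite(
            "planted", list(query.residue_ids), names,
            query.ca_coords.copy(), query.gp.copy(),
        )
        library = {"planted": planted}
        for k in range(50):
            library[f"decoy{k}"] = random_site(rng, 8, parent=f"d{k}")
        hits, _ = sa.screen_sites(query, library, n_background=100, seed=0)
        assert hits[0].target_id == "planted"
        assert hits[0].tier != "none"

    def test_tiers_consistent_with_pvalues(self, rng):
        query = random_site(rng, 6, parent="q")
        library = {"self": query}
        hits, _ = sa.screen_sites(
            query, library, alpha=0.5, alpha_stringent=0.1, n_background=60, seed=1
        )
        h = hits[0]
        expected = (
            "stringent" if h.p_value < 0.1 else
            "significant" if h.p_value < 0.5 else "none"
        )
        assert h.tier == expected
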