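"""Kabsch superposition, TM-score, and sequence-independent alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foldclust as fc
from foldclust.structures import ProteinStructure, Residue

from _oracles import grid_min_rmsd
from conftest import make_random_fold


def as_structure(coords, id="s"):
    return ProteinStructure(
        id, [Residue(i + 1, "ALA", c, 90.0) for i, c in enumerate(coords)]
    )


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return fc.RigidTransform(R, rng.uniform(-10, 10, 3))


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        P = rng.normal(size=(8, 3))
        transform, rmsd = fc.kabsch_superpose(P, P)
        assert rmsd < 1e-9
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0.0, atol=1e-9)

    def test_recovers_planted_rigid_relation(self, rng):
        P = rng.normal(size=(10, 3))
        theta = np.pi / 2
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        Q = P @ R.T + np.array([1.0, 2.0, 3.0])
        transform, rmsd = fc.kabsch_superpose(P, Q)
        assert rmsd < 1e-9
        assert np.allclose(transform.apply(P), Q, atol=1e-9)

    def test_mirrored_set_matches_grid_search_oracle(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        Q = P * np.array([1.0, 1.0, -1.0])  # reflection through the xy-plane
        _, rmsd = fc.kabsch_superpose(P, Q)
        assert rmsd > 0
        assert abs(rmsd - grid_min_rmsd(P, Q)) < 0.02

    def test_rejects_fewer_than_three_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            fc.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rotation_is_always_proper(self, rng):
        for _ in range(10):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            transform, _ = fc.kabsch_superpose(P, Q)
            assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)


class TestPairRmsd:
    def test_exact_rigid_relation_gives_zero(self, rng):
        P = rng.normal(size=(5, 3))
        g = random_rigid(rng)
        assert fc.pair_rmsd(P, g.apply(P), g) < 1e-9

    def test_three_four_five(self):
        P = np.array([[0.0, 0.0, 0.0]])
        Q = np.array([[3.0, 4.0, 0.0]])
        assert fc.pair_rmsd(P, Q) == pytest.approx(5.0)

    def test_matches_direct_formula(self, rng):
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        expected = np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))
        assert fc.pair_rmsd(P, Q) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            fc.pair_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_invariant_under_common_rigid_motion(self, rng):
        P = rng.normal(size=(7, 3))
        Q = rng.normal(size=(7, 3))
        g = random_rigid(rng)
        assert fc.pair_rmsd(g.apply(P), g.apply(Q)) == pytest.approx(
            fc.pair_rmsd(P, Q), abs=1e-9
        )


class TestTmScore:
    def test_d0_formula(self):
        assert fc.tm_d0(126) == pytest.approx(1.24 * 111 ** (1 / 3) - 1.8, abs=1e-12)
        assert fc.tm_d0(126) == pytest.approx(4.159, abs=1e-3)
        assert fc.tm_d0(15) == 0.5  # clamp
        assert fc.tm_d0(20) == 0.5  # formula gives 0.32, clamped

    def test_self_score_is_one(self):
        A = as_structure(make_random_fold(30, 5))
        corr = fc.Correspondence.full(30)
        assert fc.tm_score(A, A, corr, fc.RigidTransform.identity(), 30) == pytest.approx(1.0)

    def test_single_pair_at_d0(self):
        L = 20
        d0 = fc.tm_d0(L)
        A = as_structure(np.arange(L)[:, None] * [3.8, 0, 0])
        B_coords = A.coords.copy()
        B_coords[0] = A.coords[0] + [0, 0, d0]
        B = as_structure(B_coords, id="b")
        corr = fc.Correspondence(np.array([[0, 0]]))
        tm = fc.tm_score(A, B, corr, fc.RigidTransform.identity(), L)
        assert tm == pytest.approx(0.5 / L, abs=1e-12)

    def test_invariant_under_common_rigid_motion(self, rng):
        A = as_structure(make_random_fold(40, 6))
        B = as_structure(make_random_fold(40, 7), id="b")
        corr = fc.Correspondence.full(40)
        ident = fc.RigidTransform.identity()
        tm0 = fc.tm_score(A, B, corr, ident, 40)
        g = random_rigid(rng)
        tm1 = fc.tm_score(
            as_structure(g.apply(A.coords)), as_structure(g.apply(B.coords), id="b"),
            corr, ident, 40,
        )
        assert tm1 == pytest.approx(tm0, abs=1e-9)


class TestStructuralAlign:
    def test_self_alignment_is_perfect(self):
        A = as_structure(make_random_fold(80, 21))
        res = fc.structural_align(A, A)
        assert res.tm_sym == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd < 1e-6
        assert res.n_aligned == 80

    def test_rigid_copy_alignment_is_perfect(self, rng):
        A = as_structure(make_random_fold(70, 22))
        B = as_structure(random_rigid(rng).apply(A.coords), id="b")
        res = fc.structural_align(A, B)
        assert res.tm_sym == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd < 1e-6

    def test_terminal_truncation_aligns_shared_residues(self, rng):
        coords = make_random_fold(120, 23)
        A = as_structure(coords)
        B = as_structure(random_rigid(rng).apply(coords[10:]), id="b")
        res = fc.structural_align(A, B)
        assert res.n_aligned == 110
        # TM normalized by the shorter chain (B, L=110)
        assert res.tm_ba == pytest.approx(1.0, abs=1e-6)

    def test_unrelated_random_walks_score_below_family_pairs(self, small_alignments):
        walk1 = as_structure(fc.make_fold([("coil", 100)], 31), id="w1")
        walk2 = as_structure(fc.make_fold([("coil", 100)], 32), id="w2")
        unrelated = fc.structural_align(walk1, walk2).tm_sym
        within = [
            r.tm_sym for (a, b), r in small_alignments.items() if a[:2] == b[:2]
        ]
        assert unrelated < min(within)

    def test_argument_order_symmetry(self, small_dataset):
        structs = small_dataset.structures.structures
        A, B = structs[0], structs[5]
        r1 = fc.structural_align(A, B)
        r2 = fc.structural_align(B, A)
        assert abs(r1.tm_sym - r2.tm_sym) < 1e-6
        assert r1.tm_ab == r2.tm_ba and r1.tm_ba == r2.tm_ab

    def test_too_short_structures_rejected(self):
        A = as_structure(np.arange(4)[:, None] * [3.8, 0, 0])
        with pytest.raises(ValueError, match="at least 5"):
            fc.structural_align(A, A)

    def test_tm_never_exceeds_one(self, small_alignments):
        for r in small_alignments.values():
            assert 0 < r.tm_ab <= 1.0 and 0 < r.tm_ba <= 1.0 and r.rmsd >= 0

    def test_noise_monotonically_degrades_expected_tm(self):
        """Mean tm_sym over 20 seeds is non-increasing in coordinate noise."""
        sigmas = [0.3, 1.0, 2.0]
        means = []
        for sigma in sigmas:
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(900 + seed)
                template = make_random_fold(60, rng)
                noisy, _ = fc.make_family_member(template, sigma, 0.0, rng)
                r = fc.structural_align(
                    as_structure(template), as_structure(noisy, id="b")
                )
                vals.append(r.tm_sym)
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]


class TestCorrespondence:
    def test_requires_strictly_increasing_indices(self):
        with pytest.raises(ValueError):
            fc.Correspondence(np.array([[0, 0], [1, 0]]))
        with pytest.raises(ValueError):
            fc.Correspondence(np.array([[2, 0], [1, 1]]))

    @given(st.integers(min_value=1, max_value=50))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_full_correspondence_is_valid(self, n):
        corr = fc.Correspondence.full(n)
        assert len(corr) == n
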