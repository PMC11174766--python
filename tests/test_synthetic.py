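"""Synthetic fold-family generator: geometry, determinism, planted truth."""

import math

import numpy as np
import pytest

import foldclust as fc
from foldclust.structures import ProteinStructure, Residue
from foldclust.synthetic import ClashError, random_segments


def as_structure(coords, id="s"):
    return ProteinStructure(
        id, [Residue(i + 1, "ALA", c, 90.0) for i, c in enumerate(coords)]
    )


class TestMakeFold:
    def test_ideal_helix_step_geometry(self):
        """Consecutive Cα distance of an ideal helix: sqrt(rise² + chord²)."""
        coords = fc.make_fold([("helix", 20)], seed=0)
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        expected = math.sqrt(1.5**2 + (2 * 2.3 * math.sin(math.radians(50))) ** 2)
        assert expected == pytest.approx(3.83, abs=0.005)
        assert np.allclose(d, expected, atol=0.01)

    def test_same_seed_is_bit_stable(self):
        segs = [("helix", 15), ("coil", 6), ("helix", 12)]
        c1 = fc.make_fold(segs, seed=9)
        c2 = fc.make_fold(segs, seed=9)
        assert np.array_equal(c1, c2)

    def test_different_seeds_differ(self):
        segs = [("helix", 15), ("coil", 6), ("helix", 12)]
        assert not np.array_equal(fc.make_fold(segs, seed=1), fc.make_fold(segs, seed=2))

    def test_no_clashes_in_output(self):
        coords = fc.make_fold([("helix", 20), ("coil", 8), ("helix", 20)], seed=4)
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(coords))
        np.fill_diagonal(D, np.inf)
        for i in range(len(coords) - 1):
            D[i, i + 1] = D[i + 1, i] = np.inf  # bonded neighbours excluded
        assert D.min() >= 3.0 - 1e-9

    def test_distinct_folds_score_below_same_fold_copies(self):
        """Different fold specs align worse than noise-free same-fold copies."""
        rng = np.random.default_rng(0)
        lows, highs = [], []
        for seed in range(10):
            f1 = fc.make_fold(random_segments(60, np.random.default_rng(seed)),
                              np.random.default_rng(seed))
            f2 = fc.make_fold(random_segments(60, np.random.default_rng(1000 + seed)),
                              np.random.default_rng(1000 + seed))
            copy, _ = fc.make_family_member(f1, 0.0, 0.0, np.random.default_rng(seed))
            lows.append(fc.structural_align(as_structure(f1), as_structure(f2, "b")).tm_sym)
            highs.append(fc.structural_align(as_structure(f1), as_structure(copy, "b")).tm_sym)
        assert max(lows) < min(highs)

    def test_too_short_fold_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            fc.make_fold([("helix", 10)], seed=0)


class TestMakeFamilyMember:
    def test_noise_free_member_is_rigid_copy(self):
        template = fc.make_fold([("helix", 20), ("coil", 5), ("helix", 15)], seed=3)
        member, trunc = fc.make_family_member(template, 0.0, 0.0, seed=5)
        assert trunc is None
        res = fc.structural_align(as_structure(template), as_structure(member, "b"))
        assert res.tm_sym == pytest.approx(1.0, abs=1e-6)
        assert res.rmsd < 1e-6

    def test_noise_rmsd_matches_gaussian_expectation(self):
        """Two independently noised copies: E[RMSD] ≈ sigma * sqrt(6)."""
        sigma = 0.3
        template = fc.make_fold([("helix", 25), ("coil", 5), ("helix", 20)], seed=6)
        rmsds = []
        for seed in range(50):
            a, _ = fc.make_family_member(template, sigma, 0.0, seed=2 * seed)
            b, _ = fc.make_family_member(template, sigma, 0.0, seed=2 * seed + 1)
            res = fc.structural_align(as_structure(a), as_structure(b, "b"))
            rmsds.append(res.rmsd)
        expected = math.sqrt(3) * sigma * math.sqrt(2)
        assert np.mean(rmsds) == pytest.approx(expected, rel=0.2)

    def test_truncation_shortens_member(self):
        template = fc.make_fold([("helix", 30), ("coil", 10), ("helix", 20)], seed=7)
        seen = False
        for seed in range(20):
            member, trunc = fc.make_family_member(template, 0.1, 1.0, seed=seed)
            assert len(member) < len(template)
            assert trunc is not None
            seen = True
        assert seen


class TestSimulatePlddt:
    def test_target_mean_below_threshold_forces_removal(self):
        values = fc.simulate_plddt(100, 90.0, 70.0, target_mean=79.0, seed=1)
        assert abs(values.mean() - 79.0) <= 0.01
        s = as_structure(np.arange(100)[:, None] * [3.8, 0, 0])
        s = ProteinStructure(
            "t", [Residue(i + 1, "ALA", r.coord, float(values[i])) for i, r in enumerate(s.residues)]
        )
        kept, removed = fc.filter_structures(fc.StructureSet([s]), 80.0)
        assert removed == ["t"]

    def test_target_mean_above_threshold_is_retained(self):
        values = fc.simulate_plddt(100, 90.0, 70.0, target_mean=85.0, seed=2)
        assert abs(values.mean() - 85.0) <= 0.01

    def test_termini_less_confident_than_core(self):
        values = fc.simulate_plddt(200, 90.0, 60.0, seed=3)
        tails = np.concatenate([values[:10], values[-10:]])
        core = values[10:-10]
        assert tails.mean() < core.mean()

    def test_values_clipped_to_valid_range(self):
        values = fc.simulate_plddt(50, 99.0, 1.0, seed=4)
        assert values.min() >= 0.0 and values.max() <= 100.0


class TestGenerateDataset:
    def test_member_counts_and_labels(self, small_dataset):
        assert len(small_dataset.structures) == 12
        assert sorted(set(small_dataset.labels.values())) == ["F1", "F2", "F3"]
        assert all(s.id in small_dataset.labels for s in small_dataset.structures)

    def test_same_spec_reproduces_bitwise(self, small_dataset):
        ds2 = fc.generate_dataset(small_dataset.spec)
        for s1, s2 in zip(small_dataset.structures, ds2.structures):
            assert s1.id == s2.id
            assert np.array_equal(s1.coords, s2.coords)
            assert np.array_equal(s1.plddt, s2.plddt)
        assert [r.seq for r in ds2.sequences] == [r.seq for r in small_dataset.sequences]

    def test_low_confidence_members_are_filtered_exactly(self):
        spec = fc.SyntheticFamilySpec(
            n_families=3, members_per_family=4, length=60,
            low_confidence_members=2, seed=21,
        )
        ds = fc.generate_dataset(spec)
        kept, removed = fc.filter_structures(ds.structures, 80.0)
        assert len(kept) == 10 and len(removed) == 2
        assert sorted(removed) == sorted(ds.low_confidence_ids)

    def test_swapped_members_recorded(self):
        spec = fc.SyntheticFamilySpec(
            n_families=3, members_per_family=4, length=60,
            swap_fraction=2 / 12, seed=22,
        )
        ds = fc.generate_dataset(spec)
        assert len(ds.swapped_ids) == 2
        seqs = {r.id: r.seq for r in ds.sequences}
        # a swapped member's sequence is closer to the donor family consensus
        for sid in ds.swapped_ids:
            fam = ds.labels[sid]
            same_family = [
                i for i in seqs
                if ds.labels[i] == fam and i not in ds.swapped_ids and i != sid
            ]
            ident = fc.sequence_identity(seqs[sid], seqs[same_family[0]])
            assert ident < 0.5  # far from its own structural family

    def test_within_family_tm_exceeds_between(self, small_alignments, small_dataset):
        within = [v.tm_sym for (a, b), v in small_alignments.items()
                  if small_dataset.labels[a] == small_dataset.labels[b]]
        between = [v.tm_sym for (a, b), v in small_alignments.items()
                   if small_dataset.labels[a] != small_dataset.labels[b]]
        assert np.mean(within) > np.mean(between)
        assert min(within) > max(between)

    def test_within_exceeds_between_across_seeds_and_sigma(self):
        """Mean within-family TM > between-family TM for sigma up to 2 Å."""
        for sigma in (0.5, 2.0):
            wins = 0
            for seed in range(10):
                spec = fc.SyntheticFamilySpec(
                    n_families=2, members_per_family=2, length=60,
                    sigma=sigma, indel_rate=0.0, seed=3000 + seed,
                )
                ds = fc.generate_dataset(spec)
                structs = {s.id: s for s in ds.structures}
                ids = sorted(structs)
                import itertools

                within, between = [], []
                for a, b in itertools.combinations(ids, 2):
                    tm = fc.structural_align(structs[a], structs[b]).tm_sym
                    (within if ds.labels[a] == ds.labels[b] else between).append(tm)
                if np.mean(within) > np.mean(between):
                    wins += 1
            assert wins >= 9

    def test_dataset_roundtrip_through_disk(self, small_dataset, tmp_path):
        paths = fc.write_dataset(small_dataset, tmp_path)
        back = fc.read_structure_dir(paths["structures"])
        assert back.ids == sorted(small_dataset.structures.ids)
        orig = {s.id: s for s in small_dataset.structures}
        for s in back:
            assert np.allclose(s.coords, orig[s.id].coords, atol=1e-3)
            assert np.allclose(s.plddt, orig[s.id].plddt, atol=0.005)
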