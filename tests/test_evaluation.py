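import itertools

import numpy as np
import pytest

from steerkit.evaluation import (
    LddtScorer, greedy_symmetry_correction, lddt, ligand_automorphisms,
    pocket_aligned_rmsd, quality_report, residue_keys_of,
)
from steerkit.synthetic import ChainSpec, ToySpec, inject_violation, make_toy_complex
from conftest import VIOLATION_FIXTURES, toy


class TestLddt:
    def test_identical_structures_score_one(self, homodimer):
        complex_, _, _ = homodimer
        x = complex_.coords_matrix
        assert lddt(x, x, residue_keys_of(complex_)) == 1.0

    def test_fully_perturbed_scores_zero(self, homodimer):
        complex_, _, _ = homodimer
        x = complex_.coords_matrix
        # scatter every atom far away: every preserved-distance test fails
        rng = np.random.default_rng(0)
        pred = x + rng.uniform(50, 500, size=x.shape) * np.sign(
            rng.standard_normal(x.shape))
        assert lddt(pred, x, residue_keys_of(complex_)) == 0.0

    def test_three_atom_hand_computed(self):
        """3 atoms, 3 pairs; moving atom 1 by +1.5 Å along x puts pairs
        (0,1) and (1,2) off by 1.5 and ~1.14 Å — both fail the 0.5 and 1 Å
        thresholds, pass 2 and 4 — so the score is (1/3+1/3+1+1)/4 = 2/3."""
        ref = np.array([[0.0, 0, 0], [4.0, 0, 0], [0, 4.0, 0]])
        pred = ref.copy()
        pred[1, 0] += 1.5
        keys = [("A", 1), ("A", 2), ("A", 3)]
        delta12 = abs(np.linalg.norm(pred[1] - pred[2])
                      - np.linalg.norm(ref[1] - ref[2]))
        assert 1.0 < delta12 < 2.0
        assert lddt(pred, ref, keys) == pytest.approx(2.0 / 3.0)

    def test_error_when_no_pairs(self):
        ref = np.array([[0.0, 0, 0], [100.0, 0, 0], [0, 100.0, 0]])
        with pytest.raises(ValueError):
            lddt(ref, ref, [("A", 1), ("B", 1), ("C", 1)])

    def test_same_residue_pairs_excluded(self):
        ref = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 3.0, 0]])
        keys = [("A", 1), ("A", 1), ("A", 2)]
        pred = ref.copy()
        pred[1] += 10.0  # only intra-residue pair and its cross pairs move
        scorer = LddtScorer(ref, keys)
        assert scorer.n_pairs == 4  # pairs (0,2) and (1,2), ordered


class TestGreedyCorrection:
    def test_identity_when_no_symmetry(self, protein_ligand):
        complex_, _, _ = protein_ligand
        asg = greedy_symmetry_correction(complex_, complex_)
        assert asg.chain_map == {c: c for c in complex_.chains}
        assert asg.achieved_lddt == pytest.approx(1.0)

    def test_swapped_homodimer_recovered(self, homodimer):
        complex_, _, _ = homodimer
        pred = complex_.copy()
        x = pred.coords_matrix
        ia, ib = pred.chain_atom_indices("A"), pred.chain_atom_indices("B")
        xs = x.copy()
        xs[ia], xs[ib] = x[ib], x[ia]
        pred.set_coords(xs)
        asg = greedy_symmetry_correction(pred, complex_)
        assert asg.chain_map == {"A": "B", "B": "A"}
        assert asg.achieved_lddt == pytest.approx(1.0)

    def test_flipped_ring_recovered(self, ring_complex):
        complex_, _, _ = ring_complex
        pred = complex_.copy()
        idx = np.array(complex_.chain_atom_indices("B"))
        flip = np.array([0, 5, 4, 3, 2, 1])
        x = pred.coords_matrix
        x[idx] = x[idx][flip]
        pred.set_coords(x)
        asg = greedy_symmetry_correction(pred, complex_)
        assert asg.achieved_lddt == pytest.approx(1.0)
        assert "B" in asg.atom_permutations

    def test_never_below_identity_assignment(self, homodimer):
        complex_, _, _ = homodimer
        rng = np.random.default_rng(1)
        for trial in range(5):
            pred = complex_.copy()
            pred.set_coords(complex_.coords_matrix
                            + rng.standard_normal((len(complex_.atoms), 3)))
            identity = lddt(pred.coords_matrix, complex_.coords_matrix,
                            residue_keys_of(complex_))
            asg = greedy_symmetry_correction(pred, complex_)
            assert asg.achieved_lddt >= identity - 1e-12

    def test_matches_exhaustive_on_small_instances(self, homodimer):
        """≤6 total permutations (2 chain swaps × automorphisms): greedy
        equals brute force exactly."""
        complex_, _, _ = homodimer
        rng = np.random.default_rng(2)
        keys = residue_keys_of(complex_)
        ia = complex_.chain_atom_indices("A")
        ib = complex_.chain_atom_indices("B")
        for trial in range(10):
            pred = complex_.copy()
            x = complex_.coords_matrix + 0.8 * rng.standard_normal(
                (len(complex_.atoms), 3))
            if trial % 2:
                xs = x.copy()
                xs[ia], xs[ib] = x[ib], x[ia]
                x = xs
            pred.set_coords(x)
            best = -1.0
            for mapping in ({"A": "A", "B": "B"}, {"A": "B", "B": "A"}):
                perm = np.arange(len(complex_.atoms))
                perm[ia] = complex_.chain_atom_indices(mapping["A"])
                perm[ib] = complex_.chain_atom_indices(mapping["B"])
                best = max(best, lddt(pred.coords_matrix[perm],
                                      complex_.coords_matrix, keys))
            asg = greedy_symmetry_correction(pred, complex_)
            assert asg.achieved_lddt == pytest.approx(best, abs=1e-12)

    def test_incremental_equals_full_recomputation(self, ring_complex):
        """Row/column-incremental LDDT equals full recomputation to 1e-9
        across 100 random permutation applications."""
        complex_, _, _ = ring_complex
        scorer = LddtScorer(complex_.coords_matrix, residue_keys_of(complex_))
        autos = ligand_automorphisms(complex_, "B")
        idx = np.array(complex_.chain_atom_indices("B"))
        rng = np.random.default_rng(3)
        pred = complex_.coords_matrix + 0.4 * rng.standard_normal(
            (len(complex_.atoms), 3))
        perm = np.arange(len(complex_.atoms))
        counts = scorer.preserved_counts(pred[perm])
        for _ in range(100):
            auto = autos[rng.integers(len(autos))]
            new_perm = perm.copy()
            new_perm[idx] = perm[idx][auto]
            s_inc, new_counts = scorer.score_update(pred, perm, counts,
                                                    new_perm, idx)
            assert s_inc == pytest.approx(scorer.score(pred, new_perm),
                                          abs=1e-9)
            perm, counts = new_perm, new_counts

    def test_caps_validated(self, homodimer):
        complex_, _, _ = homodimer
        with pytest.raises(ValueError):
            greedy_symmetry_correction(complex_, complex_, chain_cap=0)


class TestLigandAutomorphisms:
    def test_ring_has_dihedral_group(self, ring_complex):
        complex_, _, _ = ring_complex
        autos = ligand_automorphisms(complex_, "B")
        assert len(autos) == 12  # rotations + reflections of a 6-cycle
        assert np.array_equal(autos[0], np.arange(6))

    def test_elements_break_symmetry(self):
        complex_, _, _ = make_toy_complex(ToySpec(chains=[
            ChainSpec("protein", 4), ChainSpec("nonpolymer", template="chiral")]))
        autos = ligand_automorphisms(complex_, "B")
        assert len(autos) == 1  # all substituents distinct

    def test_cap_respected(self, ring_complex):
        complex_, _, _ = ring_complex
        assert len(ligand_automorphisms(complex_, "B", cap=4)) <= 4


class TestQualityReport:
    @pytest.mark.parametrize("kind", sorted(VIOLATION_FIXTURES))
    def test_clean_fixture_passes_everything(self, kind):
        complex_, cs, _ = toy(kind)
        report = quality_report(complex_, cs)
        assert report.overall_pass
        assert all(v is True for v in report.checks.values())

    @pytest.mark.parametrize("kind,failing", [
        ("chiral_flip", "chirality_ok"),
        ("stereo_flip", "stereo_ok"),
        ("bond_stretch", "bond_lengths_ok"),
        ("internal_clash", "internal_clash_ok"),
        ("interchain_clash", "interchain_clash_ok"),
    ])
    def test_single_violation_fails_single_check(self, kind, failing):
        complex_, cs, _ = toy(kind)
        bad = inject_violation(complex_, cs, kind)
        report = quality_report(bad, cs)
        assert report.checks[failing] is False
        for name, value in report.checks.items():
            if name != failing:
                assert value is not False
        assert not report.overall_pass

    def test_clash_boundary_at_three_quarters(self):
        """Two multi-atom chains with one close pair: fail below
        0.75·(r_i+r_j), pass above."""
        complex_, cs, _ = make_toy_complex(ToySpec(
            chains=[ChainSpec("protein", 6), ChainSpec("protein", 8)],
            separation=20.0))
        for s, expected in ((0.5, False), (0.74, False), (0.76, True)):
            bad = inject_violation(complex_, cs, "interchain_clash", magnitude=s)
            assert quality_report(bad, cs).interchain_clash_ok is expected

    def test_missing_bounds_reported_not_evaluable(self):
        complex_, cs, _ = toy("bond_stretch")
        cs.ligand_bounds = []
        report = quality_report(complex_, cs)
        assert report.bond_lengths_ok is None
        assert report.overall_pass  # not-evaluable is not a failure


class TestPocketAlignedRmsd:
    def test_identical_is_zero(self, ring_complex):
        complex_, _, _ = ring_complex
        assert pocket_aligned_rmsd(complex_, complex_, "B") \
            == pytest.approx(0.0, abs=1e-9)

    def test_translated_ligand(self, ring_complex):
        complex_, _, _ = ring_complex
        pred = complex_.copy()
        idx = np.array(complex_.chain_atom_indices("B"))
        x = pred.coords_matrix
        x[idx] += np.array([0.0, 0.0, 3.0])
        pred.set_coords(x)
        assert pocket_aligned_rmsd(pred, complex_, "B") == pytest.approx(3.0, abs=1e-6)

    def test_flipped_symmetric_ligand_is_zero(self, ring_complex):
        complex_, _, _ = ring_complex
        pred = complex_.copy()
        idx = np.array(complex_.chain_atom_indices("B"))
        x = pred.coords_matrix
        x[idx] = x[idx][np.array([0, 5, 4, 3, 2, 1])]
        pred.set_coords(x)
        assert pocket_aligned_rmsd(pred, complex_, "B") == pytest.approx(0.0, abs=1e-9)

    def test_empty_pocket_rejected(self):
        complex_, _, _ = make_toy_complex(ToySpec(chains=[
            ChainSpec("protein", 6), ChainSpec("nonpolymer", template="ring")],
            separation=50.0))
        with pytest.raises(ValueError):
            pocket_aligned_rmsd(complex_, complex_, "B", pocket_radius=10.0)
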