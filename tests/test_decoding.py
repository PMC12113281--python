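"""Pseudo-population assembly, balanced folds, decoding engine mechanics."""

import numpy as np
import pytest

import headbody as hb
from headbody.decoding import _slot_fold_accuracy


class TestPseudoPopulation:
    def test_shapes_and_roster(self, conjunctive_pop_0180):
        conds = hb.monkey_conditions("P1", "MC", angles=(0,))
        pp = hb.build_pseudopopulation(conjunctive_pop_0180, conds, seed=0)
        assert len(pp.vectors) == 8
        for mat in pp.vectors.values():
            assert mat.shape == (8, 60)
        assert len(pp.unit_ids) == 60

    def test_every_unit_contributes_once(self, conjunctive_pop_0180):
        """Vectors are permutations of each unit's own trials."""
        cond = hb.monkey_condition("P1", 0, 0)
        pp = hb.build_pseudopopulation(conjunctive_pop_0180, [cond], seed=1)
        unit = conjunctive_pop_0180[17]
        raw = np.sort(unit.counts[cond][:, 2] / 0.25)
        assert np.array_equal(np.sort(pp.vectors[cond][:, 17]), raw)

    def test_determinism(self, conjunctive_pop_0180):
        conds = hb.monkey_conditions("P1", "MC", angles=(0,))
        a = hb.build_pseudopopulation(conjunctive_pop_0180, conds, seed=3)
        b = hb.build_pseudopopulation(conjunctive_pop_0180, conds, seed=3)
        assert all(np.array_equal(a.vectors[c], b.vectors[c]) for c in conds)

    def test_single_unit_roster(self, conjunctive_pop_0180):
        cond = hb.monkey_condition("P1", 0, 0)
        pp = hb.build_pseudopopulation(conjunctive_pop_0180[:1], [cond], seed=0)
        assert pp.vectors[cond].shape == (8, 1)


class TestBalancedFolds:
    def test_fold_sizes_eight_orientations(self):
        classes = {a: hb.monkey_conditions("P1", "MC", angles=(a,)) for a in (0, 180)}
        folds = hb.balanced_folds(classes, seed=0)
        assert len(folds) == 8
        for fold in folds:
            per_class = {a: sum(len(fold[c][0]) for c in classes[a]) for a in classes}
            assert per_class == {0: 56, 180: 56}  # 7 x 8 orientations

    def test_fold_sizes_four_orientations(self):
        classes = {
            a: hb.monkey_conditions("P1", "MC", angles=(a,),
                                    orientations=hb.PLUS_ORIENTATIONS)
            for a in (0, 180)
        }
        folds = hb.balanced_folds(classes, seed=0)
        for fold in folds:
            assert sum(len(fold[c][0]) for c in classes[0]) == 28  # 7 x 4

    def test_test_sets_partition_trials(self):
        classes = {a: hb.monkey_conditions("P1", "MC", angles=(a,)) for a in (0, 180)}
        folds = hb.balanced_folds(classes, seed=1)
        for cond in classes[0] + classes[180]:
            tested = sorted(fold[cond][1] for fold in folds)
            assert tested == list(range(8))
            for fold in folds:
                train, test = fold[cond]
                assert test not in train and len(train) == 7


class TestBalanceGuard:
    def test_balanced_contrast_accepted(self):
        classes = {
            a: [(c.head_orientation, c.body_orientation)
                for c in hb.monkey_conditions("P1", "MC", angles=(a,))]
            for a in (0, 180)
        }
        hb.check_balance(classes)  # no error

    def test_unbalanced_contrast_rejected(self):
        bad = {
            0: [(0, 0), (90, 90)],
            180: [(180, 0), (270, 90)],  # head orientations differ between classes
        }
        with pytest.raises(hb.BalanceError):
            hb.check_balance(bad)

    def test_decode_rejects_unbalanced_orientations(self, conjunctive_pop_0180):
        # a single-orientation contrast of two angles has different head
        # orientations in the two classes -> rejected before any fitting
        with pytest.raises(hb.BalanceError):
            hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 90),
                                 train_orientations=(0,), n_resamples=1)

    def test_full_circle_pooling_is_balanced(self):
        """Pooling all 8 orientations balances any angle pair by construction."""
        for pair in [(0, 90), (45, -45), (0, 180)]:
            classes = {
                a: [(c.head_orientation, c.body_orientation)
                    for c in hb.monkey_conditions("P1", "MC", angles=(a,))]
                for a in pair
            }
            hb.check_balance(classes)


class TestDecodeAnglePair:
    def test_conjunctive_population_decodable(self, conjunctive_pop_0180):
        res = hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 180),
                                   n_resamples=5, seed=1)
        assert res.mean > 0.9

    def test_additive_population_at_chance(self, additive_pop_0180):
        res = hb.decode_angle_pair(additive_pop_0180, angles=(0, 180),
                                   n_resamples=10, seed=1)
        assert abs(res.mean - 0.5) < 0.12

    def test_seed_determinism_and_pairing(self, conjunctive_pop_0180):
        a = hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 180),
                                 n_resamples=4, seed=9, n_units=20)
        b = hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 180),
                                 n_resamples=4, seed=9, n_units=20)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_subject_balanced_subsampling_errors(self, conjunctive_pop_0180):
        with pytest.raises(ValueError):
            hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 180),
                                 n_units=61, n_resamples=1)  # not divisible
        with pytest.raises(ValueError):
            hb.decode_angle_pair(conjunctive_pop_0180[:10], angles=(0, 180),
                                 n_units=60, n_resamples=1)  # too few units

    def test_cross_centering_not_above_within(self):
        """Generalizing across centering cannot beat within-centering decoding."""
        grid = (hb.monkey_conditions("P1", "MC", angles=(0, 180))
                + hb.monkey_conditions("P1", "HC", angles=(0, 180)))
        pop = hb.decoding_population(n_units=40, w_conj=1.0, c_tol=0.5,
                                     seed=30, grid=grid)
        within = hb.decode_angle_pair(pop, angles=(0, 180), train_centering="MC",
                                      n_resamples=8, seed=2)
        across = hb.decode_angle_pair(pop, angles=(0, 180), train_centering="MC",
                                      test_centering="HC", n_resamples=8, seed=2)
        assert across.mean <= within.mean + 0.05

    def test_cross_orientation_generalization(self):
        """A conjunctive code generalizes from '+' to 'x' orientations."""
        pop = hb.decoding_population(n_units=60, w_conj=1.0, seed=31)
        res = hb.decode_angle_pair(pop, angles=(0, 180),
                                   train_orientations=hb.PLUS_ORIENTATIONS,
                                   test_orientations=hb.CROSS_ORIENTATIONS,
                                   n_resamples=8, seed=3)
        assert res.mean > 0.6


class TestNullsAndComparison:
    def test_binary_null_centered_at_chance(self, additive_pop_0180):
        nulls = hb.permutation_null(hb.decode_angle_pair, n_runs=60, seed=5,
                                    units=additive_pop_0180, angles=(0, 180))
        assert abs(nulls.mean() - 0.5) < 3 * nulls.std() / np.sqrt(len(nulls)) + 0.02

    def test_compare_identical_specs(self, conjunctive_pop_0180):
        a = hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 180),
                                 n_resamples=20, seed=6, n_units=20)
        b = hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 180),
                                 n_resamples=20, seed=6, n_units=20)
        assert hb.compare_decodings(a, b) == pytest.approx(0.5)

    def test_compare_swap_symmetry(self, conjunctive_pop_0180, additive_pop_0180):
        a = hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 180),
                                 n_resamples=10, seed=7)
        b = hb.decode_angle_pair(additive_pop_0180, angles=(0, 180),
                                 n_resamples=10, seed=7)
        assert hb.compare_decodings(a, b) == pytest.approx(
            1 - hb.compare_decodings(b, a))

    def test_compare_requires_matched_lengths(self, conjunctive_pop_0180):
        a = hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 180),
                                 n_resamples=4, seed=8)
        b = hb.decode_angle_pair(conjunctive_pop_0180, angles=(0, 180),
                                 n_resamples=5, seed=8)
        with pytest.raises(ValueError):
            hb.compare_decodings(a, b)


class TestOrientationDecoding:
    def test_upright_high_accuracy_and_inversion_effect(self):
        grid = (hb.monkey_conditions("P1", "MC", angles=(0,))
                + hb.monkey_conditions("P1", "MC", angles=(0,),
                                       inversion="inverted"))
        pop = hb.decoding_population(n_units=80, w_conj=0.5, a_inv=0.5,
                                     seed=40, grid=grid, gain=40.0)
        up = hb.decode_orientation(pop, inversion="upright", n_units=60,
                                   n_resamples=20, seed=4)
        inv = hb.decode_orientation(pop, inversion="inverted", n_units=60,
                                    n_resamples=20, seed=4)
        assert up.n_classes == 8
        assert up.mean > 0.8
        assert inv.mean < up.mean
        diffs = hb.inversion_difference(up, inv, block=10)
        assert np.all(diffs > 0)

    def test_too_few_units_rejected(self, conjunctive_pop_0180):
        with pytest.raises(ValueError):
            hb.decode_orientation(conjunctive_pop_0180[:10], n_units=60,
                                  n_resamples=1)


class TestSumDecoding:
    def test_sums_require_isolated_parts(self, conjunctive_pop_0180):
        # population lacks isolated-part conditions
        with pytest.raises(ValueError):
            hb.decode_from_sums(conjunctive_pop_0180, n_resamples=1)


class TestNeuronDropping:
    def test_identical_units_contribute_comparably(self):
        """Units with identical recordings are exchangeable: leave-one-out
        contributions are all small and mutually similar (they differ only
        through resampling noise of the trial assembly)."""
        grid = hb.monkey_conditions("P1", "MC", angles=(0, 180))
        params = hb.TuningParams(kappa_head=2, kappa_body=2, w_conj=1.0,
                                 gain=60, baseline=5)
        pop = [hb.simulate_unit(params, grid, seed=50, unit_id=f"u{i}",
                                subject="M1" if i % 2 else "M2")
               for i in range(8)]  # same params, same counts
        res = hb.neuron_dropping(pop, n_resamples=5, seed=0,
                                 curve_sizes=[2, 4, 8])
        assert np.abs(res.contributions - res.contributions.mean()).max() < 0.1
        assert np.ptp(res.curve_accuracies) < 0.2

    def test_top_roster_enriched_for_conjunctive_units(self):
        """With 20 uninformative and 5 strongly conjunctive units, the
        top-5 contribution roster is enriched for the conjunctive units
        well above their 0.2 base rate.  (Not every conjunctive unit
        contributes positively -- redundant or contrast-irrelevant tuning
        can even hurt -- so enrichment, not purity, is the check.)"""
        grid = hb.monkey_conditions("P1", "MC", angles=(0, 180))
        flat = hb.TuningParams(gain=0.0, baseline=10.0)
        pop = [hb.simulate_unit(flat, grid, seed=100 + i, unit_id=f"flat{i}",
                                subject=("M1", "M2")[i % 2]) for i in range(20)]
        conj = hb.decoding_population(n_units=5, w_conj=1.0, seed=41, grid=grid,
                                      gain=100.0)
        for i, u in enumerate(conj):
            u.unit_id = f"conj{i}"
        res = hb.neuron_dropping(pop + conj, n_resamples=10, seed=1, top_k=5,
                                 curve_sizes=[5, 25])
        flags = {u.unit_id: u.unit_id.startswith("conj") for u in pop + conj}
        assert res.top_fraction(flags) >= 0.6
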