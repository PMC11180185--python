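"""Event space, ordering validity, and the model likelihoods."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ordsustain as osn
from ordsustain.sequences import stage_loglik_matrix

from conftest import all_valid_sequences


def random_valid_sequence(rng, regions, max_level):
    labels = [r for r in regions for _ in range(max_level)]
    rng.shuffle(labels)
    counts = {r: 0 for r in regions}
    events = []
    for r in labels:
        counts[r] += 1
        events.append((r, counts[r]))
    return osn.EventSequence(tuple(events))


class TestValidityAndCounting:
    def test_chain_order_enforced_at_construction(self):
        with pytest.raises(ValueError):
            osn.EventSequence((("A", 2), ("A", 1), ("B", 1), ("B", 2)))

    def test_non_permutation_rejected(self):
        assert not osn.is_valid_sequence((("A", 1), ("A", 1), ("B", 1), ("B", 2)))

    @pytest.mark.parametrize(
        "R,Z,expected",
        [(2, 2, 6), (3, 2, 90), (2, 1, 2)],
    )
    def test_count_matches_enumeration(self, R, Z, expected):
        regions = [chr(65 + i) for i in range(R)]
        assert osn.count_valid_sequences(R, Z) == expected
        assert len(all_valid_sequences(regions, Z)) == expected

    def test_full_event_space_count_exact_integer(self):
        # 10 regions x 4 transitions: 40!/(4!)^10, exact arithmetic
        expected = math.factorial(40) // math.factorial(4) ** 10
        assert osn.count_valid_sequences(10, 4) == expected


class TestImpliedScores:
    def test_stage_zero_and_stage_K_extremes(self):
        seq = osn.EventSequence((("A", 1), ("B", 1), ("A", 2), ("B", 2)))
        assert np.array_equal(osn.implied_scores(seq, 0), [0, 0])
        assert np.array_equal(osn.implied_scores(seq, 4), [2, 2])

    def test_intermediate_stage(self):
        seq = osn.EventSequence((("A", 1), ("B", 1), ("A", 2), ("B", 2)))
        assert np.array_equal(osn.implied_scores(seq, 2), [1, 1])

    def test_out_of_range_stage_rejected(self):
        seq = osn.EventSequence((("A", 1), ("B", 1)))
        with pytest.raises(ValueError):
            osn.implied_scores(seq, 3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_stage_for_random_valid_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_valid_sequence(rng, ["A", "B", "C"], 3)
        prev = osn.implied_scores(seq, 0)
        for k in range(1, seq.n_events + 1):
            cur = osn.implied_scores(seq, k)
            assert (cur >= prev).all()
            prev = cur


class TestLikelihoods:
    def test_all_missing_subject_constant_over_stages(self):
        row = np.full((2, 2), 0.5)  # R=2, Z=1, uniform
        seq = osn.EventSequence((("A", 1), ("B", 1)))
        for k in range(3):
            assert osn.stage_likelihood(row, seq, k) == pytest.approx(0.25)

    def test_one_hot_subject_at_implied_stage(self):
        seq = osn.EventSequence((("A", 1), ("B", 1)))
        row = np.array([[0.0, 1.0], [1.0, 0.0]])  # A at 1, B at 0 -> stage 1
        assert osn.stage_likelihood(row, seq, 1) == pytest.approx(1.0)

    def test_hand_computed_product(self):
        seq = osn.EventSequence((("A", 1), ("B", 1)))
        row = np.array([[0.9, 0.1], [0.6, 0.4]])
        assert osn.stage_likelihood(row, seq, 1) == pytest.approx(0.06)

    def test_marginal_is_prior_weighted_stage_sum(self):
        seq = osn.EventSequence((("A", 1), ("B", 1)))
        row = np.array([[0.9, 0.1], [0.6, 0.4]])
        prior = np.full(3, 1 / 3)
        expected = (0.9 * 0.6 + 0.06 + 0.1 * 0.4) / 3
        assert osn.subject_marginal_likelihood(row, seq, prior) == pytest.approx(
            expected, abs=1e-12
        )

    def test_point_mass_prior_recovers_stage_likelihood(self):
        seq = osn.EventSequence((("A", 1), ("B", 1)))
        row = np.array([[0.0, 1.0], [1.0, 0.0]])
        prior = np.array([0.0, 1.0, 0.0])
        assert osn.subject_marginal_likelihood(row, seq, prior) == pytest.approx(1.0)

    def test_unnormalised_prior_rejected(self):
        seq = osn.EventSequence((("A", 1), ("B", 1)))
        with pytest.raises(ValueError):
            osn.subject_marginal_likelihood(np.full((2, 2), 0.5), seq, np.array([1.0, 1.0, 1.0]))


class TestMixture:
    def _cube(self, seed=0, n=3, regions=("A", "B"), max_level=1):
        rng = np.random.default_rng(seed)
        prob = rng.random((n, len(regions), max_level + 1))
        prob /= prob.sum(axis=2, keepdims=True)
        return osn.ScoreProbabilityCube(
            prob, [f"s{i}" for i in range(n)], list(regions), 0.5
        )

    def test_single_subtype_equals_summed_marginals(self, small_cube):
        seq = osn.EventSequence(
            (("A", 1), ("B", 1), ("C", 1), ("A", 2), ("B", 2), ("C", 2))
        )
        model = osn.SubtypeModel(sequences=[seq], fractions=np.array([1.0]))
        prior = osn.uniform_stage_prior(6)
        expected = sum(
            np.log(
                osn.subject_marginal_likelihood(
                    small_cube.prob[j][[0, 1, 2]], seq, prior
                )
            )
            for j in range(small_cube.n_subjects)
        )
        assert osn.mixture_loglikelihood(small_cube, model) == pytest.approx(
            expected, abs=1e-10
        )

    def test_duplicating_a_subtype_leaves_value_unchanged(self, small_cube):
        seq = osn.EventSequence(
            (("A", 1), ("B", 1), ("C", 1), ("A", 2), ("B", 2), ("C", 2))
        )
        single = osn.SubtypeModel(sequences=[seq], fractions=np.array([1.0]))
        split = osn.SubtypeModel(
            sequences=[seq, seq], fractions=np.array([0.3, 0.7])
        )
        assert osn.mixture_loglikelihood(small_cube, split) == pytest.approx(
            osn.mixture_loglikelihood(small_cube, single), abs=1e-10
        )

    def test_matches_exhaustive_enumeration_oracle(self):
        # brute force: sum over all subtypes and stages per subject
        cube = self._cube(seed=1)
        seq_a = osn.EventSequence((("A", 1), ("B", 1)))
        seq_b = osn.EventSequence((("B", 1), ("A", 1)))
        model = osn.SubtypeModel(
            sequences=[seq_a, seq_b], fractions=np.array([0.4, 0.6])
        )
        prior = osn.uniform_stage_prior(2)
        expected = 0.0
        for j in range(cube.n_subjects):
            tot = 0.0
            for f, seq in zip(model.fractions, model.sequences):
                for k in range(3):
                    implied = osn.implied_scores(seq, k)
                    regs = seq.regions
                    p = 1.0
                    for idx, r in enumerate(regs):
                        p *= cube.prob[j, cube.regions.index(r), implied[idx]]
                    tot += f * prior[k] * p
            expected += np.log(tot)
        assert osn.mixture_loglikelihood(cube, model) == pytest.approx(
            expected, abs=1e-10
        )

    def test_loglik_nonpositive_for_probability_rows(self, small_cube):
        seq = osn.EventSequence(
            (("A", 1), ("B", 1), ("C", 1), ("A", 2), ("B", 2), ("C", 2))
        )
        model = osn.SubtypeModel(sequences=[seq], fractions=np.array([1.0]))
        assert osn.mixture_loglikelihood(small_cube, model) <= 0

    def test_region_relabelling_invariance(self):
        cube = self._cube(seed=2)
        seq = osn.EventSequence((("A", 1), ("B", 1)))
        model = osn.SubtypeModel(sequences=[seq], fractions=np.array([1.0]))
        base = osn.mixture_loglikelihood(cube, model)
        # swap region labels and cube columns consistently
        swapped = osn.ScoreProbabilityCube(
            cube.prob[:, ::-1, :], cube.subject_ids, ["B", "A"], 0.5
        )
        seq2 = osn.EventSequence((("A", 1), ("B", 1)))
        model2 = osn.SubtypeModel(sequences=[seq2], fractions=np.array([1.0]))
        assert osn.mixture_loglikelihood(swapped, model2) == pytest.approx(
            base, abs=1e-12
        )

    def test_empty_cube_is_zero_with_warning(self):
        cube = osn.ScoreProbabilityCube(
            np.empty((0, 2, 2)), [], ["A", "B"], 0.5
        )
        seq = osn.EventSequence((("A", 1), ("B", 1)))
        model = osn.SubtypeModel(sequences=[seq], fractions=np.array([1.0]))
        with pytest.warns(UserWarning):
            assert osn.mixture_loglikelihood(cube, model) == 0.0


class TestKendallDistance:
    def test_identical_zero_reversed_one(self):
        a = osn.EventSequence((("A", 1), ("B", 1)))
        b = osn.EventSequence((("B", 1), ("A", 1)))
        assert osn.kendall_distance(a, a) == 0.0
        assert osn.kendall_distance(a, b) == 1.0

    def test_fast_stage_matrix_agrees_with_definition(self, small_cube):
        seq = osn.EventSequence(
            (("B", 1), ("A", 1), ("C", 1), ("B", 2), ("C", 2), ("A", 2))
        )
        lp = small_cube.log_prob()
        r_idx, z_idx = seq.to_arrays(small_cube.regions)
        mat = stage_loglik_matrix(lp, r_idx, z_idx)
        for j in range(small_cube.n_subjects):
            for k in range(7):
                implied = osn.implied_scores(seq, k)
                direct = sum(
                    lp[j, small_cube.regions.index(r), implied[idx]]
                    for idx, r in enumerate(seq.regions)
                )
                assert mat[j, k] == pytest.approx(direct, abs=1e-10)
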