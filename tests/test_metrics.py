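"""Breadth, meaning-loss, information, and re-ranking statistics."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hypersig as hs
from hypersig.game_space import ValidationError
from hypersig.metrics import speaker_assignment, word_rank_values


def P_rows(*rows):
    return np.asarray(rows, dtype=float)


class TestBreadth:
    def test_identity_uses_all_words(self):
        assert hs.lexical_breadth(np.eye(3)) == 3

    def test_one_word_language(self):
        assert hs.lexical_breadth(P_rows((1, 0, 0), (1, 0, 0), (1, 0, 0))) == 1

    def test_two_word_language(self):
        assert hs.lexical_breadth(P_rows((1, 0, 0), (0, 1, 0), (0, 1, 0))) == 2

    def test_fractions_examples(self):
        all_three = np.broadcast_to(np.eye(3), (4, 3, 3))
        np.testing.assert_array_equal(hs.breadth_fractions(all_three), [0, 0, 1])
        one_word = np.broadcast_to(P_rows((1, 0, 0), (1, 0, 0), (1, 0, 0)), (2, 3, 3))
        mixed = np.concatenate([all_three[:2], one_word])
        np.testing.assert_array_equal(hs.breadth_fractions(mixed), [0.5, 0, 0.5])

    def test_fractions_partition_random_populations(self, rng):
        stack = rng.dirichlet(np.ones(3), size=(30, 3))
        assert hs.breadth_fractions(stack).sum() == pytest.approx(1.0)


class TestPopulationAverage:
    def test_identical_agents(self):
        P0, Q0 = hs.initial_matrices()
        S, L = hs.population_average(
            np.broadcast_to(P0, (6, 3, 3)), np.broadcast_to(Q0, (6, 3, 5))
        )
        np.testing.assert_array_equal(S, P0)
        np.testing.assert_array_equal(L, Q0)

    def test_entrywise_mean_and_stochastic_rows(self, rng):
        stack = rng.dirichlet(np.ones(3), size=(10, 3))
        S, _ = hs.population_average(stack, rng.dirichlet(np.ones(5), size=(10, 3)))
        np.testing.assert_allclose(S, stack.mean(axis=0))
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-12)


class TestMeaningLoss:
    def test_initial_language_has_no_loss(self):
        P0, Q0 = hs.initial_matrices()
        assert hs.meaning_loss_speaker(P0) == 0.0
        assert hs.meaning_loss_listener(Q0) == 0.0

    def test_uniform_limits(self):
        assert hs.meaning_loss_speaker(np.full((3, 3), 1 / 3)) == pytest.approx(2 / 3)
        assert hs.meaning_loss_listener(np.full((3, 5), 1 / 5)) == pytest.approx(4 / 5)

    def test_one_word_population_hits_speaker_bound(self):
        S = P_rows((1, 0, 0), (1, 0, 0), (1, 0, 0))
        assert hs.meaning_loss_speaker(S) == pytest.approx(2 / 3)

    def test_listener_collapse_to_middle_action(self):
        L = np.zeros((3, 5))
        L[:, 2] = 1.0  # every word heard as 1/2: only word y is "original"
        assert hs.meaning_loss_listener(L) == pytest.approx(2 / 3)

    def test_mutation_draw_limits(self, rng):
        n = 20_000
        S = rng.dirichlet(np.ones(3), size=(n, 3)).mean(axis=0)
        L = rng.dirichlet(np.ones(5), size=(n, 3)).mean(axis=0)
        assert hs.meaning_loss_speaker(S) == pytest.approx(2 / 3, abs=0.02)
        assert hs.meaning_loss_listener(L) == pytest.approx(4 / 5, abs=0.02)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValidationError):
            hs.meaning_loss_speaker(np.full((3, 4), 0.25))
        with pytest.raises(ValidationError):
            hs.meaning_loss_listener(np.eye(3))


class TestListenerPosteriorAndInformation:
    def test_identity_language_is_unambiguous(self):
        p = np.full(3, 1 / 3)
        post = hs.listener_posterior(np.eye(3), p)
        np.testing.assert_allclose(post, np.eye(3))
        for j in range(3):
            assert hs.kl_information(post[:, j], p) == pytest.approx(np.log(3))

    def test_uninformative_word_matches_prior(self):
        p = np.array([0.5, 0.3, 0.2])
        S = np.broadcast_to(np.full(3, 1 / 3), (3, 3))  # same usage in every state
        post = hs.listener_posterior(S, p)
        np.testing.assert_allclose(post[:, 0], p)
        assert hs.kl_information(post[:, 0], p) == pytest.approx(0.0, abs=1e-15)

    def test_partial_pooling_column(self):
        S = P_rows((0.5, 0.5, 0), (0.5, 0.5, 0), (0, 0, 1))
        post = hs.listener_posterior(S, np.full(3, 1 / 3))
        np.testing.assert_allclose(post[:, 0], [0.5, 0.5, 0.0])

    def test_unused_word_flagged_not_raised(self):
        S = P_rows((1, 0, 0), (1, 0, 0), (1, 0, 0))
        post = hs.listener_posterior(S, np.full(3, 1 / 3))
        assert np.all(np.isnan(post[:, 1]))
        assert np.isnan(hs.kl_information(post[:, 1], np.full(3, 1 / 3)))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_information_nonnegative(self, seed):
        gen = np.random.default_rng(seed)
        q = gen.dirichlet(np.ones(3))
        p = gen.dirichlet(np.ones(3))
        assert hs.kl_information(q, p) >= 0.0


class TestSwapEvents:
    def test_static_assignment(self):
        S = np.eye(3)
        assert hs.speaker_swap_events(S, S) == 0

    def test_single_pair_reversal(self):
        S0 = np.eye(3)                       # states use words (x, y, z)
        S1 = P_rows((0, 1, 0), (1, 0, 0), (0, 0, 1))  # words x and y trade places
        assert hs.speaker_swap_events(S0, S1) == 1

    def test_word_leaving_ranking_is_not_a_swap(self):
        S0 = np.eye(3)
        S1 = P_rows((1, 0, 0), (1, 0, 0), (0, 0, 1))  # y leaves; x now covers two states
        assert hs.speaker_swap_events(S0, S1) == 0

    def test_full_reversal_counts_all_pairs_and_collapse(self):
        S0 = np.eye(3)
        S1 = S0[::-1].copy()
        assert hs.speaker_swap_events(S0, S1) == 3
        assert hs.speaker_swap_events(S0, S1, collapse=True) == 1

    def test_rank_values(self):
        assign = speaker_assignment(P_rows((1, 0, 0), (1, 0, 0), (0, 0, 1)))
        ranks = word_rank_values(assign, 3)
        assert ranks[0] == pytest.approx(0.5)
        assert np.isnan(ranks[1]) and ranks[2] == 2.0

    def test_listener_hamming(self):
        L0 = np.zeros((3, 5))
        L0[0, 0] = L0[1, 2] = L0[2, 4] = 1.0
        assert hs.listener_swap_events(L0, L0) == 0
        L1 = L0.copy()
        L1[1] = 0.0
        L1[1, 3] = 1.0
        assert hs.listener_swap_events(L0, L1) == 1
        assert hs.listener_swap_events(L0, L0[::-1].copy()) == 2  # middle row unchanged

    def test_swap_rate_arithmetic(self, catalog):
        cfg = hs.SimConfig(game=catalog[0], generations=20, record_every=1, N=10, seed=0)
        log = hs.run_realization(cfg)
        assert hs.swap_rate(log, "speaker") == pytest.approx(
            log.frame["swap_speaker"].iloc[1:].sum() / 20
        )
        thinned = hs.run_realization(
            hs.SimConfig(game=catalog[0], generations=20, record_every=5, N=10, seed=0)
        )
        with pytest.raises(ValidationError):
            hs.swap_rate(thinned)


class TestRerankRate:
    def test_constant_table(self):
        table = pd.DataFrame({"w1": [5, 5, 5], "w2": [3, 3, 3]})
        assert hs.rerank_rate_from_frequency_table(table) == 0.0

    def test_single_swap_over_ten_transitions(self):
        w1 = [10] * 5 + [1] * 6
        w2 = [1] * 5 + [10] * 6
        table = pd.DataFrame({"w1": w1, "w2": w2})
        assert hs.rerank_rate_from_frequency_table(table) == pytest.approx(0.1)

    def test_row_scaling_invariance(self, rng):
        values = rng.uniform(0.1, 5.0, size=(8, 4))
        base = hs.rerank_rate_from_frequency_table(pd.DataFrame(values))
        scaled = values * rng.uniform(0.5, 10.0, size=(8, 1))
        assert hs.rerank_rate_from_frequency_table(pd.DataFrame(scaled)) == base

    def test_all_zero_rows_skipped(self):
        table = pd.DataFrame({"w1": [5, 0, 1], "w2": [1, 0, 5]})
        # the zero row is dropped: one transition remains, with one reversal
        assert hs.rerank_rate_from_frequency_table(table) == pytest.approx(1.0)

    def test_reads_tsv(self, tmp_path):
        path = tmp_path / "freqs.tsv"
        path.write_text("time\tvery\tso\n1900\t10\t2\n1950\t3\t8\n2000\t9\t4\n")
        assert hs.rerank_rate_from_frequency_table(path) == pytest.approx(1.0)

    def test_needs_two_time_points(self):
        with pytest.raises(ValidationError):
            hs.rerank_rate_from_frequency_table(pd.DataFrame({"w": [1.0]}))
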