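"""Column-state alphabet, substitution matrix, Smith-Waterman prefilter."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from _oracles import smith_waterman_bruteforce
from coemit.align import pair_forward
from coemit.alphabet import (
    AlphabetError,
    ColumnStateAlphabet,
    FLOOR_BITS,
    StateSequence,
    discretize,
    prefilter_pairs,
    smith_waterman,
    state_substitution_matrix,
    train_alphabet,
)
from coemit.model import N_AA, default_background
from coemit.simulate import make_toy_hmms


def _point_mass_alphabet(k=20, scale=2.0):
    profiles = np.eye(N_AA)[:k]
    uniform = np.full(N_AA, 1 / 20)
    matrix = state_substitution_matrix(profiles, uniform, scale)
    return ColumnStateAlphabet(profiles, matrix, scale=scale,
                               background=uniform)


class TestTrainAlphabet:
    def test_k1_is_sqrt_mean_profile(self, rng):
        """With one cluster the state is the (Hellinger) mean profile."""
        columns = rng.dirichlet(np.ones(N_AA), size=30)
        alpha = train_alphabet(columns, K=1, seed=0)
        mean_sqrt = np.sqrt(columns).mean(axis=0) ** 2
        expected = mean_sqrt / mean_sqrt.sum()
        np.testing.assert_allclose(alpha.state_profiles[0], expected,
                                   atol=1e-9)

    def test_two_separated_clusters_recovered(self, rng):
        """K=2 centroids match per-cluster means found by true assignment."""
        a = np.zeros(N_AA)
        a[:3] = [0.6, 0.3, 0.1]
        b = np.zeros(N_AA)
        b[-3:] = [0.1, 0.3, 0.6]
        cols = np.vstack(
            [a + rng.random(N_AA) * 0.01 for _ in range(10)]
            + [b + rng.random(N_AA) * 0.01 for _ in range(10)]
        )
        cols /= cols.sum(axis=1, keepdims=True)
        alpha = train_alphabet(cols, K=2, seed=0)
        expected = []
        for group in (cols[:10], cols[10:]):
            m = np.sqrt(group).mean(axis=0) ** 2
            expected.append(m / m.sum())
        got = sorted(alpha.state_profiles, key=lambda p: p[0])
        want = sorted(expected, key=lambda p: p[0])
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_too_few_columns_advises_smaller_k(self, rng):
        columns = rng.dirichlet(np.ones(N_AA), size=5)
        with pytest.raises(AlphabetError, match="smaller K"):
            train_alphabet(columns, K=10)

    def test_deterministic_under_seed(self, rng):
        columns = rng.dirichlet(np.ones(N_AA), size=60)
        a1 = train_alphabet(columns, K=8, seed=3)
        a2 = train_alphabet(columns, K=8, seed=3)
        np.testing.assert_array_equal(a1.state_profiles, a2.state_profiles)
        np.testing.assert_array_equal(a1.subst_matrix, a2.subst_matrix)


class TestSubstitutionMatrix:
    def test_identical_point_mass_uniform_background(self):
        """Same-residue point masses, uniform f, scale 1 -> round(log2 20)."""
        uniform = np.full(N_AA, 1 / 20)
        profiles = np.eye(N_AA)[:2]
        S = state_substitution_matrix(profiles, uniform, scale=1.0)
        assert S[0, 0] == round(math.log2(20)) == 4

    def test_background_state_scores_zero(self):
        f = default_background()
        S = state_substitution_matrix(np.vstack([f, f]), f, scale=1.0)
        assert S[0, 1] == 0

    def test_orthogonal_point_masses_floored(self):
        uniform = np.full(N_AA, 1 / 20)
        S = state_substitution_matrix(np.eye(N_AA), uniform, scale=2.0)
        assert S[0, 1] == round(2.0 * FLOOR_BITS)

    def test_matches_double_loop_recomputation(self, rng):
        profiles = rng.dirichlet(np.ones(N_AA), size=7)
        f = default_background()
        scale = 2.0
        S = state_substitution_matrix(profiles, f, scale)
        assert np.array_equal(S, S.T)
        for a in range(7):
            for b in range(7):
                odds = sum(
                    profiles[a, x] * profiles[b, x] / f[x] for x in range(N_AA)
                )
                assert S[a, b] == round(scale * math.log2(odds))


class TestDiscretize:
    def test_self_column_maps_to_own_state(self, rng):
        profiles = rng.dirichlet(np.ones(N_AA), size=10)
        f = default_background()
        alpha = ColumnStateAlphabet(
            profiles, state_substitution_matrix(profiles, f), background=f
        )
        (model,) = make_toy_hmms(1, 4, seed=0)
        model.match_emissions[2] = profiles[7]
        seq = discretize(model, alpha)
        assert len(seq) == model.length
        assert seq.states[2] == 7

    def test_matches_exhaustive_argmax(self, rng):
        profiles = rng.dirichlet(np.ones(N_AA), size=12)
        f = default_background()
        alpha = ColumnStateAlphabet(
            profiles, state_substitution_matrix(profiles, f), background=f
        )
        (model,) = make_toy_hmms(1, 9, seed=2)
        seq = discretize(model, alpha)
        for i in range(model.length):
            scores = [
                math.log2(np.sum(model.match_emissions[i] * profiles[k] / f))
                for k in range(12)
            ]
            assert seq.states[i] == int(np.argmax(scores))


class TestSmithWaterman:
    def test_identical_sequences_score_n_times_diagonal(self):
        alpha = _point_mass_alphabet()
        d = alpha.subst_matrix[3, 3]
        seq = StateSequence("x", [3] * 7)
        assert smith_waterman(seq, seq, alpha) == 7 * d

    def test_disjoint_letter_sets_score_zero(self):
        alpha = _point_mass_alphabet()
        s1 = StateSequence("a", [0, 1, 2])
        s2 = StateSequence("b", [10, 11, 12])
        assert smith_waterman(s1, s2, alpha) == 0

    def test_empty_sequence_scores_zero(self):
        alpha = _point_mass_alphabet()
        assert smith_waterman(StateSequence("a", []),
                              StateSequence("b", [1, 2]), alpha) == 0

    def test_matches_bruteforce_enumeration(self, rng):
        profiles = rng.dirichlet(np.full(N_AA, 0.3), size=6)
        f = default_background()
        alpha = ColumnStateAlphabet(
            profiles, state_substitution_matrix(profiles, f), background=f
        )
        for _ in range(25):
            a = rng.integers(0, 6, size=rng.integers(1, 6))
            b = rng.integers(0, 6, size=rng.integers(1, 6))
            got = smith_waterman(a, b, alpha, gap_open=6, gap_extend=1)
            want = smith_waterman_bruteforce(a, b, alpha.subst_matrix, 6, 1)
            assert got == want, (a, b)

    def test_symmetry(self, rng):
        profiles = rng.dirichlet(np.ones(N_AA), size=8)
        f = default_background()
        alpha = ColumnStateAlphabet(
            profiles, state_substitution_matrix(profiles, f), background=f
        )
        for _ in range(10):
            a = rng.integers(0, 8, size=12)
            b = rng.integers(0, 8, size=9)
            assert smith_waterman(a, b, alpha) == smith_waterman(b, a, alpha)


class TestPrefilterPairs:
    @pytest.fixture()
    def library(self, rng):
        alpha = _point_mass_alphabet()
        seqs = [
            StateSequence(f"m{i}", rng.integers(0, 20, size=15))
            for i in range(5)
        ]
        return alpha, seqs

    def test_threshold_zero_keeps_all_pairs(self, library):
        alpha, seqs = library
        keep = prefilter_pairs(seqs, alpha, "threshold", 0.0)
        assert len(keep) == 25

    def test_topn_full_keeps_all_pairs(self, library):
        alpha, seqs = library
        keep = prefilter_pairs(seqs, alpha, "topN", len(seqs) - 1)
        assert len(keep) == 25

    def test_output_symmetric_and_reflexive(self, library):
        alpha, seqs = library
        keep = prefilter_pairs(seqs, alpha, "threshold", 50.0)
        for i in range(5):
            assert (i, i) in keep
        for i, j in keep:
            assert (j, i) in keep

    def test_invalid_mode_rejected(self, library):
        alpha, seqs = library
        with pytest.raises(AlphabetError, match="mode"):
            prefilter_pairs(seqs, alpha, "best", 1)


class TestPrefilterSignal:
    def test_sw_scores_track_coemission_scores(self, rng):
        """Spearman correlation between prefilter and full scores > 0.5."""
        base = make_toy_hmms(3, 25, seed=21)
        library = []
        for fam, model in enumerate(base):
            for rep in range(3):
                noisy = model.match_emissions + rng.dirichlet(
                    np.ones(N_AA), size=model.length
                ) * 0.15
                noisy /= noisy.sum(axis=1, keepdims=True)
                m = make_toy_hmms(1, 25, seed=500 + fam * 3 + rep)[0]
                m.match_emissions = noisy
                m.name = f"fam{fam}_{rep}"
                library.append(m.validate())
        columns = np.vstack([m.match_emissions for m in library])
        alpha = train_alphabet(columns, K=40, seed=0)
        seqs = [discretize(m, alpha) for m in library]
        sw, full = [], []
        for i in range(len(library)):
            for j in range(i + 1, len(library)):
                sw.append(smith_waterman(seqs[i], seqs[j], alpha))
                full.append(pair_forward(library[i], library[j]).forward_bits)
        rho = spearmanr(sw, full).statistic
        assert rho > 0.5, rho

    def test_finer_alphabets_fit_columns_no_worse(self, rng):
        """Mean co-emission of columns with their state grows with K."""
        columns = rng.dirichlet(np.full(N_AA, 0.4), size=300)
        f = default_background()
        means = []
        for K in (1, 8, 64):
            alpha = train_alphabet(columns, K=K, seed=0)
            odds = (columns / f) @ alpha.state_profiles.T
            means.append(np.log2(odds.max(axis=1)).mean())
        assert means[0] <= means[1] <= means[2]
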