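import itertools

import numpy as np
import pytest

from actichain.chmm import (
    CHMM,
    LabeledSequence,
    forward_loglik,
    train_level1,
    train_level2,
    viterbi_decode,
)
from actichain.gmm import MixtureModel, fit_gmm_classifier
from actichain.markov import ObservableMarkovModel, estimate_tpm, sample_chain

PERSISTENT_A3 = np.array(
    [[0.85, 0.075, 0.075], [0.075, 0.85, 0.075], [0.075, 0.075, 0.85]]
)
SEPARATED_MEANS = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])


def _index_path(labels):
    return [int(lab[1:]) - 1 for lab in labels]


class TestLevel1:
    def test_tpm_matches_counting_estimator_bit_exact(self, gaussian_sequences):
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 4, 100, seed=0)
        chmm = train_level1(seqs)
        idx_seqs = [_index_path(s.y) for s in seqs]
        np.testing.assert_array_equal(chmm.omm.tpm, estimate_tpm(idx_seqs, 3))

    def test_single_state_data(self):
        X = np.random.default_rng(0).standard_normal((30, 2))
        seq = LabeledSequence(X, np.array(["only"] * 30, dtype=object))
        chmm = train_level1([seq])
        np.testing.assert_array_equal(chmm.omm.tpm, [[1.0]])
        assert len(chmm.emissions) == 1

    def test_parameter_recovery(self, gaussian_sequences):
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 10, 300, seed=1)
        chmm = train_level1(seqs)
        assert np.abs(chmm.omm.tpm - PERSISTENT_A3).max() < 0.05
        for i in range(3):
            assert np.linalg.norm(
                chmm.emissions[i].means[0] - SEPARATED_MEANS[i]
            ) < 0.1  # within 0.1 sigma (unit noise)

    def test_excluded_labels_dropped_from_fits(self, gaussian_sequences):
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 2, 200, seed=2)
        # poison some frames and relabel them as transition/garbage
        for seq in seqs:
            seq.X[:20] = 1e6
            seq.y[:10] = "transition"
            seq.y[10:20] = "garbage"
        chmm = train_level1(seqs)
        assert np.abs(chmm.emissions[0].means[0]).max() < 5.0

    def test_unobserved_state_reported(self, gaussian_sequences):
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 1, 50, seed=3)
        with pytest.raises(ValueError, match="S9"):
            train_level1(seqs, states=("S1", "S2", "S3", "S9"))


class TestLevel2:
    def test_loglik_history_nondecreasing(self, gaussian_sequences):
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 3, 150, seed=4,
                                  noise_sd=2.0)
        chmm = train_level1(seqs)
        _, hist = train_level2(chmm, [s.X for s in seqs], max_iter=15)
        hist = np.array(hist)
        assert len(hist) >= 2
        assert (np.diff(hist) >= -1e-6 * np.abs(hist[:-1])).all()

    def test_fixed_point_after_convergence(self, gaussian_sequences):
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 3, 150, seed=5)
        chmm = train_level1(seqs)
        conv, _ = train_level2(chmm, [s.X for s in seqs], max_iter=200, tol=1e-12)
        again, _ = train_level2(conv, [s.X for s in seqs], max_iter=1)
        assert np.abs(again.omm.tpm - conv.omm.tpm).max() < 1e-6
        assert np.abs(again.omm.priors - conv.omm.priors).max() < 1e-6

    def test_refinement_does_not_worsen_initialization(self, gaussian_sequences):
        """Level-1 from 10% of the labels, level-2 on the rest: the row-wise L1
        distance of A to truth must not grow."""
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 10, 200, seed=6)
        init = train_level1(seqs[:1])
        refined, _ = train_level2(init, [s.X for s in seqs[1:]], max_iter=50)
        err0 = np.abs(init.omm.tpm - PERSISTENT_A3).sum(axis=1).max()
        err1 = np.abs(refined.omm.tpm - PERSISTENT_A3).sum(axis=1).max()
        assert err1 <= err0 + 1e-9

    def test_update_all_reestimates_emissions(self, gaussian_sequences):
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 3, 150, seed=7)
        chmm = train_level1(seqs)
        refined, _ = train_level2(
            chmm, [s.X for s in seqs], update="all", max_iter=5
        )
        assert not np.array_equal(refined.emissions[0].means, chmm.emissions[0].means)

    def test_zero_likelihood_guidance(self, gaussian_sequences):
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 1, 50, seed=8)
        chmm = train_level1(seqs)
        far = np.full((5, 2), 1e200)  # squared distance overflows to -inf logpdf
        with pytest.raises(RuntimeError, match="covariance floor"):
            train_level2(chmm, [far], max_iter=2)


class TestForward:
    def test_length_one_closed_form(self, random_chmm):
        m = random_chmm(3, 2, seed=10)
        x = np.random.default_rng(0).standard_normal((1, 2))
        dens = np.array([mix.density(x)[0] for mix in m.emissions])
        assert forward_loglik(m, x) == pytest.approx(
            np.log(np.dot(m.omm.priors, dens)), abs=1e-12
        )

    def test_matches_path_sum_oracle(self, random_chmm, path_logprob):
        m = random_chmm(2, 2, seed=11)
        X = np.random.default_rng(1).standard_normal((4, 2))
        total = -np.inf
        for path in itertools.product(range(2), repeat=4):
            total = np.logaddexp(total, path_logprob(m, X, path))
        assert forward_loglik(m, X) == pytest.approx(total, abs=1e-9)

    def test_state_duplication_invariance(self, random_chmm):
        m = random_chmm(2, 2, seed=12)
        X = np.random.default_rng(2).standard_normal((6, 2))
        # duplicate both states, halving priors and splitting transitions
        pri2 = np.repeat(m.omm.priors, 2) / 2
        A2 = np.repeat(np.repeat(m.omm.tpm, 2, axis=0), 2, axis=1) / 2
        dup = CHMM(
            ObservableMarkovModel(pri2, A2),
            [m.emissions[0], m.emissions[0], m.emissions[1], m.emissions[1]],
        )
        assert forward_loglik(dup, X) == pytest.approx(
            forward_loglik(m, X), abs=1e-9
        )


class TestViterbi:
    def test_identity_chain_reduces_to_framewise_argmax(self):
        means = SEPARATED_MEANS
        ems = [
            MixtureModel(np.array([1.0]), means[i : i + 1], np.eye(2)[None])
            for i in range(3)
        ]
        m = CHMM(ObservableMarkovModel(np.full(3, 1 / 3), np.eye(3)), ems)
        rng = np.random.default_rng(3)
        X = means[rng.integers(0, 3, 12)] + 0.1 * rng.standard_normal((12, 2))
        # identity A forbids any transition: the path collapses to one state,
        # so test single-state blocks
        for i in range(3):
            Xi = means[i] + 0.1 * rng.standard_normal((5, 2))
            assert (viterbi_decode(m, Xi) == i).all()

    def test_matches_exhaustive_path_search(self, random_chmm, path_logprob):
        m = random_chmm(3, 2, seed=13)
        X = np.random.default_rng(4).standard_normal((6, 2))
        best, best_path = -np.inf, None
        for path in itertools.product(range(3), repeat=6):
            lp = path_logprob(m, X, path)
            if lp > best:
                best, best_path = lp, path
        np.testing.assert_array_equal(viterbi_decode(m, X), best_path)

    def test_left_right_chain_never_moves_backward(self):
        A = np.array([[0.8, 0.2, 0.0], [0.0, 0.8, 0.2], [0.0, 0.0, 1.0]])
        ems = [
            MixtureModel(np.array([1.0]), SEPARATED_MEANS[i : i + 1],
                         np.eye(2)[None] * 4.0)
            for i in range(3)
        ]
        m = CHMM(ObservableMarkovModel(np.array([1.0, 0.0, 0.0]), A), ems)
        rng = np.random.default_rng(5)
        X = rng.normal(3.0, 4.0, (40, 2))  # ambiguous emissions
        path = viterbi_decode(m, X)
        assert (np.diff(path) >= 0).all()

    def test_decoded_path_at_least_as_probable_as_truth(
        self, random_chmm, path_logprob, gaussian_sequences
    ):
        seqs = gaussian_sequences(PERSISTENT_A3, 1.5 * np.eye(3, 2), 5, 40,
                                  seed=14)
        ems = [
            MixtureModel(np.array([1.0]), (1.5 * np.eye(3, 2))[i : i + 1],
                         np.eye(2)[None])
            for i in range(3)
        ]
        m = CHMM(
            ObservableMarkovModel(np.full(3, 1 / 3), PERSISTENT_A3), ems
        )
        for seq in seqs:
            decoded = viterbi_decode(m, seq.X)
            truth = _index_path(seq.y)
            assert path_logprob(m, seq.X, decoded) >= path_logprob(
                m, seq.X, truth
            ) - 1e-9

    def test_rejected_frames_carry_forward_labels(self, random_chmm):
        m = random_chmm(3, 2, seed=15)
        X = np.random.default_rng(6).standard_normal((8, 2))
        mask = np.array([True, False, True, True, False, False, True, False])
        full = viterbi_decode(m, X, mask=mask)
        sub = viterbi_decode(m, X[~mask])
        np.testing.assert_array_equal(full[~mask], sub)
        assert full[0] == full[1]  # leading rejected frame takes first retained
        assert full[2] == full[1] and full[3] == full[1]
        assert full[6] == full[5]

    def test_all_rejected_is_an_error(self, random_chmm):
        m = random_chmm(2, 2, seed=16)
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="all frames rejected"):
            viterbi_decode(m, X, mask=np.ones(3, bool))

    def test_feature_permutation_invariance(self, random_chmm):
        m = random_chmm(3, 4, seed=17)
        X = np.random.default_rng(7).standard_normal((10, 4))
        perm = [2, 0, 3, 1]
        ems_p = [
            MixtureModel(
                e.weights,
                e.means[:, perm],
                e.covariances[:, perm][:, :, perm],
            )
            for e in m.emissions
        ]
        mp = CHMM(m.omm, ems_p)
        assert forward_loglik(mp, X[:, perm]) == pytest.approx(
            forward_loglik(m, X), abs=1e-9
        )
        np.testing.assert_array_equal(
            viterbi_decode(mp, X[:, perm]), viterbi_decode(m, X)
        )


class TestSequentialAdvantage:
    def test_viterbi_beats_framewise_on_persistent_overlapping_data(
        self, gaussian_sequences
    ):
        """With persistent dynamics (diagonal 0.85) and overlapping emissions
        (means 1.5 sigma apart) the sequential decoder must not lose to the
        single-frame argmax on average."""
        means = np.array([[0.0, 0.0], [1.5, 0.0], [0.0, 1.5]])
        hmm_acc, gmm_acc = [], []
        for rep in range(20):
            train = gaussian_sequences(PERSISTENT_A3, means, 3, 150,
                                       seed=100 + rep)
            test = gaussian_sequences(PERSISTENT_A3, means, 1, 150,
                                      seed=900 + rep)[0]
            chmm = train_level1(train, rng_seed=rep)
            truth = np.array(_index_path(test.y))
            hmm_acc.append((viterbi_decode(chmm, test.X) == truth).mean())
            clf = fit_gmm_classifier(
                np.concatenate([s.X for s in train]),
                np.concatenate([s.y for s in train]),
                rng_seed=rep,
            )
            labels, _ = clf.classify(test.X)
            pred = np.array(_index_path(labels))
            gmm_acc.append((pred == truth).mean())
        assert np.mean(hmm_acc) >= np.mean(gmm_acc)

    def test_serialization_roundtrip(self, gaussian_sequences, tmp_path):
        seqs = gaussian_sequences(PERSISTENT_A3, SEPARATED_MEANS, 2, 80, seed=18)
        chmm = train_level1(seqs)
        path = tmp_path / "chmm.json"
        chmm.save(path)
        back = CHMM.load(path)
        X = seqs[0].X[:20]
        assert forward_loglik(back, X) == pytest.approx(
            forward_loglik(chmm, X), abs=1e-12
        )
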