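import numpy as np
import pytest

from actichain.chmm import LabeledSequence
from actichain.evaluation import (
    ConfusionMatrix,
    evaluate,
    loso_split,
    rejection_performance,
)

PERSISTENT_A3 = np.array(
    [[0.85, 0.075, 0.075], [0.075, 0.85, 0.075], [0.075, 0.075, 0.85]]
)
WELL_SEPARATED = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])


def _dataset(gaussian_sequences, n_subjects=3, noise=1.0, seed=0,
             means=WELL_SEPARATED, with_garbage=False):
    rng = np.random.default_rng(seed)
    data = {}
    for s in range(n_subjects):
        seqs = gaussian_sequences(
            PERSISTENT_A3, means, 2, 120, seed=seed * 97 + s,
            noise_sd=noise, subject_id=f"subj{s}",
            mean_shift=rng.normal(0, 0.2, 2),
        )
        if with_garbage:
            for seq in seqs:
                n_g = len(seq) // 4
                pos = rng.choice(len(seq), n_g, replace=False)
                seq.X[pos] = rng.normal(30.0, 1.0, (n_g, 2))
                seq.y[pos] = "garbage"
                seq.spurious = np.zeros(len(seq), bool)
                seq.spurious[pos] = True
        data[f"subj{s}"] = seqs
    return data


class TestLosoSplit:
    @pytest.mark.parametrize("n", [7, 20])
    def test_fold_counts(self, n):
        folds = loso_split([f"s{i}" for i in range(n)])
        assert len(folds) == n

    def test_test_sets_partition_subjects(self):
        subjects = ["a", "b", "c", "d"]
        folds = loso_split(subjects)
        tests = [t for _, t in folds]
        assert sorted(tests) == sorted(subjects)
        for train, test in folds:
            assert test not in train
            assert sorted(train + [test]) == sorted(subjects)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            loso_split(["only"])


class TestRejectionPerformance:
    def test_perfect_flags(self):
        true = np.array([True, True, False, False])
        assert rejection_performance(true, true) == (1.0, 1.0)

    def test_inverted_flags(self):
        true = np.array([True, True, False, False])
        assert rejection_performance(~true, true) == (0.0, 0.0)

    def test_matches_contingency_oracle(self):
        rng = np.random.default_rng(0)
        true = rng.random(500) < 0.3
        pred = rng.random(500) < 0.5
        se, sp = rejection_performance(pred, true)
        tp = (pred & true).sum()
        fn = (~pred & true).sum()
        tn = (~pred & ~true).sum()
        fp = (pred & ~true).sum()
        assert se == pytest.approx(tp / (tp + fn))
        assert sp == pytest.approx(tn / (tn + fp))

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            rejection_performance(np.array([True]), np.array([True]))


class TestEvaluate:
    def test_perfect_separation_gives_unit_accuracy(self, gaussian_sequences):
        data = _dataset(gaussian_sequences, noise=0.1)
        report = evaluate(data, model="gmm", rng_seed=0)
        assert report.mean_accuracy == 1.0
        conf = report.confusion.counts
        assert np.all(conf == np.diag(np.diag(conf)))
        # sequential decoding is near-perfect too (an unseen transition can
        # cost the decoder an isolated frame)
        seq_report = evaluate(data, model="chmm1", rng_seed=0)
        assert seq_report.mean_accuracy > 0.99

    def test_accuracy_equals_trace_over_total(self, gaussian_sequences):
        data = _dataset(gaussian_sequences, noise=2.0, seed=1)
        report = evaluate(data, model="gmm", rng_seed=0)
        conf = report.confusion
        assert conf.accuracy == pytest.approx(np.trace(conf.counts) / conf.total)

    def test_mean_sd_recomputable_from_subject_list(self, gaussian_sequences):
        data = _dataset(gaussian_sequences, noise=2.0, seed=2)
        report = evaluate(data, model="chmm2", rng_seed=0, bw_max_iter=3)
        vals = list(report.per_subject_accuracy.values())
        assert report.mean_accuracy == pytest.approx(np.mean(vals))
        assert report.sd_accuracy == pytest.approx(np.std(vals, ddof=1))

    def test_confusion_total_counts_retained_genuine_frames(
        self, gaussian_sequences
    ):
        data = _dataset(gaussian_sequences, seed=3, with_garbage=True)
        report = evaluate(data, model="gmm", reject=True, rng_seed=0)
        total_frames = sum(len(s) for seqs in data.values() for s in seqs)
        assert report.confusion.total <= total_frames
        assert report.sensitivity is not None and report.sensitivity > 0.9

    def test_rejection_improves_contaminated_accuracy(self, gaussian_sequences):
        data = _dataset(gaussian_sequences, seed=4, with_garbage=True)
        plain = evaluate(data, model="chmm1", reject=False, rng_seed=0)
        rej = evaluate(data, model="chmm1", reject=True, rng_seed=0)
        assert rej.mean_accuracy > plain.mean_accuracy

    def test_no_information_leak_from_test_labels(self, gaussian_sequences):
        """Permuting the held-out subject's labels must not change predictions
        (models and thresholds derive from training folds only)."""
        from actichain import rejection as rj
        from actichain.evaluation import _fit_fold, _select_fold_threshold
        from actichain.chmm import viterbi_decode

        data = _dataset(gaussian_sequences, seed=5, with_garbage=True)
        train = data["subj0"] + data["subj1"]
        test_seq = data["subj2"][0]
        chmm, gmm = _fit_fold(train, "chmm1", 1, 0, 1e-6, None, 5)
        th = _select_fold_threshold(gmm, train)
        logd = gmm.log_density_matrix(test_seq.X)
        mask = rj.rejection_mask(logd, th)
        pred = viterbi_decode(chmm, test_seq.X, mask=mask)
        # permute test labels; refit from the same training data
        rng = np.random.default_rng(0)
        permuted = LabeledSequence(
            test_seq.X, rng.permutation(test_seq.y), test_seq.subject_id,
            test_seq.spurious,
        )
        chmm2, gmm2 = _fit_fold(train, "chmm1", 1, 0, 1e-6, None, 5)
        th2 = _select_fold_threshold(gmm2, train)
        mask2 = rj.rejection_mask(gmm2.log_density_matrix(permuted.X), th2)
        pred2 = viterbi_decode(chmm2, permuted.X, mask=mask2)
        assert th == th2
        np.testing.assert_array_equal(pred, pred2)

    def test_strict_mode_penalizes_rejected_genuine_frames(
        self, gaussian_sequences
    ):
        data = _dataset(gaussian_sequences, seed=6, with_garbage=True)
        default = evaluate(data, model="gmm", reject=True, rng_seed=0)
        strict = evaluate(data, model="gmm", reject=True, strict=True, rng_seed=0)
        assert strict.mean_accuracy <= default.mean_accuracy + 1e-12

    def test_unknown_model_rejected(self, gaussian_sequences):
        data = _dataset(gaussian_sequences, seed=7)
        with pytest.raises(ValueError, match="model"):
            evaluate(data, model="svm")


class TestConfusionMatrix:
    def test_row_sums_are_true_class_counts(self):
        y_true = ["a", "a", "b", "b", "b"]
        y_pred = ["a", "b", "b", "b", "a"]
        conf = ConfusionMatrix.from_predictions(y_true, y_pred, ("a", "b"))
        np.testing.assert_array_equal(conf.counts.sum(axis=1), [2, 3])
        assert conf.accuracy == pytest.approx(3 / 5)

    def test_addition_requires_matching_labels(self):
        c = ConfusionMatrix(("a", "b"), np.eye(2, dtype=int))
        with pytest.raises(ValueError):
            c + ConfusionMatrix(("a", "c"), np.eye(2, dtype=int))
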