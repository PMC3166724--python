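"""Leave-one-subject-out evaluation of the single-frame and sequential classifiers.

Each fold trains on all subjects but one and tests on the held-out subject:
level-1 supervised training (counts + mixture fits), optionally level-2
Baum-Welch refinement, optional rejection-threshold selection on the
*training* folds' ROC, then per-frame classification (GMM) or Viterbi
decoding (cHMM) of the test sequences.

Accuracy conventions: without rejection every frame counts and garbage
frames are always errors (their true label is outside the vocabulary).
With rejection, rejected frames are excluded from the denominator by
default (accuracy "after automatic rejection"); ``strict=True`` instead
counts rejected genuine frames as errors and keeps them in the denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rejection as rej
from .chmm import (
    CHMM,
    EXCLUDED_LABELS,
    LabeledSequence,
    train_level1,
    train_level2,
    viterbi_decode,
)
from .gmm import GMMClassifier

__all__ = [
    "ConfusionMatrix",
    "CVReport",
    "loso_split",
    "rejection_performance",
    "evaluate",
]


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        q = len(self.labels)
        if self.counts.shape != (q, q):
            raise ValueError("counts must be square over the labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels) -> "ConfusionMatrix":
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(tuple(labels), counts)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label sets differ")
        return ConfusionMatrix(self.labels, self.counts + other.counts)


@dataclass
class CVReport:
    """Aggregated LOSO results."""

    per_subject_accuracy: dict[str, float]
    confusion: ConfusionMatrix
    sensitivity: float | None = None
    specificity: float | None = None
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.per_subject_accuracy.values())))

    @property
    def sd_accuracy(self) -> float:
        vals = list(self.per_subject_accuracy.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> str:
        lines = [
            "Leave-one-subject-out report",
            f"  subjects: {len(self.per_subject_accuracy)}",
            f"  accuracy: {100 * self.mean_accuracy:.1f} +/- "
            f"{100 * self.sd_accuracy:.1f} %",
        ]
        if self.sensitivity is not None:
            lines.append(
                f"  rejection Se = {100 * self.sensitivity:.1f} %, "
                f"Sp = {100 * self.specificity:.1f} %"
            )
        lines.append("  confusion matrix (rows = true, cols = predicted):")
        lines.append(self.confusion.to_dataframe().to_string())
        return "\n".join(lines)


def loso_split(subjects) -> list[tuple[list, object]]:
    """One fold per subject: (training subjects, test subject)."""
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [
        ([s for s in subjects if s != test], test) for test in subjects
    ]


def rejection_performance(flags_pred, flags_true) -> tuple[float, float]:
    """(Se, Sp) with spurious as the positive class.

    Se = rejected spurious / all spurious; Sp = retained genuine / all genuine.
    """
    pred = np.asarray(flags_pred, dtype=bool)
    true = np.asarray(flags_true, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("flag arrays must have equal length")
    if true.all() or not true.any():
        raise ValueError("both spurious and genuine frames required in the truth")
    se = float((pred & true).sum() / true.sum())
    sp = float((~pred & ~true).sum() / (~true).sum())
    return se, sp


def _fit_fold(
    train_seqs: list[LabeledSequence],
    model: str,
    n_components: int,
    rng_seed: int,
    reg: float,
    states: tuple | None,
    bw_max_iter: int,
):
    """Train one fold's classifier (and its rejection ROC inputs)."""
    chmm = train_level1(
        train_seqs, n_components=n_components, rng_seed=rng_seed, reg=reg,
        states=states,
    )
    if model == "chmm2":
        # Baum-Welch on the training sequences with known spurious/transition
        # frames removed, pooled across subjects.
        clean = []
        for seq in train_seqs:
            keep = np.array(
                [
                    lab not in EXCLUDED_LABELS
                    and not (seq.spurious is not None and seq.spurious[t])
                    for t, lab in enumerate(seq.y)
                ]
            )
            if keep.any():
                clean.append(seq.X[keep])
        chmm, _ = train_level2(chmm, clean, update="transitions",
                               max_iter=bw_max_iter)
    gmm = GMMClassifier(chmm.omm.state_names, chmm.emissions)
    return chmm, gmm


def _select_fold_threshold(gmm: GMMClassifier, train_seqs) -> float:
    X = np.concatenate([s.X for s in train_seqs])
    flags = np.concatenate(
        [
            s.spurious
            if s.spurious is not None
            else np.zeros(len(s), dtype=bool)
            for s in train_seqs
        ]
    )
    roc = rej.roc_curve(gmm.log_density_matrix(X), flags)
    return rej.select_threshold(roc)


def evaluate(
    dataset: dict[str, list[LabeledSequence]],
    model: str = "chmm2",
    reject: bool = False,
    n_components: int = 1,
    rng_seed: int = 0,
    reg: float = 1e-6,
    strict: bool = False,
    bw_max_iter: int = 20,
    states: tuple | None = None,
    verbose: bool = False,
) -> CVReport:
    """LOSO cross-validation of one classifier variant.

    model: "gmm" (single-frame), "chmm1" (supervised HMM) or "chmm2"
    (supervised + Baum-Welch-refined HMM).
    """
    if model not in ("gmm", "chmm1", "chmm2"):
        raise ValueError("model must be 'gmm', 'chmm1' or 'chmm2'")
    folds = loso_split(dataset.keys())
    rng = np.random.default_rng(rng_seed)
    per_subject: dict[str, float] = {}
    thresholds: dict[str, float] = {}
    confusion: ConfusionMatrix | None = None
    tp = fn = tn = fp = 0
    fold_errors: dict[str, str] = {}
    for train_subjects, test_subject in folds:
        fold_seed = int(rng.integers(2**31 - 1))
        train_seqs = [s for subj in train_subjects for s in dataset[subj]]
        try:
            chmm, gmm = _fit_fold(
                train_seqs, model, n_components, fold_seed, reg, states,
                bw_max_iter,
            )
        except (ValueError, RuntimeError) as exc:
            fold_errors[test_subject] = str(exc)
            continue
        vocab = chmm.omm.state_names
        th = -np.inf
        if reject:
            th = _select_fold_threshold(gmm, train_seqs)
            thresholds[test_subject] = th
        correct = 0
        denom = 0
        fold_conf = ConfusionMatrix(vocab, np.zeros((len(vocab), len(vocab))))
        for seq in dataset[test_subject]:
            logd = gmm.log_density_matrix(seq.X)
            mask = rej.rejection_mask(logd, th) if reject else np.zeros(
                len(seq), dtype=bool
            )
            if mask.all():
                # nothing retained: every frame is an unclassified error
                denom += len(seq)
                continue
            if model == "gmm":
                pred = np.argmax(logd, axis=1)
            else:
                pred = viterbi_decode(chmm, seq.X, mask=mask)
            pred_labels = np.asarray(vocab, dtype=object)[pred]
            true_spur = (
                seq.spurious
                if seq.spurious is not None
                else np.zeros(len(seq), dtype=bool)
            )
            genuine = ~true_spur & np.array([lab in vocab for lab in seq.y])
            if reject:
                tp += int((mask & true_spur).sum())
                fn += int((~mask & true_spur).sum())
                tn += int((~mask & ~true_spur).sum())
                fp += int((mask & ~true_spur).sum())
            retained = ~mask
            hit = genuine & (pred_labels == seq.y)
            if strict and reject:
                # rejected genuine frames stay in the denominator as errors;
                # correctly rejected garbage leaves the denominator
                denom += int((retained | genuine).sum())
                correct += int((hit & retained).sum())
            else:
                denom += int(retained.sum())
                correct += int((hit & retained).sum())
            scored = genuine & retained
            if scored.any():
                fold_conf = fold_conf + ConfusionMatrix.from_predictions(
                    seq.y[scored], pred_labels[scored], vocab
                )
        per_subject[test_subject] = correct / denom if denom else 0.0
        confusion = fold_conf if confusion is None else confusion + fold_conf
        if verbose:
            print(
                f"fold {test_subject}: accuracy "
                f"{100 * per_subject[test_subject]:.1f} %"
            )
    if fold_errors and not per_subject:
        raise RuntimeError(f"all folds failed: {fold_errors}")
    if fold_errors:
        import warnings

        warnings.warn(f"fold failures: {fold_errors}", stacklevel=2)
    se = sp = None
    if reject and (tp + fn) > 0 and (tn + fp) > 0:
        se = tp / (tp + fn)
        sp = tn / (tn + fp)
    return CVReport(per_subject, confusion, se, sp, thresholds)
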