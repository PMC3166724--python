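"""Model/Results interface over the sequential activity classifier.

``ActivityHMM`` holds the training data and configuration; ``fit`` runs the
two-level training and returns an ``ActivityHMMResults`` carrying the
estimated (pi, A), their count-based standard errors, the per-state emission
mixtures, the Baum-Welch log-likelihood history and a ``summary()`` table.
Decoding, rejection-threshold selection and simulation hang off the results
object.
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
    _genuine_index_sequences,
    forward_loglik,
    train_level1,
    train_level2,
    viterbi_decode,
)
from .gmm import GMMClassifier
from .markov import sample_chain

__all__ = ["ActivityHMM", "ActivityHMMResults"]


class ActivityHMM:
    """Sequential activity classifier specification.

    Parameters
    ----------
    sequences : list of LabeledSequence (or (X, y) tuples)
        Labeled training sequences; frames labeled 'transition', 'garbage'
        or 'unknown' are ignored during estimation.
    states : optional explicit state vocabulary/order.
    n_components : mixture components per state (M).
    covariance_reg : eigenvalue floor for emission covariances.
    """

    def __init__(
        self,
        sequences,
        states: tuple | None = None,
        n_components: int = 1,
        covariance_reg: float = 1e-6,
    ) -> None:
        self.sequences = [
            s if isinstance(s, LabeledSequence) else LabeledSequence(*s)
            for s in sequences
        ]
        if not self.sequences:
            raise ValueError("at least one training sequence required")
        self.states = states
        self.n_components = n_components
        self.covariance_reg = covariance_reg

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "activity",
        sequence_col: str | None = "subject",
        feature_cols: list[str] | None = None,
        **kwargs,
    ) -> "ActivityHMM":
        """Build from a long-format frame table (one row per data frame).

        Rows are grouped into sequences by ``sequence_col`` (in row order
        within each group); remaining numeric columns are the features.
        """
        if feature_cols is None:
            feature_cols = [
                c
                for c in df.columns
                if c not in (label_col, sequence_col)
                and pd.api.types.is_numeric_dtype(df[c])
            ]
        seqs = []
        groups = (
            df.groupby(sequence_col, sort=True) if sequence_col else [(None, df)]
        )
        for sid, g in groups:
            seqs.append(
                LabeledSequence(
                    g[feature_cols].to_numpy(float),
                    g[label_col].to_numpy(),
                    None if sid is None else str(sid),
                )
            )
        return cls(seqs, **kwargs)

    def fit(
        self,
        method: str = "two-level",
        max_iter: int = 50,
        tol: float = 1e-6,
        update: str = "transitions",
        seed: int = 0,
    ) -> "ActivityHMMResults":
        """Train the classifier.

        method="supervised" runs level-1 only; "two-level" (default) follows
        with Baum-Welch refinement of the transition parameters.
        """
        if method not in ("supervised", "two-level"):
            raise ValueError("method must be 'supervised' or 'two-level'")
        chmm = train_level1(
            self.sequences,
            n_components=self.n_components,
            rng_seed=seed,
            reg=self.covariance_reg,
            states=self.states,
        )
        # count-based SEs of the level-1 transition estimates
        idx_seqs, _ = _genuine_index_sequences(
            self.sequences, chmm.omm.state_names
        )
        history: list[float] = []
        if method == "two-level":
            clean = []
            for seq in self.sequences:
                keep = np.array(
                    [
                        lab not in EXCLUDED_LABELS
                        and not (seq.spurious is not None and seq.spurious[t])
                        for t, lab in enumerate(seq.y)
                    ]
                )
                if keep.any():
                    clean.append(seq.X[keep])
            chmm, history = train_level2(
                chmm, clean, update=update, max_iter=max_iter, tol=tol,
                reg=self.covariance_reg,
            )
        return ActivityHMMResults(self, chmm, idx_seqs, history, method)


def _transition_counts(idx_seqs, q: int) -> np.ndarray:
    counts = np.zeros((q, q))
    for s in idx_seqs:
        np.add.at(counts, (s[:-1], s[1:]), 1.0)
    return counts


@dataclass
class ActivityHMMResults:
    """Fitted sequential classifier."""

    model: ActivityHMM
    chmm: CHMM
    _idx_seqs: list[np.ndarray]
    loglik_history: list[float] = field(default_factory=list)
    method: str = "two-level"

    @property
    def states(self) -> tuple:
        return self.chmm.omm.state_names

    @property
    def priors(self) -> pd.Series:
        return pd.Series(self.chmm.omm.priors, index=self.states, name="prior")

    @property
    def transition_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(self.chmm.omm.tpm, index=self.states, columns=self.states)

    @property
    def transition_counts(self) -> pd.DataFrame:
        q = len(self.states)
        return pd.DataFrame(
            _transition_counts(self._idx_seqs, q).astype(int),
            index=self.states,
            columns=self.states,
        )

    @property
    def transition_se(self) -> pd.DataFrame:
        """Binomial standard errors sqrt(a*(1-a)/n_i) of the count estimates."""
        counts = self.transition_counts.to_numpy().astype(float)
        n_out = counts.sum(axis=1, keepdims=True)
        a = np.divide(counts, n_out, out=np.zeros_like(counts), where=n_out > 0)
        se = np.sqrt(
            np.divide(a * (1 - a), n_out, out=np.zeros_like(a), where=n_out > 0)
        )
        return pd.DataFrame(se, index=self.states, columns=self.states)

    @property
    def emissions(self):
        return self.chmm.emissions

    def as_gmm_classifier(self) -> GMMClassifier:
        """Single-frame classifier sharing this model's emission mixtures."""
        return GMMClassifier(self.states, self.chmm.emissions)

    def loglik(self, X) -> float:
        """log P(X | model) of a feature sequence."""
        return forward_loglik(self.chmm, X)

    def predict(self, X, reject_threshold: float | None = None) -> np.ndarray:
        """Viterbi-decoded state labels, optionally with spurious rejection."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mask = None
        if reject_threshold is not None:
            logd = self.as_gmm_classifier().log_density_matrix(X)
            mask = rej.rejection_mask(logd, reject_threshold)
        path = viterbi_decode(self.chmm, X, mask=mask)
        return np.asarray(self.states, dtype=object)[path]

    def select_rejection_threshold(self, sequences) -> float:
        """ROC-based threshold from sequences with known spurious flags."""
        gmm = self.as_gmm_classifier()
        X = np.concatenate([s.X for s in sequences])
        flags = np.concatenate(
            [
                s.spurious
                if s.spurious is not None
                else np.zeros(len(s), dtype=bool)
                for s in sequences
            ]
        )
        roc = rej.roc_curve(gmm.log_density_matrix(X), flags)
        return rej.select_threshold(roc)

    def simulate(self, T: int, seed: int = 0) -> LabeledSequence:
        """Sample a feature sequence from the fitted chain and emissions."""
        rng = np.random.default_rng(seed)
        path = sample_chain(self.chmm.omm, T, rng)
        X = np.empty((T, self.chmm.dim))
        for t, s in enumerate(path):
            X[t] = self.chmm.emissions[s].sample(1, rng)
        y = np.asarray(self.states, dtype=object)[path]
        return LabeledSequence(X, y)

    def summary(self) -> str:
        n_frames = sum(len(s) for s in self.model.sequences)
        lines = [
            "Activity cHMM (two-level supervised training)"
            if self.method == "two-level"
            else "Activity cHMM (level-1 supervised training)",
            "=" * 56,
            f"states:            {len(self.states)} "
            f"({', '.join(map(str, self.states))})",
            f"sequences:         {len(self.model.sequences)}",
            f"frames:            {n_frames}",
            f"feature dimension: {self.chmm.dim}",
            f"mixture components per state: {self.model.n_components}",
        ]
        if self.loglik_history:
            lines.append(
                f"Baum-Welch iterations: {len(self.loglik_history)} "
                f"(final log-likelihood {self.loglik_history[-1]:.2f})"
            )
        lines.append("")
        lines.append("Prior probabilities:")
        lines.append(self.priors.round(4).to_string())
        lines.append("")
        lines.append("Transition probability matrix:")
        lines.append(self.transition_matrix.round(4).to_string())
        lines.append("")
        lines.append("Count-based standard errors of the transitions:")
        lines.append(self.transition_se.round(4).to_string())
        return "\n".join(lines)
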