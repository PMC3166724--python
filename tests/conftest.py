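import numpy as np
import pytest

from actichain.chmm import CHMM, LabeledSequence
from actichain.gmm import MixtureModel
from actichain.markov import ObservableMarkovModel, sample_chain


@pytest.fixture
def random_chmm():
    """Factory for a random CHMM with single-Gaussian emissions."""

    def make(q: int, d: int, seed: int = 0) -> CHMM:
        r = np.random.default_rng(seed)
        tpm = r.dirichlet(np.ones(q), q)
        priors = r.dirichlet(np.ones(q))
        emissions = [
            MixtureModel(
                np.array([1.0]),
                r.normal(0.0, 2.0, (1, d)),
                np.eye(d)[None] * (0.5 + r.random()),
            )
            for _ in range(q)
        ]
        return CHMM(ObservableMarkovModel(priors, tpm), emissions)

    return make


@pytest.fixture
def path_logprob():
    """Log-probability of one explicit state path under a CHMM."""

    def score(chmm: CHMM, X: np.ndarray, path) -> float:
        logB = chmm.log_emission_matrix(X)
        with np.errstate(divide="ignore"):
            log_pi = np.log(chmm.omm.priors)
            logA = np.log(chmm.omm.tpm)
        lp = log_pi[path[0]] + logB[0, path[0]]
        for t in range(1, len(path)):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        return float(lp)

    return score


@pytest.fixture
def gaussian_sequences():
    """Factory for labeled sequences from a known 1-Gaussian-per-state cHMM."""

    def make(
        tpm: np.ndarray,
        means: np.ndarray,
        n_seq: int,
        T: int,
        seed: int = 0,
        noise_sd: float = 1.0,
        subject_id=None,
        mean_shift=None,
    ) -> list[LabeledSequence]:
        rng = np.random.default_rng(seed)
        q, d = means.shape
        omm = ObservableMarkovModel(np.full(q, 1.0 / q), tpm)
        shift = np.zeros(d) if mean_shift is None else np.asarray(mean_shift)
        out = []
        for _ in range(n_seq):
            path = sample_chain(omm, T, rng)
            X = means[path] + shift + noise_sd * rng.standard_normal((T, d))
            y = np.array([f"S{i + 1}" for i in path], dtype=object)
            out.append(LabeledSequence(X, y, subject_id))
        return out

    return make
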