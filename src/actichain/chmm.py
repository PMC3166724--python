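"""Continuous-emission HMM: two-level supervised training and Viterbi decoding.

The sequential classifier couples an observable Markov model (pi, A) over
activity states with per-state Gaussian-mixture emission densities over
feature vectors. Training is split in two levels:

* level 1 (supervised): with labeled training sequences, (pi, A) come from
  counting initial states and transitions, and each state's mixture is
  fitted on that state's frames. Frames labeled 'transition', 'garbage' or
  'unknown' (or flagged spurious) are excluded from both counts and fits.
* level 2 (Baum-Welch): EM re-estimation initialized at the level-1
  parameters. By default only the transition parameters (pi, A) are
  refined, with emissions frozen; ``update="all"`` re-estimates the
  emission mixtures as well.

All recursions run in the log domain with log-sum-exp, so long sequences of
low-density frames do not underflow.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import markov
from .gmm import MixtureModel, _floor_covariance, fit_mixture
from .markov import ObservableMarkovModel

__all__ = [
    "CHMM",
    "LabeledSequence",
    "EXCLUDED_LABELS",
    "train_level1",
    "train_level2",
    "forward_loglik",
    "viterbi_decode",
]

#: Frame labels excluded from supervised counting and emission fitting.
EXCLUDED_LABELS = frozenset({"transition", "garbage", "unknown"})


@dataclass
class LabeledSequence:
    """A feature-vector sequence with per-frame state labels.

    ``spurious`` optionally flags frames known to come from outside the
    activity vocabulary (used by rejection training and evaluation).
    """

    X: np.ndarray
    y: np.ndarray
    subject_id: str | None = None
    spurious: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=object)
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("one label per frame required")
        if self.spurious is not None:
            self.spurious = np.asarray(self.spurious, dtype=bool)
            if self.spurious.shape[0] != self.X.shape[0]:
                raise ValueError("one spurious flag per frame required")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class CHMM:
    """(pi, A) plus one emission mixture per state."""

    omm: ObservableMarkovModel
    emissions: list[MixtureModel]

    def __post_init__(self) -> None:
        if len(self.emissions) != self.omm.n_states:
            raise ValueError("one emission model per state required")
        dims = {m.dim for m in self.emissions}
        if len(dims) != 1:
            raise ValueError("all emission models must share the feature dimension")

    @property
    def n_states(self) -> int:
        return self.omm.n_states

    @property
    def dim(self) -> int:
        return self.emissions[0].dim

    def log_emission_matrix(self, X) -> np.ndarray:
        """(T, Q) matrix of log p(x_t | S_i)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError(f"dimension mismatch: {X.shape[1]} != {self.dim}")
        return np.column_stack([m.log_density(X) for m in self.emissions])

    def to_dict(self) -> dict:
        return {
            "omm": self.omm.to_dict(),
            "emissions": [m.to_dict() for m in self.emissions],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CHMM":
        return cls(
            ObservableMarkovModel.from_dict(d["omm"]),
            [MixtureModel.from_dict(m) for m in d["emissions"]],
        )

    @classmethod
    def load(cls, path) -> "CHMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _genuine_index_sequences(
    data: list[LabeledSequence], states: tuple
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-sequence genuine-frame index paths and the matching feature rows."""
    state_to_idx = {s: i for i, s in enumerate(states)}
    idx_seqs, x_seqs = [], []
    for seq in data:
        keep = np.array(
            [
                (lab in state_to_idx)
                and not (seq.spurious is not None and seq.spurious[t])
                for t, lab in enumerate(seq.y)
            ],
            dtype=bool,
        )
        labels = seq.y[keep]
        if labels.size == 0:
            continue
        idx_seqs.append(np.array([state_to_idx[lab] for lab in labels]))
        x_seqs.append(seq.X[keep])
    if not idx_seqs:
        raise ValueError("no genuine labeled frames in the training data")
    return idx_seqs, x_seqs


def train_level1(
    data: list[LabeledSequence],
    n_components: int = 1,
    rng_seed: int = 0,
    reg: float = 1e-6,
    states: tuple | None = None,
) -> CHMM:
    """First-level supervised training from labeled sequences.

    (pi, A) come from counting; per-state emissions are mixture fits on that
    state's frames. Raises if any state in the vocabulary has no frames.
    """
    if states is None:
        observed = set()
        for seq in data:
            observed.update(l for l in seq.y.tolist() if l not in EXCLUDED_LABELS)
        states = tuple(sorted(observed))
    idx_seqs, x_seqs = _genuine_index_sequences(data, states)
    q = len(states)
    all_idx = np.concatenate(idx_seqs)
    all_x = np.concatenate(x_seqs)
    missing = [states[i] for i in range(q) if not np.any(all_idx == i)]
    if missing:
        raise ValueError(f"states with no training frames: {missing}")
    priors = markov.estimate_priors(idx_seqs, n_states=q)
    tpm = markov.estimate_tpm(idx_seqs, n_states=q)
    rng = np.random.default_rng(rng_seed)
    emissions = []
    for i in range(q):
        frames = all_x[all_idx == i]
        if frames.shape[0] <= n_components:
            raise ValueError(
                f"state {states[i]!r} has {frames.shape[0]} frames; "
                f"need more than {n_components}"
            )
        emissions.append(
            fit_mixture(
                frames,
                n_components=n_components,
                rng_seed=int(rng.integers(2**31 - 1)),
                reg=reg,
            )
        )
    omm = ObservableMarkovModel(priors, tpm, tuple(states))
    return CHMM(omm, emissions)


def _forward_backward(chmm: CHMM, X: np.ndarray):
    """Log-domain forward/backward; returns (log_alpha, log_beta, loglik, logB)."""
    logB = chmm.log_emission_matrix(X)
    T, q = logB.shape
    log_pi = np.log(chmm.omm.priors, where=chmm.omm.priors > 0,
                    out=np.full(q, -np.inf))
    with np.errstate(divide="ignore"):
        logA = np.log(chmm.omm.tpm)
    la = np.empty((T, q))
    la[0] = log_pi + logB[0]
    for t in range(1, T):
        la[t] = logsumexp(la[t - 1][:, None] + logA, axis=0) + logB[t]
    lb = np.zeros((T, q))
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(logA + logB[t + 1] + lb[t + 1], axis=1)
    ll = float(logsumexp(la[-1]))
    return la, lb, ll, logB, logA


def forward_loglik(chmm: CHMM, X) -> float:
    """log P(X | model) via the scaled (log-domain) forward recursion."""
    _, _, ll, _, _ = _forward_backward(chmm, np.atleast_2d(np.asarray(X, float)))
    return ll


def train_level2(
    chmm: CHMM,
    sequences,
    update: str = "transitions",
    max_iter: int = 50,
    tol: float = 1e-6,
    reg: float = 1e-6,
) -> tuple[CHMM, list[float]]:
    """Second-level Baum-Welch refinement, pooled over sequences.

    ``update="transitions"`` (default) re-estimates only (pi, A), keeping
    the level-1 emissions frozen; ``update="all"`` re-estimates the emission
    mixtures too. Returns the refined model and the per-iteration total
    log-likelihood history (non-decreasing by the EM guarantee; a decrease
    beyond round-off raises).
    """
    if update not in ("transitions", "all"):
        raise ValueError("update must be 'transitions' or 'all'")
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in sequences]
    if not seqs:
        raise ValueError("at least one sequence required")
    q = chmm.n_states
    history: list[float] = []
    current = chmm
    for _ in range(max_iter):
        pi_acc = np.zeros(q)
        xi_acc = np.zeros((q, q))
        gamma_acc = [np.zeros((s.shape[0], q)) for s in seqs]
        total_ll = 0.0
        for si, X in enumerate(seqs):
            la, lb, ll, logB, logA = _forward_backward(current, X)
            if not np.isfinite(ll):
                raise RuntimeError(
                    "zero-likelihood sequence under the model; "
                    "increase the covariance floor (reg)"
                )
            total_ll += ll
            gamma = np.exp(la + lb - ll)
            gamma_acc[si] = gamma
            pi_acc += gamma[0]
            T = X.shape[0]
            if T > 1:
                for t in range(T - 1):
                    log_xi = la[t][:, None] + logA + logB[t + 1] + lb[t + 1] - ll
                    xi_acc += np.exp(log_xi)
        if history and total_ll < history[-1] - 1e-6 * max(1.0, abs(history[-1])):
            raise RuntimeError("Baum-Welch log-likelihood decreased")
        converged = bool(
            history
            and (total_ll - history[-1]) <= tol * max(1.0, abs(history[-1]))
        )
        history.append(total_ll)
        if converged:
            break
        new_priors = pi_acc / pi_acc.sum()
        row = xi_acc.sum(axis=1)
        new_tpm = current.omm.tpm.copy()
        live = row > 0
        new_tpm[live] = xi_acc[live] / row[live, None]
        emissions = current.emissions
        if update == "all":
            emissions = _reestimate_emissions(current, seqs, gamma_acc, reg)
        current = CHMM(
            ObservableMarkovModel(new_priors, new_tpm, current.omm.state_names),
            emissions,
        )
    return current, history


def _reestimate_emissions(chmm: CHMM, seqs, gammas, reg: float) -> list[MixtureModel]:
    """Standard Baum-Welch mixture update weighted by state occupancies."""
    X = np.concatenate(seqs)
    G = np.concatenate(gammas)  # (n, Q)
    out = []
    for i, mix in enumerate(chmm.emissions):
        log_comp = mix.component_log_densities(X)  # includes log weights
        comp_resp = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])
        w = G[:, i][:, None] * comp_resp  # (n, M)
        nk = w.sum(axis=0)
        nk = np.where(nk == 0, 1e-300, nk)
        weights = nk / nk.sum()
        means = (w.T @ X) / nk[:, None]
        covs = np.empty((mix.n_components, mix.dim, mix.dim))
        for m in range(mix.n_components):
            diff = X - means[m]
            covs[m] = _floor_covariance((w[:, m, None] * diff).T @ diff / nk[m], reg)
        out.append(MixtureModel(weights, means, covs))
    return out


def viterbi_decode(chmm: CHMM, X, mask=None) -> np.ndarray:
    """Most likely state path (indices), in the log domain.

    ``mask`` flags rejected frames: they carry no emission term — decoding
    runs over the retained frames only, with transition parameters
    unchanged — and each rejected frame inherits the decoded state of the
    previous retained frame (leading rejected frames take the first
    retained state). Ties resolve to the lowest state index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = X.shape[0]
    if mask is None:
        mask = np.zeros(T, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != T:
        raise ValueError("one mask flag per frame required")
    retained = np.flatnonzero(~mask)
    if retained.size == 0:
        raise ValueError("all frames rejected; nothing to decode")
    logB = chmm.log_emission_matrix(X[retained])
    q = chmm.n_states
    log_pi = np.log(chmm.omm.priors, where=chmm.omm.priors > 0,
                    out=np.full(q, -np.inf))
    with np.errstate(divide="ignore"):
        logA = np.log(chmm.omm.tpm)
    Tr = retained.size
    delta = np.empty((Tr, q))
    back = np.zeros((Tr, q), dtype=np.int64)
    delta[0] = log_pi + logB[0]
    for t in range(1, Tr):
        scores = delta[t - 1][:, None] + logA
        back[t] = np.argmax(scores, axis=0)  # first max = lowest index
        delta[t] = scores[back[t], np.arange(q)] + logB[t]
    path = np.empty(Tr, dtype=np.int64)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(Tr - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    out = np.empty(T, dtype=np.int64)
    out[retained] = path
    last = path[0]  # leading rejected frames take the first retained state
    for t in range(T):
        if mask[t]:
            out[t] = last
        else:
            last = out[t]
    return out
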