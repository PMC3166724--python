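"""Gaussian-mixture class-conditional densities and the single-frame classifier.

Each activity class w_i gets a mixture p(x | w_i) = sum_m c_m N(x; mu_m, Sigma_m)
with full covariances and mixing weights summing to 1. A frame is assigned
to the class with the highest class-conditional density — no prior
weighting. With M = 1 the fit reduces to the closed-form maximum-likelihood
mean and covariance; for M > 1 parameters are estimated by EM with
k-means++ seeding and an eigenvalue floor on the covariances.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

__all__ = ["MixtureModel", "GMMClassifier", "fit_mixture", "fit_gmm_classifier"]

_LOG2PI = np.log(2.0 * np.pi)


def _floor_covariance(cov: np.ndarray, reg: float) -> np.ndarray:
    """Symmetrize and floor the eigenvalues at ``reg`` (keeps SPD)."""
    cov = (cov + cov.T) / 2.0
    w, V = np.linalg.eigh(cov)
    w = np.maximum(w, reg)
    return (V * w) @ V.T


def _gauss_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate normal log-density via Cholesky, vectorized over rows."""
    L = np.linalg.cholesky(cov)
    diff = X - mean
    z = solve_triangular(L, diff.T, lower=True).T
    maha = np.sum(z**2, axis=1)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (mean.size * _LOG2PI + logdet + maha)


@dataclass
class MixtureModel:
    """Gaussian mixture: weights (M,), means (M, d), covariances (M, d, d)."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def component_log_densities(self, X: np.ndarray) -> np.ndarray:
        """(n, M) matrix of log c_m + log N(x; mu_m, Sigma_m)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError(f"dimension mismatch: {X.shape[1]} != {self.dim}")
        out = np.empty((X.shape[0], self.n_components))
        for m in range(self.n_components):
            out[:, m] = np.log(self.weights[m]) + _gauss_logpdf(
                X, self.means[m], self.covariances[m]
            )
        return out

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """log p(x) for each row of X."""
        return logsumexp(self.component_log_densities(X), axis=1)

    def density(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(X))

    def sample(self, n: int, rng_seed=0) -> np.ndarray:
        rng = np.random.default_rng(rng_seed)
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        out = np.empty((n, self.dim))
        for m in range(self.n_components):
            idx = comp == m
            if idx.any():
                out[idx] = rng.multivariate_normal(
                    self.means[m], self.covariances[m], size=int(idx.sum())
                )
        return out

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            np.array(d["weights"]),
            np.array(d["means"]),
            np.array(d["covariances"]),
        )


def fit_mixture(
    X,
    n_components: int = 1,
    rng_seed: int = 0,
    reg: float = 1e-6,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MixtureModel:
    """Maximum-likelihood mixture fit.

    M = 1 is closed form (sample mean and ML covariance); M > 1 runs EM
    from k-means++ seeded means. Covariance eigenvalues are floored at
    ``reg`` after every M-step. The per-iteration log-likelihood trace is
    stored on the returned model and verified to be non-decreasing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n <= n_components:
        raise ValueError(
            f"need more samples ({n}) than mixture components ({n_components})"
        )
    if n_components == 1:
        mean = X.mean(axis=0)
        diff = X - mean
        cov = _floor_covariance(diff.T @ diff / n, reg)
        model = MixtureModel(np.array([1.0]), mean[None], cov[None])
        model.loglik_trace = [float(model.log_density(X).sum())]
        return model

    rng = np.random.default_rng(rng_seed)
    seed_int = int(rng.integers(2**31 - 1))
    means, _ = kmeans_plusplus(X, n_clusters=n_components, random_state=seed_int)
    base_cov = _floor_covariance(np.cov(X.T, ddof=0).reshape(d, d), reg)
    covs = np.repeat(base_cov[None], n_components, axis=0)
    weights = np.full(n_components, 1.0 / n_components)
    model = MixtureModel(weights, means, covs)

    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_comp = model.component_log_densities(X)
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        if trace and ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            raise RuntimeError("EM log-likelihood decreased; numerical failure")
        trace.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = np.empty((n_components, d, d))
        for m in range(n_components):
            diff = X - means[m]
            covs[m] = _floor_covariance(
                (resp[:, m, None] * diff).T @ diff / nk[m], reg
            )
        model = MixtureModel(weights, means, covs)
        if prev_ll > -np.inf and (ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
    model.loglik_trace = trace
    return model


@dataclass
class GMMClassifier:
    """Per-class mixtures sharing one feature dimension.

    Classification is the argmax over classes of the class-conditional
    density; exact ties resolve to the lowest class index.
    """

    classes: tuple
    mixtures: list[MixtureModel]

    def __post_init__(self) -> None:
        dims = {m.dim for m in self.mixtures}
        if len(dims) != 1:
            raise ValueError("all class mixtures must share the feature dimension")
        if len(self.classes) != len(self.mixtures):
            raise ValueError("one mixture per class required")

    @property
    def dim(self) -> int:
        return self.mixtures[0].dim

    def log_density_matrix(self, X) -> np.ndarray:
        """(n_frames, n_classes) log class-conditional densities."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([m.log_density(X) for m in self.mixtures])

    def classify(self, X):
        """Return (labels, log-density matrix); ties go to the lowest index."""
        logd = self.log_density_matrix(X)
        idx = np.argmax(logd, axis=1)  # first max = lowest class index
        labels = np.asarray(self.classes, dtype=object)[idx]
        return labels, logd

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "mixtures": [m.to_dict() for m in self.mixtures],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GMMClassifier":
        return cls(
            tuple(d["classes"]),
            [MixtureModel.from_dict(m) for m in d["mixtures"]],
        )

    @classmethod
    def load(cls, path) -> "GMMClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_gmm_classifier(
    X,
    y,
    n_components: int = 1,
    rng_seed: int = 0,
    reg: float = 1e-6,
) -> GMMClassifier:
    """Fit one mixture per class on that class's frames."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    rng = np.random.default_rng(rng_seed)
    mixtures = []
    for cls in classes:
        sub = X[y == cls]
        mixtures.append(
            fit_mixture(
                sub,
                n_components=n_components,
                rng_seed=int(rng.integers(2**31 - 1)),
                reg=reg,
            )
        )
    return GMMClassifier(classes, mixtures)
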