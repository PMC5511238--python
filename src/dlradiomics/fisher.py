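"""Fisher-vector encoding of deep filter responses.

A single K-component univariate Gaussian mixture — the "visual word
dictionary" — is fitted once on responses pooled over all filters from an
encoder-fit subset of cases.  Each case's (F, T) response set is then
encoded per filter into first-order (mean-gradient) and second-order
(variance-gradient) Fisher statistics against that shared mixture:

    G_{f,k} = 1/(T √w_k)    Σ_t γ_k(x_t) (x_t − μ_k)/σ_k
    H_{f,k} = 1/(T √(2w_k)) Σ_t γ_k(x_t) [((x_t − μ_k)/σ_k)² − 1]

where γ_k(x) is the posterior responsibility of component k.  The blocks
are laid out as index(f, k, order) = f·2K + order·K + k, giving a
2·K·F-dimensional descriptor (16,384 at the defaults F=128, K=64).  The
improved-Fisher-vector post-processing — element-wise signed square root
followed by global L2 normalization — is applied by default; both steps
can be disabled to obtain the raw gradient vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .features import FilterResponseSet

__all__ = [
    "GmmModel",
    "FisherDescriptor",
    "fit_gmm",
    "posterior",
    "encode_case",
    "descriptor_index",
    "descriptor_unindex",
]


@dataclass
class GmmModel:
    """Shared scalar Gaussian mixture: weights, means, variances per component."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    n_fit: int = 0
    seed: int = 0
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if not (self.weights.shape == self.means.shape == self.variances.shape):
            raise ValueError("weights, means, variances must share shape (K,)")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("component weights must sum to 1")
        if np.any(self.weights <= 0):
            raise ValueError("component weights must be strictly positive")
        if np.any(self.variances <= 0):
            raise ValueError("component variances must be strictly positive")

    @property
    def K(self) -> int:
        return self.weights.size

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "n_fit": self.n_fit,
                "seed": self.seed,
                "log_likelihood": self.log_likelihood,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GmmModel":
        d = json.loads(text)
        return cls(
            weights=d["weights"],
            means=d["means"],
            variances=d["variances"],
            n_fit=d["n_fit"],
            seed=d["seed"],
            log_likelihood=d["log_likelihood"],
        )

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        """Draw n scalars from the mixture (used by consistency checks)."""
        rng = np.random.default_rng(seed)
        comps = rng.choice(self.K, size=n, p=self.weights)
        return rng.normal(self.means[comps], np.sqrt(self.variances[comps]))


@dataclass
class FisherDescriptor:
    """Fixed-length Fisher vector with its layout and normalization flags."""

    values: np.ndarray
    n_filters: int
    n_components: int
    signed_sqrt: bool = True
    l2_normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expect = 2 * self.n_components * self.n_filters
        if self.values.shape != (expect,):
            raise ValueError(f"descriptor length {self.values.size}, expected {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor must be finite")

    def __len__(self) -> int:
        return self.values.size


def fit_gmm(responses_pool: np.ndarray, K: int = 64, seed: int = 0) -> GmmModel:
    """EM fit of the K-component scalar mixture on a pooled response sample.

    Initialization is k-means++ from the seed; convergence at
    log-likelihood gain below 1e-6 or 500 iterations; variances floored
    at 1e-6 times the pool variance.  The pool must contain at least
    ``10*K`` distinct values.
    """
    pool = np.asarray(responses_pool, dtype=np.float64).ravel()
    n_distinct = np.unique(pool).size
    if n_distinct < 10 * K:
        raise ValueError(
            f"pool has {n_distinct} distinct values; need >= {10 * K} for K={K}"
        )
    pool_var = pool.var()
    if pool_var == 0:
        raise ValueError("degenerate pool: zero variance")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="diag",
        tol=1e-6,
        reg_covar=1e-6 * pool_var,
        max_iter=500,
        init_params="k-means++",
        random_state=seed,
    )
    X = pool[:, None]
    gm.fit(X)
    return GmmModel(
        weights=gm.weights_,
        means=gm.means_[:, 0],
        variances=gm.covariances_[:, 0],
        n_fit=pool.size,
        seed=seed,
        log_likelihood=float(gm.score(X) * pool.size),
    )


def _log_responsibilities(gmm: GmmModel, x: np.ndarray) -> np.ndarray:
    """(T, K) log posterior responsibilities, computed in log-space."""
    x = np.asarray(x, dtype=np.float64)[:, None]
    log_norm = -0.5 * (
        np.log(2 * np.pi * gmm.variances) + (x - gmm.means) ** 2 / gmm.variances
    )
    log_joint = np.log(gmm.weights) + log_norm
    return log_joint - logsumexp(log_joint, axis=1, keepdims=True)


def posterior(gmm: GmmModel, x) -> np.ndarray:
    """Responsibilities γ_k(x); shape (K,) for a scalar, (T, K) for an array."""
    scalar = np.isscalar(x) or np.ndim(x) == 0
    gamma = np.exp(_log_responsibilities(gmm, np.atleast_1d(x)))
    return gamma[0] if scalar else gamma


def descriptor_index(f: int, k: int, order: int, K: int = 64, F: int = 128) -> int:
    """Position of (filter f, component k, order) in the descriptor layout."""
    if not (0 <= f < F and 0 <= k < K and order in (0, 1)):
        raise IndexError(f"(f={f}, k={k}, order={order}) out of range for F={F}, K={K}")
    return f * 2 * K + order * K + k


def descriptor_unindex(idx: int, K: int = 64, F: int = 128) -> tuple[int, int, int]:
    """Inverse of :func:`descriptor_index`."""
    if not 0 <= idx < 2 * K * F:
        raise IndexError(f"index {idx} out of range for F={F}, K={K}")
    f, rem = divmod(idx, 2 * K)
    order, k = divmod(rem, K)
    return f, k, order


def encode_case(
    response_set: FilterResponseSet,
    gmm: GmmModel,
    signed_sqrt: bool = True,
    l2_normalize: bool = True,
) -> FisherDescriptor:
    """Encode one case's (F, T) responses into the 2·K·F Fisher vector."""
    R = response_set.responses
    F, T = R.shape
    if T == 0:
        raise ValueError("response set has length 0")
    K = gmm.K
    sigma = np.sqrt(gmm.variances)

    out = np.empty(2 * K * F)
    for f in range(F):
        x = R[f]
        gamma = np.exp(_log_responsibilities(gmm, x))  # (T, K)
        u = (x[:, None] - gmm.means) / sigma  # standardized residuals
        G = (gamma * u).sum(axis=0) / (T * np.sqrt(gmm.weights))
        H = (gamma * (u**2 - 1.0)).sum(axis=0) / (T * np.sqrt(2.0 * gmm.weights))
        base = f * 2 * K
        out[base : base + K] = G
        out[base + K : base + 2 * K] = H

    if signed_sqrt:
        out = np.sign(out) * np.sqrt(np.abs(out))
    if l2_normalize:
        norm = np.linalg.norm(out)
        if norm > 0:
            out = out / norm
    return FisherDescriptor(
        values=out,
        n_filters=F,
        n_components=K,
        signed_sqrt=signed_sqrt,
        l2_normalized=l2_normalize,
    )
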