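"""Gaussian mixture model fit by expectation-maximization, from scratch.

The mixture density is f(x) = sum_k c_k N(x | mu_k, Sigma_k) with weights
c_k in [0, 1] summing to one.  EM alternates the posterior-responsibility
E-step with closed-form weighted-moment M-step updates, monotonically
increasing the data log-likelihood.  All density evaluations run in
log-space through a Cholesky factorization (no explicit inverses), with
the log-sum-exp trick for normalization, so strongly separated components
do not underflow.  Classification is the Bayes rule: the component with
the highest posterior responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, solve_triangular
from scipy.special import logsumexp

from .imu_core import DataError, LmrError

__all__ = [
    "GaussianComponent",
    "GmmModel",
    "Responsibilities",
    "EmptyComponentError",
    "NumericError",
    "mvn_pdf",
    "e_step",
    "log_likelihood",
    "m_step",
    "fit_gmm",
    "classify",
    "init_from_labels",
    "init_random",
]

_LOG_2PI = np.log(2.0 * np.pi)


class EmptyComponentError(LmrError):
    """A mixture component lost all responsibility mass during EM.

    Usually caused by a degenerate initialization; restart from a
    different initial model (e.g. re-seeded random init).
    """


class NumericError(LmrError):
    """A likelihood computation produced non-finite values."""


@dataclass
class GaussianComponent:
    """One weighted multivariate normal component (c_k, mu_k, Sigma_k)."""

    weight: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.weight = float(self.weight)
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        d = len(self.mean)
        if not 0.0 <= self.weight <= 1.0:
            raise DataError(f"component weight {self.weight} outside [0, 1]")
        if self.cov.shape != (d, d):
            raise DataError(
                f"covariance shape {self.cov.shape} does not match dim {d}"
            )
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise DataError("covariance must be symmetric")
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise DataError("covariance must be positive definite") from exc


@dataclass
class GmmModel:
    """A K-component Gaussian mixture in d dimensions."""

    components: list[GaussianComponent]

    def __post_init__(self) -> None:
        if not self.components:
            raise DataError("mixture needs at least one component")
        dims = {len(c.mean) for c in self.components}
        if len(dims) != 1:
            raise DataError("components disagree on dimension")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-12:
            raise DataError(f"component weights sum to {total!r}, not 1")

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def d(self) -> int:
        return len(self.components[0].mean)


@dataclass
class Responsibilities:
    """N x K posterior component-membership probabilities, rows sum to 1."""

    gamma: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.size:
            if np.any(self.gamma < 0) or np.any(self.gamma > 1):
                raise DataError("responsibilities must lie in [0, 1]")
            if np.max(np.abs(self.gamma.sum(axis=1) - 1.0)) > 1e-12:
                raise DataError("responsibility rows must sum to 1")


def _mvn_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log multivariate-normal density for rows of X, via Cholesky."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = np.asarray(mean, dtype=float).ravel()
    cov = np.asarray(cov, dtype=float)
    d = len(mean)
    try:
        chol, lower = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DataError("covariance is not positive definite") from exc
    dev = X - mean
    # Solve L z = dev^T; Mahalanobis distance is ||z||^2.
    z = solve_triangular(chol, dev.T, lower=lower)
    maha = np.sum(z * z, axis=0)
    log_det = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * _LOG_2PI + log_det + maha)


def mvn_pdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float | np.ndarray:
    """Multivariate normal density; scalar for a single point."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = np.exp(_mvn_logpdf(x, mu, sigma))
    return float(out[0]) if single else out


def _log_weighted_densities(X: np.ndarray, model: GmmModel) -> np.ndarray:
    """N x K matrix of log(c_k) + log N_k(x_n)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = []
    for comp in model.components:
        with np.errstate(divide="ignore"):
            logw = np.log(comp.weight) if comp.weight > 0 else -np.inf
        cols.append(logw + _mvn_logpdf(X, comp.mean, comp.cov))
    return np.column_stack(cols)


def e_step(X: np.ndarray, model: GmmModel) -> Responsibilities:
    """Posterior responsibilities gamma_nk, normalized per row in log-space."""
    log_wd = _log_weighted_densities(X, model)
    row_log_norm = logsumexp(log_wd, axis=1)
    dead = ~np.isfinite(row_log_norm)
    if np.any(dead):
        raise NumericError(
            f"all component densities underflowed for row {int(np.argmax(dead))}"
        )
    gamma = np.exp(log_wd - row_log_norm[:, None])
    # exp/logsumexp can leave rows a few ulp from 1; renormalize exactly.
    gamma /= gamma.sum(axis=1, keepdims=True)
    return Responsibilities(gamma=gamma)


def log_likelihood(X: np.ndarray, model: GmmModel) -> float:
    """Total data log-likelihood sum_n ln sum_k c_k N_k(x_n)."""
    log_wd = _log_weighted_densities(X, model)
    row = logsumexp(log_wd, axis=1)
    if not np.all(np.isfinite(row)):
        raise NumericError(
            f"log-likelihood underflowed for row {int(np.argmax(~np.isfinite(row)))}"
        )
    return float(np.sum(row))


def m_step(X: np.ndarray, gamma: Responsibilities, ridge: float = 1e-6) -> GmmModel:
    """Closed-form weighted-moment updates of means, covariances, weights.

    ``ridge`` is added to the covariance diagonal to keep each component
    invertible even when its responsibility mass concentrates on nearly
    collinear points.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = gamma.gamma
    n, d = X.shape
    if G.shape[0] != n:
        raise DataError("responsibilities do not match data")
    nk = G.sum(axis=0)
    if np.any(nk < 1e-10):
        raise EmptyComponentError(
            f"component {int(np.argmax(nk < 1e-10))} has no responsibility "
            "mass; re-initialize and restart"
        )
    comps = []
    weights = nk / n
    weights = weights / weights.sum()
    for k in range(G.shape[1]):
        mu = G[:, k] @ X / nk[k]
        dev = X - mu
        cov = (dev * G[:, k, None]).T @ dev / nk[k] + ridge * np.eye(d)
        comps.append(GaussianComponent(weight=weights[k], mean=mu, cov=cov))
    return GmmModel(components=comps)


def fit_gmm(
    X: np.ndarray,
    K: int,
    init: GmmModel,
    tol: float = 1e-6,
    max_iter: int = 200,
    ridge: float = 1e-6,
) -> tuple[GmmModel, list[float]]:
    """Run EM from ``init`` until the log-likelihood stalls.

    Convergence when the relative log-likelihood change drops below
    ``tol`` or after ``max_iter`` iterations.  Returns the fitted model
    and the per-iteration log-likelihood trace (including the initial
    value); the trace is non-decreasing up to numerical noise, which is
    EM's defining guarantee.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if init.K != K:
        raise DataError(f"init has {init.K} components, expected {K}")
    n, d = X.shape
    if n <= K * d:
        raise DataError(f"need more than K*d = {K * d} points, got {n}")
    model = init
    trace = [log_likelihood(X, model)]
    for _ in range(max_iter):
        gamma = e_step(X, model)
        model = m_step(X, gamma, ridge=ridge)
        ll = log_likelihood(X, model)
        if not np.isfinite(ll):
            raise NumericError("log-likelihood became non-finite during EM")
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1e-12):
            break
    return model, trace


def classify(x: np.ndarray, model: GmmModel) -> tuple[int, np.ndarray]:
    """Bayes classification: argmax_k of the posterior responsibility.

    Ties break toward the smallest component index.  Returns the winning
    component index and the full responsibility row.
    """
    gamma = e_step(np.atleast_2d(x), model).gamma[0]
    return int(np.argmax(gamma)), gamma


# ---------------------------------------------------------------------------
# Initialization helpers
# ---------------------------------------------------------------------------


def init_from_labels(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-6
) -> GmmModel:
    """Initial mixture from labeled class statistics, uniform weights.

    Means and covariances come from each class's sample moments; weights
    start uniform at 1/K.  Component k corresponds to the k-th smallest
    class label.  Fixes EM's identifiability when labels are available.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    labels = np.unique(y)
    d = X.shape[1]
    comps = []
    for lab in labels:
        sub = X[y == lab]
        if len(sub) < 2:
            raise DataError(f"class {lab!r} has fewer than 2 points")
        comps.append(
            GaussianComponent(
                weight=1.0 / len(labels),
                mean=sub.mean(axis=0),
                cov=np.cov(sub, rowvar=False, bias=True) + ridge * np.eye(d),
            )
        )
    return GmmModel(components=comps)


def init_random(
    X: np.ndarray, K: int, rng: np.random.Generator, ridge: float = 1e-6
) -> GmmModel:
    """Label-blind initialization: K distinct data points as means,
    the pooled covariance for every component, uniform weights."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    idx = rng.choice(n, size=K, replace=False)
    cov = np.cov(X, rowvar=False, bias=True) + ridge * np.eye(d)
    cov = np.atleast_2d(cov)
    return GmmModel(
        components=[
            GaussianComponent(weight=1.0 / K, mean=X[i], cov=cov.copy())
            for i in idx
        ]
    )
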