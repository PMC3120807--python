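"""Log-density components of the joint posterior.

The model has four pieces, which add on the log scale:

* **measurement model** — surrogate exposures W are the latent true exposures
  X plus independent N(0, sigma^2_p) noise per exposure (classical additive,
  non-differential error on the log scale);
* **disease model** — conditional logistic regression: within each matched
  set, the probability that the observed case is the case, given that the set
  contains exactly one, is exp(eta_case) / sum_j exp(eta_j) with linear
  predictor eta = X' beta + Z' delta;
* **exposure model** — a two-level multivariate normal: set-level means M_i
  vary around a plug-in grand mean mu with between-set covariance V_B, and
  subjects vary around their set mean with within-set covariance V_W;
* **priors** — diffuse normals on beta and delta, Wishart priors on the
  within- and between-set precision matrices.

`log_joint` sums the four; the MCMC sampler targets exactly this density (its
incremental acceptance ratios are tested against differences of `log_joint`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import wishart

from .data_io import MatchedStudy
from .qc_variance import MeasurementErrorSpec

__all__ = [
    "PriorSpec",
    "LatentState",
    "log_disease",
    "log_measurement",
    "log_exposure",
    "log_priors",
    "log_joint",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PriorSpec:
    """Hyperparameters of the prior block.

    ``beta_var`` / ``delta_var`` are the variances of the mean-zero normal
    priors on the log odds ratios (default 1e4, i.e. essentially flat over any
    epidemiologically plausible effect).  The precision matrices V_W^-1 and
    V_B^-1 carry Wishart priors with inverse scale ``wishart_R`` (default
    identity) and ``wishart_df`` degrees of freedom (default P, the minimal
    proper choice).  ``mu`` is the plug-in grand mean of the exposures; when
    None it is filled with the across-set sample mean of the observed W.
    """

    beta_var: float = 1e4
    delta_var: float = 1e4
    wishart_R: np.ndarray | None = None
    wishart_df: float | None = None
    mu: np.ndarray | None = None

    def resolved(self, P: int, W: np.ndarray | None = None, study: MatchedStudy | None = None) -> "PriorSpec":
        """Fill in defaults that depend on the exposure dimension / data."""
        R = np.eye(P) if self.wishart_R is None else np.asarray(self.wishart_R, float)
        df = float(P) if self.wishart_df is None else float(self.wishart_df)
        mu = self.mu
        if mu is None:
            if W is None or study is None:
                raise ValueError("mu not set and no data supplied to estimate it")
            # across-set sample mean: unweighted mean of the set-level means
            set_sums = np.add.reduceat(W, study.offsets, axis=0)
            mu = (set_sums / study.sizes[:, None]).mean(axis=0)
        mu = np.asarray(mu, float)
        if self.beta_var <= 0 or self.delta_var <= 0:
            raise ValueError("prior variances must be positive")
        if df < P:
            raise ValueError("wishart_df must be at least P for a proper prior")
        _chol_or_raise(R, "wishart_R")
        return PriorSpec(self.beta_var, self.delta_var, R, df, mu)


@dataclass
class LatentState:
    """One point in the space the posterior lives on."""

    beta: np.ndarray              # (P,) log ORs per unit exposure
    delta: np.ndarray             # (K,) log ORs per unit confounder
    X: np.ndarray                 # (S, P) latent true exposures
    M: np.ndarray                 # (N, P) set-level exposure means
    V_W: np.ndarray               # (P, P) within-set covariance
    V_B: np.ndarray               # (P, P) between-set covariance

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        self.delta = np.atleast_1d(np.asarray(self.delta, float)) if np.size(self.delta) else np.zeros(0)
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.M = np.atleast_2d(np.asarray(self.M, float))
        self.V_W = np.atleast_2d(np.asarray(self.V_W, float))
        self.V_B = np.atleast_2d(np.asarray(self.V_B, float))


def _chol_or_raise(A: np.ndarray, name: str):
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError(f"{name} must be a symmetric matrix")
    try:
        return cho_factor(A, lower=True)
    except np.linalg.LinAlgError as e:  # pragma: no cover - scipy raises LinAlgError
        raise ValueError(f"{name} is not positive definite") from e


def _set_logsumexp(eta: np.ndarray, study: MatchedStudy) -> np.ndarray:
    """Per-set log sum exp of the linear predictor (stable)."""
    sidx = study.set_index
    m = np.full(study.n_sets, -np.inf)
    np.maximum.at(m, sidx, eta)
    return m + np.log(np.add.reduceat(np.exp(eta - m[sidx]), study.offsets))


def log_disease(
    beta: np.ndarray,
    delta: np.ndarray | None,
    X: np.ndarray,
    Z: np.ndarray | None,
    study: MatchedStudy,
) -> float:
    """Conditional logistic log-likelihood over all matched sets.

    Sum over sets of eta_case − log sum_j exp(eta_j), with
    eta = X beta (+ Z delta when confounders are present).  Assumes the case
    is stored first in each set, the container's convention.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape != (study.n_subjects, len(beta)):
        raise ValueError(
            f"X has shape {X.shape}, expected {(study.n_subjects, len(beta))}"
        )
    eta = X @ beta
    if delta is not None and np.size(delta):
        delta = np.atleast_1d(np.asarray(delta, float))
        Z = np.atleast_2d(np.asarray(Z, float))
        if Z.shape != (study.n_subjects, len(delta)):
            raise ValueError(f"Z has shape {Z.shape}, expected {(study.n_subjects, len(delta))}")
        eta = eta + Z @ delta
    lse = _set_logsumexp(eta, study)
    return float(np.sum(eta[study.offsets] - lse))


def log_measurement(W: np.ndarray, X: np.ndarray, spec: MeasurementErrorSpec) -> float:
    """Classical-error log-density: independent N(x_ijp, sigma^2_p) per entry."""
    sigma2 = spec.sigma2
    if np.any(sigma2 <= 0):
        raise ValueError(
            "zero error variance: the measurement model is degenerate; "
            "use the naive analysis (W identical to X) instead"
        )
    W = np.atleast_2d(np.asarray(W, float))
    X = np.atleast_2d(np.asarray(X, float))
    if W.shape != X.shape:
        raise ValueError("W and X must have the same shape")
    n = W.shape[0]
    quad = ((W - X) ** 2 / sigma2).sum()
    return float(-0.5 * (n * np.sum(np.log(2.0 * np.pi * sigma2)) + quad))


def _mvn_logpdf_rows(D: np.ndarray, cov_chol, logdet: float) -> float:
    """Sum of N_P(d; 0, Sigma) log-densities over rows d of D."""
    P = D.shape[1]
    sol = cho_solve(cov_chol, D.T)
    quad = float(np.sum(D.T * sol))
    return -0.5 * (D.shape[0] * (P * _LOG_2PI + logdet) + quad)


def log_exposure(
    X: np.ndarray,
    M: np.ndarray,
    prior: PriorSpec,
    V_W: np.ndarray,
    V_B: np.ndarray,
    study: MatchedStudy,
) -> float:
    """Two-level random-effect exposure model log-density.

    Sum over sets of log N_P(M_i; mu, V_B) plus, over subjects, of
    log N_P(X_ij; M_i, V_W).
    """
    cW = _chol_or_raise(V_W, "V_W")
    cB = _chol_or_raise(V_B, "V_B")
    ldW = 2.0 * float(np.sum(np.log(np.diag(cW[0]))))
    ldB = 2.0 * float(np.sum(np.log(np.diag(cB[0]))))
    mu = np.asarray(prior.mu, float)
    X = np.atleast_2d(np.asarray(X, float))
    M = np.atleast_2d(np.asarray(M, float))
    between = _mvn_logpdf_rows(M - mu, cB, ldB)
    within = _mvn_logpdf_rows(X - M[study.set_index], cW, ldW)
    return float(between + within)


def log_priors(state: LatentState, prior: PriorSpec) -> float:
    """Normal priors on beta/delta plus Wishart priors on the two precisions."""
    P = len(state.beta)
    lp = -0.5 * float(
        np.sum(state.beta**2) / prior.beta_var
        + P * np.log(2.0 * np.pi * prior.beta_var)
    )
    K = len(state.delta)
    if K:
        lp -= 0.5 * float(
            np.sum(state.delta**2) / prior.delta_var
            + K * np.log(2.0 * np.pi * prior.delta_var)
        )
    R = prior.wishart_R
    df = prior.wishart_df
    if R is None or df is None:
        raise ValueError("prior must be resolved (wishart_R / wishart_df set)")
    # Wishart on the precision matrices; inverse scale R means scale R^-1
    scale = np.linalg.inv(R)
    for V, name in ((state.V_W, "V_W"), (state.V_B, "V_B")):
        _chol_or_raise(V, name)
        lam = np.linalg.inv(V)
        lp += float(wishart.logpdf(lam, df=df, scale=scale))
    return lp


def log_joint(
    state: LatentState,
    study: MatchedStudy,
    spec: MeasurementErrorSpec,
    prior: PriorSpec,
    W: np.ndarray | None = None,
    Z: np.ndarray | None = None,
) -> float:
    """Unnormalised log-posterior: measurement + disease + exposure + priors.

    ``W`` and ``Z`` default to the study's observed arrays; they are exposed
    so callers can evaluate the same state against modified data.
    """
    W = study.W if W is None else W
    Z = study.Z if Z is None else Z
    prior = prior if prior.mu is not None and prior.wishart_R is not None else prior.resolved(study.P, W, study)
    val = (
        log_measurement(W, state.X, spec)
        + log_disease(state.beta, state.delta, state.X, Z, study)
        + log_exposure(state.X, state.M, prior, state.V_W, state.V_B, study)
        + log_priors(state, prior)
    )
    return float(val)
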