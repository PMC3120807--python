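"""Metropolis-within-Gibbs sampler for the measurement-error-corrected model.

Each sweep updates, in order:

1. set-level exposure means ``M_i`` — conjugate multivariate-normal draw;
2. the within- and between-set precision matrices — conjugate Wishart draws;
3. latent exposures ``X_ij`` — random-walk Metropolis, one set position at a
   time (positions are updated simultaneously across sets, which are mutually
   independent given the rest of the state);
4. the log odds ratios ``(beta, delta)`` — joint random-walk Metropolis whose
   proposal covariance is learned during burn-in.

Random-walk step sizes adapt (Robbins-Monro toward a target acceptance rate)
during burn-in only, then freeze, so the post-burn-in chain is a genuine
Markov chain with the posterior as invariant distribution.

The module also provides the convergence diagnostics used throughout: the
split-chain Gelman-Rubin potential scale reduction factor and the batch-means
Monte Carlo standard error.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import multigammaln

from .data_io import MatchedStudy
from .model_core import PriorSpec
from .qc_variance import MeasurementErrorSpec

__all__ = [
    "SamplerConfig",
    "ChainSet",
    "run",
    "gelman_rubin",
    "mcse",
    "accept_probability",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class SamplerConfig:
    """Chain-length, seeding and tuning knobs for the sampler.

    Defaults mirror the protocol used for the motivating analysis: two chains
    of 55,000 sweeps with the first 5,000 discarded as burn-in.
    """

    n_iter: int = 55_000
    n_burn: int = 5_000
    n_chains: int = 2
    base_seed: int = 0
    adapt_window: int = 50
    step_x: float = 0.4
    step_theta: float = 0.2
    target_accept: float = 0.35
    theta_updates: int = 2  # Metropolis refreshes of (beta, delta) per sweep
    cov_thin: int = 10
    fix_covariances: bool = False
    exposure_only: bool = False
    store_latent: bool = False
    init_V_W: np.ndarray | None = None
    init_V_B: np.ndarray | None = None
    jitter_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class ChainSet:
    """Posterior draws across chains, with burn-in metadata.

    ``beta``/``delta`` hold every sweep including burn-in (chains x sweeps x
    dim); covariance matrices (and optionally the latent state) are thinned by
    ``cov_thin``.  Selectors for the diagnostic helpers: ``"beta"``,
    ``"delta"`` or ``"theta"`` (both stacked).
    """

    beta: np.ndarray
    delta: np.ndarray
    logpost: np.ndarray
    V_W: np.ndarray
    V_B: np.ndarray
    n_burn: int
    cov_thin: int
    acceptance: list
    param_names: list
    mode: str
    config: SamplerConfig
    X_thin: np.ndarray | None = None
    M_thin: np.ndarray | None = None
    runtime_s: float = 0.0

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    def _select(self, param: str) -> np.ndarray:
        if param == "beta":
            return self.beta
        if param == "delta":
            return self.delta
        if param == "theta":
            return np.concatenate([self.beta, self.delta], axis=2)
        raise KeyError(f"unknown parameter selector {param!r}")

    def post_burn(self, param: str = "theta") -> np.ndarray:
        """(chains, kept sweeps, dim) array of post-burn-in draws."""
        d = self._select(param)
        if d.shape[1] <= self.n_burn:
            raise ValueError("no post-burn-in draws")
        return d[:, self.n_burn :, :]

    def pooled(self, param: str = "theta") -> np.ndarray:
        """Post-burn-in draws pooled over chains, (draws, dim)."""
        d = self.post_burn(param)
        return d.reshape(-1, d.shape[2])

    def dump_csv(self, path) -> None:
        """One row per kept sweep per chain, one column per tracked parameter."""
        frames = []
        for c in range(self.n_chains):
            th = np.concatenate([self.beta[c], self.delta[c]], axis=1)
            df = pd.DataFrame(th, columns=self.param_names)
            df.insert(0, "iteration", np.arange(th.shape[0]))
            df.insert(0, "chain", c)
            df["log_posterior"] = self.logpost[c]
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def accept_probability(log_ratio: float) -> float:
    """Metropolis acceptance probability min(1, exp(log_ratio))."""
    return float(min(1.0, np.exp(min(log_ratio, 0.0))))


def _sample_wishart(rng: np.random.Generator, df: float, scale: np.ndarray):
    """Bartlett-decomposition Wishart draw; returns (draw, log-determinant)."""
    P = scale.shape[0]
    L = np.linalg.cholesky(scale)
    A = np.zeros((P, P))
    idx = np.tril_indices(P, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    A[np.diag_indices(P)] = np.sqrt(rng.chisquare(df - np.arange(P)))
    T = L @ A
    return T @ T.T, 2.0 * float(np.sum(np.log(np.diag(T))))


def _row_logsumexp(etas: np.ndarray) -> np.ndarray:
    m = etas.max(axis=1)
    return m + np.log(np.exp(etas - m[:, None]).sum(axis=1))


class _Design:
    """Precomputed index structures for one study layout."""

    def __init__(self, study: MatchedStudy):
        self.sizes = study.sizes
        self.offsets = study.offsets
        self.set_index = study.set_index
        self.N = study.n_sets
        self.S = study.n_subjects
        self.max_n = int(self.sizes.max())
        self.pos_in_set = np.arange(self.S) - self.offsets[self.set_index]
        # subjects at each within-set position, and the sets they belong to
        self.positions = []
        for j in range(self.max_n):
            sets_j = np.where(self.sizes > j)[0]
            self.positions.append((self.offsets[sets_j] + j, sets_j))
        # sets grouped by size (shared conjugate precision for the M update)
        self.size_groups = [
            (int(n), np.where(self.sizes == n)[0]) for n in np.unique(self.sizes)
        ]


def _init_covariances(W: np.ndarray, d: _Design):
    set_means = np.add.reduceat(W, d.offsets, axis=0) / d.sizes[:, None]
    E = W - set_means[d.set_index]
    P = W.shape[1]
    V_W = E.T @ E / max(d.S - d.N, 1) + 1e-3 * np.eye(P)
    centered = set_means - set_means.mean(axis=0)
    V_B = centered.T @ centered / max(d.N - 1, 1) + 1e-3 * np.eye(P)
    return set_means, V_W, V_B


def _run_chain(
    study: MatchedStudy,
    W: np.ndarray,
    Z: np.ndarray,
    sigma2: np.ndarray | None,
    prior: PriorSpec,
    config: SamplerConfig,
    mode: str,
    chain_idx: int,
):
    d = _Design(study)
    S, P = W.shape
    K = Z.shape[1]
    D = P + K
    rng = np.random.default_rng([int(config.base_seed), int(chain_idx)])
    naive = mode == "naive"

    mu = np.asarray(prior.mu, float)
    R = np.asarray(prior.wishart_R, float)
    b = float(prior.wishart_df)

    # ---- initial state ---------------------------------------------------
    set_means, V_W0, V_B0 = _init_covariances(W, d)
    if config.init_V_W is not None:
        V_W0 = np.atleast_2d(np.asarray(config.init_V_W, float))
    if config.init_V_B is not None:
        V_B0 = np.atleast_2d(np.asarray(config.init_V_B, float))
    X = W.copy()
    M = set_means.copy()
    theta = np.zeros(D)
    if chain_idx > 0:
        shift = config.jitter_scale * chain_idx
        sd_w = W.std(axis=0)
        X = X + shift * sd_w
        M = M + shift * sd_w
        theta = theta + shift * 0.3

    beta = theta[:P]
    delta = theta[P:]
    lam_W = np.linalg.inv(V_W0)
    lam_B = np.linalg.inv(V_B0)
    ld_lam_W = float(np.linalg.slogdet(lam_W)[1])
    ld_lam_B = float(np.linalg.slogdet(lam_B)[1])

    eta = X @ beta + (Z @ delta if K else 0.0)
    pad_template = np.full((d.N, d.max_n), -np.inf)
    eta_pad = pad_template.copy()
    eta_pad[d.set_index, d.pos_in_set] = eta
    lse = _row_logsumexp(eta_pad)
    loglik_dis = float((eta_pad[:, 0] - lse).sum())

    half_inv_s2 = 0.5 / sigma2 if sigma2 is not None else None
    meas_const = (
        -0.5 * S * float(np.sum(np.log(2.0 * np.pi * sigma2)))
        if sigma2 is not None
        else 0.0
    )
    # Wishart prior normalising constant (inverse scale R => scale R^-1)
    sign, ld_R = np.linalg.slogdet(R)
    wish_const = -0.5 * b * P * np.log(2.0) + 0.5 * b * ld_R - multigammaln(0.5 * b, P)
    theta_prior_var = np.concatenate(
        [np.full(P, prior.beta_var), np.full(K, prior.delta_var)]
    )
    theta_prior_const = -0.5 * float(np.sum(np.log(2.0 * np.pi * theta_prior_var)))

    def log_posterior() -> float:
        lp = -0.5 * float(np.sum(theta**2 / theta_prior_var)) + theta_prior_const
        if not config.exposure_only:
            lp += loglik_dis
        if naive:
            return lp
        e_w = X - M[d.set_index]
        e_b = M - mu
        lp += meas_const - float(((W - X) ** 2 * half_inv_s2).sum())
        lp += 0.5 * S * (ld_lam_W - P * _LOG_2PI) - 0.5 * float(
            np.sum((e_w @ lam_W) * e_w)
        )
        lp += 0.5 * d.N * (ld_lam_B - P * _LOG_2PI) - 0.5 * float(
            np.sum((e_b @ lam_B) * e_b)
        )
        for lam, ld in ((lam_W, ld_lam_W), (lam_B, ld_lam_B)):
            lp += (
                wish_const
                + 0.5 * (b - P - 1) * ld
                - 0.5 * float(np.trace(R @ lam))
            )
        return lp

    if not np.isfinite(log_posterior()):
        raise RuntimeError(
            "non-finite log-posterior at initialization; "
            f"state: theta={theta}, V_W0={V_W0}, V_B0={V_B0}"
        )

    # ---- storage ---------------------------------------------------------
    T = config.n_iter
    out_beta = np.empty((T, P))
    out_delta = np.empty((T, K))
    out_lp = np.empty(T)
    n_cov = T // config.cov_thin
    out_VW = np.empty((n_cov, P, P)) if not naive else np.empty((0, P, P))
    out_VB = np.empty_like(out_VW)
    out_X = np.empty((n_cov, S, P)) if (config.store_latent and not naive) else None
    out_M = np.empty((n_cov, d.N, P)) if (config.store_latent and not naive) else None

    # ---- adaptation state ------------------------------------------------
    log_step_x = np.log(config.step_x)
    log_step_t = np.log(config.step_theta)
    prop_chol = np.eye(D)
    burn_thetas = np.empty((config.n_burn, D))
    win_acc_x = win_prop_x = 0
    win_acc_t = win_prop_t = 0
    post_acc_x = post_prop_x = 0
    post_acc_t = post_prop_t = 0
    n_windows = 0

    t0 = time.perf_counter()
    for t in range(T):
        step_x = np.exp(log_step_x)
        step_t = np.exp(log_step_t)

        if not naive:
            # (1) conjugate update of the set means M_i
            sum_X = np.add.reduceat(X, d.offsets, axis=0)
            rhs = mu @ lam_B + sum_X @ lam_W
            for n, gsets in d.size_groups:
                prec = lam_B + n * lam_W
                L = np.linalg.cholesky(prec)
                half = solve_triangular(L, rhs[gsets].T, lower=True)
                mean = solve_triangular(L.T, half, lower=False)
                noise = solve_triangular(
                    L.T, rng.standard_normal((P, len(gsets))), lower=False
                )
                M[gsets] = (mean + noise).T

            # (2) conjugate Wishart updates of the precision matrices
            if not config.fix_covariances:
                e_w = X - M[d.set_index]
                lam_W, ld_lam_W = _sample_wishart(
                    rng, b + S, np.linalg.inv(R + e_w.T @ e_w)
                )
                e_b = M - mu
                lam_B, ld_lam_B = _sample_wishart(
                    rng, b + d.N, np.linalg.inv(R + e_b.T @ e_b)
                )

            # (3) random-walk Metropolis on latent X, one set position at a time
            for j, (rows, sets_j) in enumerate(d.positions):
                x_old = X[rows]
                prop = x_old + step_x * rng.standard_normal(x_old.shape)
                d_meas = ((W[rows] - x_old) ** 2 - (W[rows] - prop) ** 2) @ half_inv_s2
                e0 = x_old - M[sets_j]
                e1 = prop - M[sets_j]
                log_r = d_meas - 0.5 * (
                    ((e1 @ lam_W) * e1).sum(1) - ((e0 @ lam_W) * e0).sum(1)
                )
                if not config.exposure_only:
                    eta_new = eta_pad[sets_j, j] + (prop - x_old) @ beta
                    etas = eta_pad[sets_j].copy()
                    etas[:, j] = eta_new
                    A_new = _row_logsumexp(etas)
                    d_dis = lse[sets_j] - A_new
                    if j == 0:
                        d_dis = d_dis + eta_new - eta_pad[sets_j, 0]
                    log_r = log_r + d_dis
                acc = np.log(rng.random(len(rows))) < log_r
                X[rows[acc]] = prop[acc]
                if not config.exposure_only:
                    sets_a = sets_j[acc]
                    eta_pad[sets_a, j] = eta_new[acc]
                    lse[sets_a] = A_new[acc]
                    loglik_dis += float(d_dis[acc].sum())
                na, npr = int(acc.sum()), len(rows)
                if t < config.n_burn:
                    win_acc_x += na
                    win_prop_x += npr
                else:
                    post_acc_x += na
                    post_prop_x += npr

        # (4) joint random-walk Metropolis on (beta, delta)
        if not config.exposure_only and D > 0:
            for _ in range(max(1, config.theta_updates)):
                prop_t = theta + step_t * (prop_chol @ rng.standard_normal(D))
                eta_new = X @ prop_t[:P] + (Z @ prop_t[P:] if K else 0.0)
                pad_new = pad_template.copy()
                pad_new[d.set_index, d.pos_in_set] = eta_new
                lse_new = _row_logsumexp(pad_new)
                ll_new = float((pad_new[:, 0] - lse_new).sum())
                d_prior = -0.5 * float(np.sum((prop_t**2 - theta**2) / theta_prior_var))
                if np.log(rng.random()) < (ll_new - loglik_dis) + d_prior:
                    theta = prop_t
                    beta = theta[:P]
                    delta = theta[P:]
                    eta_pad = pad_new
                    lse = lse_new
                    loglik_dis = ll_new
                    acc_t = 1
                else:
                    acc_t = 0
                if t < config.n_burn:
                    win_acc_t += acc_t
                    win_prop_t += 1
                else:
                    post_acc_t += acc_t
                    post_prop_t += 1

        # ---- burn-in adaptation ----
        if t < config.n_burn:
            burn_thetas[t] = theta
            if (t + 1) % config.adapt_window == 0:
                n_windows += 1
                g = n_windows**-0.5
                if win_prop_x:
                    log_step_x += g * (win_acc_x / win_prop_x - config.target_accept)
                if win_prop_t:
                    log_step_t += g * (win_acc_t / win_prop_t - config.target_accept)
                win_acc_x = win_prop_x = win_acc_t = win_prop_t = 0
            if t + 1 == config.n_burn // 2 and D > 0:
                draws = burn_thetas[config.n_burn // 4 : t + 1]
                cov = np.cov(draws.T).reshape(D, D) + 1e-8 * np.eye(D)
                scale = np.exp(np.mean(np.log(np.diag(cov))))
                prop_chol = np.linalg.cholesky(cov / scale)

        out_beta[t] = beta
        out_delta[t] = delta
        out_lp[t] = log_posterior()
        if not naive and config.cov_thin and (t + 1) % config.cov_thin == 0:
            k = (t + 1) // config.cov_thin - 1
            if k < n_cov:
                out_VW[k] = np.linalg.inv(lam_W)
                out_VB[k] = np.linalg.inv(lam_B)
                if out_X is not None:
                    out_X[k] = X
                    out_M[k] = M

    acc = {
        "x": post_acc_x / post_prop_x if post_prop_x else np.nan,
        "theta": post_acc_t / post_prop_t if post_prop_t else np.nan,
        "step_x": float(np.exp(log_step_x)),
        "step_theta": float(np.exp(log_step_t)),
    }
    return {
        "beta": out_beta,
        "delta": out_delta,
        "logpost": out_lp,
        "V_W": out_VW,
        "V_B": out_VB,
        "X": out_X,
        "M": out_M,
        "acceptance": acc,
        "runtime": time.perf_counter() - t0,
    }


def run(
    study: MatchedStudy,
    spec: MeasurementErrorSpec | None,
    prior: PriorSpec,
    config: SamplerConfig,
    mode: str = "me",
    W: np.ndarray | None = None,
    Z: np.ndarray | None = None,
) -> ChainSet:
    """Run ``config.n_chains`` chains of the sampler and collect the draws.

    ``mode="me"`` targets the full joint posterior (latent exposures sampled);
    ``mode="naive"`` fixes X at the observed W and samples (beta, delta) from
    the conditional-logistic likelihood times the priors.  Pass ``Z`` with
    zero columns to fit an exposure-only ("simple") disease model.
    """
    W = study.W if W is None else np.asarray(W, float)
    Z = study.Z if Z is None else np.asarray(Z, float)
    if mode not in ("me", "naive"):
        raise ValueError("mode must be 'me' or 'naive'")
    sigma2 = None
    if mode == "me":
        if spec is None:
            raise ValueError("measurement-error mode needs a MeasurementErrorSpec")
        sigma2 = np.asarray(spec.sigma2, float)
        if np.any(sigma2 <= 0):
            raise ValueError(
                "zero error variance: run the naive analysis instead of mode='me'"
            )
    prior = prior.resolved(study.P, W, study)

    results = [
        _run_chain(study, W, Z, sigma2, prior, config, mode, c)
        for c in range(config.n_chains)
    ]
    names = list(study.exposure_names[: study.P])
    if Z.shape[1]:
        names += list(study.confounder_names[: Z.shape[1]])
        if len(names) != study.P + Z.shape[1]:
            names = [f"p{i}" for i in range(study.P + Z.shape[1])]
    store = config.store_latent and results[0]["X"] is not None
    return ChainSet(
        beta=np.stack([r["beta"] for r in results]),
        delta=np.stack([r["delta"] for r in results]),
        logpost=np.stack([r["logpost"] for r in results]),
        V_W=np.stack([r["V_W"] for r in results]),
        V_B=np.stack([r["V_B"] for r in results]),
        n_burn=config.n_burn,
        cov_thin=config.cov_thin,
        acceptance=[r["acceptance"] for r in results],
        param_names=names,
        mode=mode,
        config=config,
        X_thin=np.stack([r["X"] for r in results]) if store else None,
        M_thin=np.stack([r["M"] for r in results]) if store else None,
        runtime_s=float(sum(r["runtime"] for r in results)),
    )


def gelman_rubin(chains: ChainSet, param: str = "theta") -> np.ndarray:
    """Split-chain potential scale reduction factor per parameter.

    Each post-burn-in chain is split in half; R-hat compares between- and
    within-half variances.  Values near 1 indicate the chains agree.
    """
    d = chains.post_burn(param)
    if d.shape[0] < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    n = d.shape[1] // 2
    halves = np.concatenate([d[:, :n, :], d[:, n : 2 * n, :]], axis=0)
    W = halves.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = halves.mean(axis=1).var(axis=0, ddof=1)
    out = np.ones(d.shape[2])
    ok = W > 0
    var_hat = (n - 1) / n * W[ok] + B_over_n[ok]
    out[ok] = np.sqrt(var_hat / W[ok])
    return out


def mcse(chains: ChainSet, param: str = "theta") -> np.ndarray:
    """Batch-means Monte Carlo standard error of the posterior-mean estimate.

    Computed per chain with ~sqrt(n) batches, then combined across chains
    (the pooled estimate is the average of the chain means).
    """
    d = chains.post_burn(param)
    C, n, D = d.shape
    if n < 100:
        raise ValueError("chains too short for a batch-means MCSE (need >= 100)")
    a = int(np.sqrt(n))
    m = n // a
    per_chain = np.empty((C, D))
    for c in range(C):
        bm = d[c, : a * m, :].reshape(a, m, D).mean(axis=1)
        var_mean = bm.var(axis=0, ddof=1) * m / (a * m)
        per_chain[c] = var_mean
    return np.sqrt(per_chain.sum(axis=0)) / C
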