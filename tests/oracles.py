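"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (grids,
quadrature, textbook densities, a plain conjugate Gibbs sampler) and never
calls into the package's own computational paths.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import multigammaln


def posterior_beta_quadrature(
    W_pairs: np.ndarray,
    v_w: float,
    v_b: float,
    sigma2: float,
    mu: float,
    beta_var: float,
    bgrid: np.ndarray,
    n_nodes: int = 48,
):
    """Posterior mean/SD of beta for P=1, pairs-only sets, by deterministic quadrature.

    The set means are integrated out analytically: within one set of size 2
    the true exposures are bivariate normal with covariance v_b*J + v_w*I.
    The latent exposures are then integrated by tensorized Gauss-Hermite
    quadrature, and beta by a dense grid.
    """
    nodes, wts = hermegauss(n_nodes)
    wts = wts / np.sqrt(2.0 * np.pi)
    V = v_b * np.ones((2, 2)) + v_w * np.eye(2)
    L = np.linalg.cholesky(V)
    z1, z2 = np.meshgrid(nodes, nodes, indexing="ij")
    wt = np.outer(wts, wts)
    x1 = mu + L[0, 0] * z1
    x2 = mu + L[1, 0] * z1 + L[1, 1] * z2
    d = x1 - x2
    loglik = np.zeros(len(bgrid))
    for w1, w2 in W_pairs:
        meas = np.exp(-((w1 - x1) ** 2 + (w2 - x2) ** 2) / (2 * sigma2)) / (
            2 * np.pi * sigma2
        )
        base = meas * wt
        lik = (base[None] / (1.0 + np.exp(-bgrid[:, None, None] * d[None]))).sum(
            axis=(1, 2)
        )
        loglik += np.log(lik)
    logpost = loglik - bgrid**2 / (2 * beta_var)
    logpost -= logpost.max()
    p = np.exp(logpost)
    p /= np.trapezoid(p, bgrid)
    mean = np.trapezoid(bgrid * p, bgrid)
    sd = np.sqrt(np.trapezoid((bgrid - mean) ** 2 * p, bgrid))
    return float(mean), float(sd)


def exact_recovery_sd(sigma: float, c: float, spike: float) -> float:
    """Exact SD of the percent recovery under the log-normal error model.

    Q = A e^{s(e_s - e_g)} - B e^{s(e - e_g)} with A=(c+a)/a, B=c/a is a
    difference of correlated log-normals; its variance follows from the
    log-normal moment formula.  The first-order expansion in s^2 is the
    delta-method variance s^2 * g(c, a).
    """
    A = (c + spike) / spike
    B = c / spike
    s2 = sigma**2
    var = (
        (A * A + B * B) * np.exp(4 * s2)
        - 2 * A * B * np.exp(3 * s2)
        - np.exp(2 * s2)
    )
    return float(np.sqrt(var))


def conditional_logistic_set_probs(x_set: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Probability that each member of one set is the case, by direct enumeration."""
    eta = np.atleast_2d(x_set) @ np.atleast_1d(beta)
    e = np.exp(eta - eta.max())
    return e / e.sum()


def wishart_logpdf_textbook(Lam: np.ndarray, df: float, scale: np.ndarray) -> float:
    """Wishart log-density, coded from the textbook formula."""
    P = Lam.shape[0]
    s, ld_lam = np.linalg.slogdet(Lam)
    s2, ld_scale = np.linalg.slogdet(scale)
    quad = np.trace(np.linalg.solve(scale, Lam))
    return float(
        0.5 * (df - P - 1) * ld_lam
        - 0.5 * quad
        - 0.5 * df * P * np.log(2.0)
        - 0.5 * df * ld_scale
        - multigammaln(0.5 * df, P)
    )


def gibbs_two_level_normal(
    X: np.ndarray,
    sizes: np.ndarray,
    mu: np.ndarray,
    R: np.ndarray,
    df: float,
    n_iter: int,
    n_burn: int,
    seed: int,
):
    """Plain conjugate Gibbs sampler for the two-level normal model with X known.

    Model: X_ij ~ N(M_i, V_W), M_i ~ N(mu, V_B), Wishart(df, R^-1) priors on
    both precisions.  Returns posterior-mean estimates of M, V_W and V_B.
    """
    from scipy.stats import wishart

    rng = np.random.default_rng(seed)
    N = len(sizes)
    S, P = X.shape
    offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    set_index = np.repeat(np.arange(N), sizes)
    sums = np.add.reduceat(X, offsets, axis=0)
    M = sums / sizes[:, None]
    lam_W = np.eye(P)
    lam_B = np.eye(P)
    acc_M = np.zeros_like(M)
    acc_VW = np.zeros((P, P))
    acc_VB = np.zeros((P, P))
    kept = 0
    for t in range(n_iter):
        for i in range(N):
            prec = lam_B + sizes[i] * lam_W
            cov = np.linalg.inv(prec)
            mean = cov @ (lam_B @ mu + lam_W @ sums[i])
            M[i] = rng.multivariate_normal(mean, cov)
        e_w = X - M[set_index]
        lam_W = wishart.rvs(df + S, np.linalg.inv(R + e_w.T @ e_w), random_state=rng)
        lam_W = np.atleast_2d(lam_W)
        e_b = M - mu
        lam_B = wishart.rvs(df + N, np.linalg.inv(R + e_b.T @ e_b), random_state=rng)
        lam_B = np.atleast_2d(lam_B)
        if t >= n_burn:
            kept += 1
            acc_M += M
            acc_VW += np.linalg.inv(lam_W)
            acc_VB += np.linalg.inv(lam_B)
    return acc_M / kept, acc_VW / kept, acc_VB / kept
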