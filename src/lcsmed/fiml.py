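"""Full-information maximum likelihood for a single regression equation.

Treats (response, predictors) as jointly multivariate normal, estimates
the mean vector and covariance matrix from all rows with at least one
observed value via EM, and maps the MLE to regression coefficients
through the conditional-normal identities

    slopes    = Sigma_xx^{-1} sigma_xy
    intercept = mu_y - slopes . mu_x

Standard errors come from the observed information: the observed-data
log-likelihood is Hessian-differentiated numerically in a Cholesky
parametrization (which keeps perturbed covariances positive definite) and
the coefficient covariance follows by the delta method.

This is a sensitivity option; listwise deletion remains the default
policy of the change-score engine.
"""
from __future__ import annotations

import numpy as np

__all__ = ["em_mvnorm", "fiml_regression"]

_LOG2PI = np.log(2.0 * np.pi)


def _patterns(Y: np.ndarray):
    masks = ~np.isnan(Y)
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(masks):
        groups.setdefault(row.tobytes(), []).append(i)
    out = []
    for key, idx in groups.items():
        obs = np.frombuffer(key, dtype=bool).copy()
        out.append((obs, np.asarray(idx)))
    return out


def _obs_loglik(Y_patterns, mu: np.ndarray, Sigma: np.ndarray) -> float:
    ll = 0.0
    for obs, idx, rows_obs in Y_patterns:
        o = np.flatnonzero(obs)
        Soo = Sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(Soo)
        if sign <= 0:
            return -np.inf
        dev = rows_obs - mu[o]
        quad = np.einsum("ij,jk,ik->", dev, np.linalg.inv(Soo), dev)
        ll += -0.5 * (len(idx) * (len(o) * _LOG2PI + logdet) + quad)
    return ll


def em_mvnorm(
    Y: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, float]:
    """EM estimate of (mu, Sigma) from data with NaN missing values.

    Rows with no observed value must be removed by the caller.
    Returns ``(mu, Sigma, loglik)``.
    """
    Y = np.asarray(Y, float)
    n, p = Y.shape
    mu = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0)
    var[var <= 0] = 1.0
    Sigma = np.diag(var)
    pats = [(obs, idx, Y[idx][:, obs]) for obs, idx in _patterns(Y)]
    prev = -np.inf
    for _ in range(max_iter):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        for obs, idx, rows_obs in pats:
            o = np.flatnonzero(obs)
            m = np.flatnonzero(~obs)
            k = len(idx)
            if m.size == 0:
                S1 += rows_obs.sum(axis=0)
                S2 += rows_obs.T @ rows_obs
                continue
            Soo_inv = np.linalg.inv(Sigma[np.ix_(o, o)])
            B = Sigma[np.ix_(m, o)] @ Soo_inv
            cond_mean = mu[m] + (rows_obs - mu[o]) @ B.T
            cond_cov = Sigma[np.ix_(m, m)] - B @ Sigma[np.ix_(o, m)]
            Ex = np.empty((k, p))
            Ex[:, o] = rows_obs
            Ex[:, m] = cond_mean
            S1 += Ex.sum(axis=0)
            S2 += Ex.T @ Ex
            add = np.zeros((p, p))
            add[np.ix_(m, m)] = k * cond_cov
            S2 += add
        mu = S1 / n
        Sigma = S2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = _obs_loglik(pats, mu, Sigma)
        if ll - prev < tol * (abs(prev) + 1.0):
            prev = ll
            break
        prev = ll
    return mu, Sigma, prev


def _theta_to_params(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    mu = theta[:p]
    L = np.zeros((p, p))
    L[np.tril_indices(p)] = theta[p:]
    return mu, L @ L.T


def _params_to_theta(mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(Sigma)
    return np.concatenate([mu, L[np.tril_indices(len(mu))]])


def _beta_of(mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    slopes = np.linalg.solve(Sigma[1:, 1:], Sigma[1:, 0])
    return np.concatenate([[mu[0] - slopes @ mu[1:]], slopes])


def fiml_regression(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """FIML point estimates and SEs for ``column 0 ~ columns 1..``.

    ``Y`` holds the response in column 0 and predictors in the remaining
    columns; NaN marks missing.  Returns ``(beta, se, n_used)`` where
    ``beta[0]`` is the intercept.
    """
    Y = np.asarray(Y, float)
    Y = Y[~np.isnan(Y).all(axis=1)]
    n, p = Y.shape
    mu, Sigma, _ = em_mvnorm(Y)
    beta = _beta_of(mu, Sigma)

    pats = [(obs, idx, Y[idx][:, obs]) for obs, idx in _patterns(Y)]
    theta = _params_to_theta(mu, Sigma)

    def nll(t: np.ndarray) -> float:
        m, S = _theta_to_params(t, p)
        return -_obs_loglik(pats, m, S)

    d = len(theta)
    h = 1e-4 * (np.abs(theta) + 1.0)
    H = np.empty((d, d))
    f0 = nll(theta)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll(theta + ei + ej)
                - nll(theta + ei - ej)
                - nll(theta - ei + ej)
                + nll(theta - ei - ej)
            ) / (4 * h[i] * h[j])

    def g(t: np.ndarray) -> np.ndarray:
        m, S = _theta_to_params(t, p)
        return _beta_of(m, S)

    J = np.empty((p, d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        J[:, i] = (g(theta + ei) - g(theta - ei)) / (2 * h[i])

    cov_theta = np.linalg.pinv(H)
    cov_beta = J @ cov_theta @ J.T
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    return beta, se, n
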