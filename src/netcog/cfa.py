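"""One-factor confirmatory factor model of general cognitive function.

Scores on diverse cognitive tests correlate positively; the shared
variance is summarized by a single latent factor g. The measurement
model is x_j = mu_j + lambda_j * g + eps_j with Var(g) fixed to 1 for
identification (all loadings free, first loading constrained positive
by sign convention) and a diagonal residual covariance Theta, optionally
augmented with free residual covariances between named test pairs
(e.g. within-domain method variance).

Missing test scores are handled by full-information maximum likelihood
(FIML): each participant contributes the log-density of their observed
variables under the model-implied moments, so no case is dropped.
Fit is assessed against a saturated model (free mean vector and
covariance matrix, estimated by EM under missingness) and an
independence baseline (diagonal covariance, closed-form under FIML),
yielding CFI, TLI, RMSEA and SRMR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular

logger = logging.getLogger(__name__)

_LN2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GFactorSpec:
    """Names of the battery's tests plus free residual-covariance pairs."""

    test_names: tuple[str, ...]
    residual_covariances: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        p = len(self.test_names)
        if p < 3:
            raise ValueError("at least 3 tests needed to identify a one-factor model")
        seen = set()
        for a, b in self.residual_covariances:
            if not (0 <= a < p and 0 <= b < p) or a == b:
                raise ValueError(f"invalid residual covariance pair ({a}, {b})")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate residual covariance pair {key}")
            seen.add(key)

    @property
    def n_tests(self) -> int:
        return len(self.test_names)


@dataclass
class GFactorFit:
    spec: GFactorSpec
    loadings: np.ndarray          # raw-metric loadings
    std_loadings: np.ndarray      # standardized (correlation-metric) loadings
    theta: np.ndarray             # residual covariance matrix
    intercepts: np.ndarray
    loglik: float
    loglik_saturated: float
    loglik_baseline: float
    df_model: int
    df_baseline: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    converged: bool
    n_used: int
    n_iter: int
    loglik_path: list = field(default_factory=list, repr=False)

    @property
    def implied_cov(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + self.theta


# ---------------------------------------------------------------------------
# missingness-pattern bookkeeping shared with the structural models


def group_patterns(X: np.ndarray):
    """Group rows of X (NaN = missing) by missingness pattern.

    Returns a list of (observed_indices, row_indices, X_observed) with
    all-missing rows excluded.
    """
    X = np.asarray(X, dtype=float)
    obs = ~np.isnan(X)
    keys, inverse = np.unique(obs, axis=0, return_inverse=True)
    out = []
    for k in range(keys.shape[0]):
        o = np.flatnonzero(keys[k])
        if o.size == 0:
            continue
        rows = np.flatnonzero(inverse == k)
        out.append((o, rows, X[np.ix_(rows, o)]))
    return out


def fiml_loglik(mu: np.ndarray, Sigma: np.ndarray, patterns) -> float:
    """Casewise FIML log-likelihood summed over missingness patterns."""
    ll = 0.0
    for o, _rows, Xo in patterns:
        So = Sigma[np.ix_(o, o)]
        try:
            L = np.linalg.cholesky(So)
        except np.linalg.LinAlgError:
            return -np.inf
        k = o.size
        logdet = 2.0 * np.log(np.diag(L)).sum()
        R = Xo - mu[o]
        Z = solve_triangular(L, R.T, lower=True)
        quad = (Z**2).sum()
        ll += -0.5 * (Xo.shape[0] * (k * _LN2PI + logdet) + quad)
    return float(ll)


# ---------------------------------------------------------------------------
# saturated and baseline models


def em_saturated(X: np.ndarray, max_iter: int = 500, tol: float = 1e-9):
    """EM estimate of an unstructured MVN (mu, Sigma) under missing data.

    Returns (mu, Sigma, loglik). Standard sweep-free EM: the E-step
    imputes conditional means and adds conditional covariances, the
    M-step recomputes moments.
    """
    X = np.asarray(X, dtype=float)
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var = np.where(var > 0, var, 1.0)
    Sigma = np.diag(var)
    patterns = group_patterns(X)
    ll_old = -np.inf
    for _ in range(max_iter):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        for o, rows, Xo in patterns:
            m = np.setdiff1d(np.arange(p), o)
            nr = rows.size
            if m.size == 0:
                S1 += Xo.sum(axis=0)
                S2[np.ix_(o, o)] += Xo.T @ Xo
                continue
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(m, o)]
            Smm = Sigma[np.ix_(m, m)]
            B = np.linalg.solve(Soo, Smo.T).T          # regression of missing on observed
            resid_cov = Smm - B @ Smo.T                # conditional covariance
            Xm = mu[m] + (Xo - mu[o]) @ B.T            # conditional means
            S1[o] += Xo.sum(axis=0)
            S1[m] += Xm.sum(axis=0)
            S2[np.ix_(o, o)] += Xo.T @ Xo
            S2[np.ix_(o, m)] += Xo.T @ Xm
            S2[np.ix_(m, o)] += Xm.T @ Xo
            S2[np.ix_(m, m)] += Xm.T @ Xm + nr * resid_cov
        mu = S1 / n
        Sigma = S2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = fiml_loglik(mu, Sigma, patterns)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    return mu, Sigma, fiml_loglik(mu, Sigma, patterns)


def baseline_loglik(X: np.ndarray) -> float:
    """FIML log-likelihood of the independence model (closed form).

    With a diagonal covariance the likelihood factorizes per variable,
    so each variable's ML mean/variance use its own observed entries.
    """
    X = np.asarray(X, dtype=float)
    ll = 0.0
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[~np.isnan(x)]
        nj = x.size
        if nj == 0:
            continue
        m = x.mean()
        v = ((x - m) ** 2).mean()
        if v <= 0:
            raise ValueError(f"test column {j} has zero variance")
        ll += -0.5 * nj * (_LN2PI + np.log(v) + 1.0)
    return float(ll)


# ---------------------------------------------------------------------------
# fit indices


def fit_indices(loglik_model: float, loglik_saturated: float,
                loglik_baseline: float, df_model: int, df_baseline: int,
                n: int, srmr: float = np.nan) -> dict:
    """Likelihood-ratio-based fit indices (CFI, TLI, RMSEA), plus SRMR.

    T = 2 (ll_sat - ll_model) is the model chi-square statistic.
    """
    if df_baseline <= 0:
        raise ValueError("baseline df must be positive")
    Tm = max(2.0 * (loglik_saturated - loglik_model), 0.0)
    Tb = max(2.0 * (loglik_saturated - loglik_baseline), 0.0)
    num = max(Tm - df_model, 0.0)
    den = max(Tb - df_baseline, Tm - df_model, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    rb = Tb / df_baseline
    rm = Tm / df_model if df_model > 0 else 0.0
    tli = (rb - rm) / (rb - 1.0) if rb != 1.0 else 1.0
    rmsea = np.sqrt(max(Tm - df_model, 0.0) / (df_model * n)) if df_model > 0 else 0.0
    return {"CFI": float(cfi), "TLI": float(tli), "RMSEA": float(rmsea),
            "SRMR": float(srmr)}


def _srmr(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """Root mean square residual between sample and implied correlations."""
    ds = np.sqrt(np.diag(sample_cov))
    di = np.sqrt(np.diag(implied_cov))
    Rs = sample_cov / np.outer(ds, ds)
    Ri = implied_cov / np.outer(di, di)
    iu = np.triu_indices(sample_cov.shape[0])  # includes (unit) diagonal
    return float(np.sqrt(np.mean((Rs[iu] - Ri[iu]) ** 2)))


# ---------------------------------------------------------------------------
# model fitting


def _unpack(theta_vec: np.ndarray, p: int, rescov):
    lam = theta_vec[:p]
    tdiag = theta_vec[p:2 * p]
    mu = theta_vec[2 * p:3 * p]
    Theta = np.diag(tdiag)
    for k, (a, b) in enumerate(rescov):
        Theta[a, b] = Theta[b, a] = theta_vec[3 * p + k]
    return lam, Theta, mu


def fit_g_model(tests: pd.DataFrame | np.ndarray, spec: GFactorSpec,
                max_iter: int = 500) -> GFactorFit:
    """Fit the one-factor model by FIML and compute fit indices.

    ``tests`` is a participants x tests matrix (DataFrame columns are
    matched to ``spec.test_names``); NaN marks a missing score.
    """
    if isinstance(tests, pd.DataFrame):
        X = tests.loc[:, list(spec.test_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(tests, dtype=float)
    p = spec.n_tests
    if X.shape[1] != p:
        raise ValueError(f"expected {p} test columns, got {X.shape[1]}")
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    n = X.shape[0]
    n_obs_per_test = (~np.isnan(X)).sum(axis=0)
    if np.any(n_obs_per_test < 2):
        raise ValueError("each test must be observed for at least 2 participants")
    patterns = group_patterns(X)

    mu0 = np.nanmean(X, axis=0)
    var0 = np.nanvar(X, axis=0, ddof=1)
    var0 = np.where(var0 > 0, var0, 1.0)
    start = np.concatenate([
        np.sqrt(0.5 * var0),      # loadings
        0.5 * var0,               # residual variances
        mu0,                      # intercepts
        np.zeros(len(spec.residual_covariances)),
    ])
    rescov = spec.residual_covariances
    path: list[float] = []

    def negloglik(vec: np.ndarray) -> float:
        lam, Theta, mu = _unpack(vec, p, rescov)
        Sigma = np.outer(lam, lam) + Theta
        ll = fiml_loglik(mu, Sigma, patterns)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    lb = np.full(start.size, -np.inf)
    ub = np.full(start.size, np.inf)
    lb[p:2 * p] = 1e-6  # residual variances positive
    res = optimize.minimize(
        negloglik, start, method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        callback=lambda v: path.append(-negloglik(v)),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    lam, Theta, mu = _unpack(res.x, p, rescov)
    if lam[0] < 0:  # sign convention: first loading positive
        lam = -lam
    loglik = -res.fun
    grad_norm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.nan
    converged = bool(res.success) or grad_norm < 1e-3 * (1 + abs(loglik))
    if not converged:
        logger.warning("g-model optimizer did not converge: %s (|grad| = %.2e)",
                       res.message, grad_norm)

    _, _, ll_sat = em_saturated(X)
    ll_base = baseline_loglik(X)
    n_free = 3 * p + len(rescov)
    n_moments = p + p * (p + 1) // 2
    df_m = n_moments - n_free
    df_b = n_moments - 2 * p

    complete = X[~np.isnan(X).any(axis=1)]
    if complete.shape[0] > p + 1:
        S = np.cov(complete, rowvar=False, bias=True)
        srmr = _srmr(S, np.outer(lam, lam) + Theta)
    else:
        srmr = np.nan

    fi = fit_indices(loglik, ll_sat, ll_base, df_m, df_b, n, srmr)
    implied_sd = np.sqrt(np.diag(np.outer(lam, lam) + Theta))
    return GFactorFit(
        spec=spec, loadings=lam, std_loadings=lam / implied_sd, theta=Theta,
        intercepts=mu, loglik=loglik, loglik_saturated=ll_sat,
        loglik_baseline=ll_base, df_model=df_m, df_baseline=df_b,
        cfi=fi["CFI"], tli=fi["TLI"], rmsea=fi["RMSEA"], srmr=fi["SRMR"],
        converged=converged, n_used=n, n_iter=int(res.nit), loglik_path=path,
    )


def score_reliability(fit: GFactorFit, tests: pd.DataFrame | np.ndarray) -> float:
    """Mean squared correlation between regression scores and latent g.

    For a participant observing the test subset o, the regression score
    has Var = corr(score, g)^2 = lambda_o' Sigma_o^{-1} lambda_o; the
    sample mean of this quantity over observed patterns is the
    reliability used to disattenuate factor-score regressions.
    """
    if isinstance(tests, pd.DataFrame):
        X = tests.loc[:, list(fit.spec.test_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(tests, dtype=float)
    Sigma = fit.implied_cov
    lam = fit.loadings
    obs = ~np.isnan(X)
    keys, inverse = np.unique(obs, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=keys.shape[0])
    total_w = 0.0
    total_n = 0
    for k in range(keys.shape[0]):
        o = np.flatnonzero(keys[k])
        if o.size == 0:
            continue
        rho2 = float(lam[o] @ np.linalg.solve(Sigma[np.ix_(o, o)], lam[o]))
        total_w += counts[k] * rho2
        total_n += counts[k]
    return total_w / total_n if total_n else np.nan


def factor_scores(fit: GFactorFit, tests: pd.DataFrame | np.ndarray) -> pd.Series:
    """Regression-method factor scores, standardized over the sample.

    g_hat_i = lambda_o' Sigma_o^{-1} (x_o - mu_o) over each participant's
    observed pattern; participants with no observed tests get NaN.
    """
    if not fit.converged:
        raise ValueError("cannot score from a non-converged fit")
    if isinstance(tests, pd.DataFrame):
        index = tests.index
        X = tests.loc[:, list(fit.spec.test_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(tests, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    Sigma = fit.implied_cov
    lam, mu = fit.loadings, fit.intercepts
    scores = np.full(X.shape[0], np.nan)
    obs = ~np.isnan(X)
    keys, inverse = np.unique(obs, axis=0, return_inverse=True)
    for k in range(keys.shape[0]):
        o = np.flatnonzero(keys[k])
        rows = np.flatnonzero(inverse == k)
        if o.size == 0:
            logger.warning("%d participant(s) with no observed tests: score missing",
                           rows.size)
            continue
        w = np.linalg.solve(Sigma[np.ix_(o, o)], lam[o])
        scores[rows] = (X[np.ix_(rows, o)] - mu[o]) @ w
    valid = ~np.isnan(scores)
    m, s = scores[valid].mean(), scores[valid].std(ddof=0)
    if s > 0:
        scores = (scores - m) / s
    return pd.Series(scores, index=index, name="g")
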