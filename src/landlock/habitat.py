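"""Occupancy and richness models for sites above and below waterfalls.

Presence/absence of a species at a site is modelled by logistic regression on
ten environmental factors (a waterfall dummy plus nine continuous measures).
Because species such as the landlocked goby occur *only* above waterfalls the
data are perfectly separated and the ordinary ML estimates diverge; fits use
Firth's bias-reduced (Jeffreys-prior penalised) likelihood, whose estimates
are finite for any full-rank design.  Model choice is exhaustive all-subsets
AIC; discrimination is summarised by the rank-statistic AUC.  Species richness
is a Poisson GLMM with a Gaussian random intercept per river system,
integrated by adaptive Gauss–Hermite quadrature.  A MANOVA (Wilks lambda)
checks whether the joint continuous environment differs above vs below
waterfalls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import f as f_dist
from scipy.stats import rankdata

ENV_FACTORS = (
    "waterfall",
    "watershed_km2",
    "elevation_m",
    "distance_sea_km",
    "river_width_m",
    "water_depth_cm",
    "water_velocity_cm_s",
    "pebble_cm",
    "slope_deg",
    "canopy_pct",
)
CONTINUOUS_FACTORS = ENV_FACTORS[1:]


@dataclass
class GlmFit:
    """A fitted (penalised) GLM: coefficients, AIC and fitted values."""

    predictors: tuple[str, ...]
    coefficients: pd.Series  # index: ("intercept", *predictors), original scale
    std_errors: pd.Series
    log_likelihood: float  # penalised for Firth fits
    aic: float
    fitted: np.ndarray = field(repr=False)
    auc: float | None = None
    converged: bool = True
    random_effect_sd: float | None = None  # GLMM only

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients) + (0 if self.random_effect_sd is None else 1)


def _design(data: pd.DataFrame, predictors, standardize=True):
    """Build [1 | X] with continuous columns z-scored; return transform info."""
    x = data.loc[:, list(predictors)].to_numpy(dtype=float)
    n, k = x.shape
    means = np.zeros(k)
    scales = np.ones(k)
    if standardize:
        for j, name in enumerate(predictors):
            col = x[:, j]
            sd = col.std(ddof=0)
            if set(np.unique(col)).issubset({0.0, 1.0}) or sd == 0:
                continue  # leave dummies / constants alone
            means[j], scales[j] = col.mean(), sd
        x = (x - means) / scales
    X = np.column_stack([np.ones(n), x])
    return X, means, scales


def _unstandardize(beta, cov, means, scales):
    """Map coefficients/covariance from the z-scored to the original scale."""
    k = beta.size - 1
    A = np.eye(k + 1)
    for j in range(k):
        A[0, j + 1] = -means[j] / scales[j]
        A[j + 1, j + 1] = 1.0 / scales[j]
    return A @ beta, A @ cov @ A.T


def firth_penalized_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Jeffreys-prior penalised binomial log-likelihood at ``beta``."""
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = expit(eta)
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic(
    y,
    data: pd.DataFrame | np.ndarray,
    predictors=None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Firth bias-reduced logistic regression.

    The Newton step uses the Firth-modified score
    ``U*_j = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ij`` with ``h`` the hat
    diagonal of the weighted design, so estimates stay finite under complete
    separation.  Continuous predictors are standardized internally for
    conditioning; coefficients and standard errors are reported on the
    original scale.  AIC uses the penalised log-likelihood (the fit
    criterion): ``AIC = -2 pll + 2 (k+1)``.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(data, pd.DataFrame):
        predictors = tuple(predictors if predictors is not None else data.columns)
        X, means, scales = _design(data, predictors)
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        X = np.column_stack([np.ones(len(X)), X])
        predictors = tuple(
            predictors if predictors is not None
            else [f"x{j}" for j in range(X.shape[1] - 1)]
        )
        means, scales = np.zeros(X.shape[1] - 1), np.ones(X.shape[1] - 1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design is rank deficient; check collinearity among {predictors}"
        )

    beta = np.zeros(X.shape[1])
    converged = False
    pll = firth_penalized_loglik(beta, X, y)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        Xw = X * w[:, None]
        info = X.T @ Xw
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", Xw, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        # step-halving on the penalised likelihood for robustness
        for _half in range(16):
            cand = beta + step
            cand_pll = firth_penalized_loglik(cand, X, y)
            if cand_pll >= pll - 1e-10:
                break
            step *= 0.5
        beta, pll = cand, cand_pll
    eta = X @ beta
    p = expit(eta)
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    beta_o, cov_o = _unstandardize(beta, cov, means, scales)
    names = ["intercept", *predictors]
    k = len(beta)
    return GlmFit(
        predictors=predictors,
        coefficients=pd.Series(beta_o, index=names),
        std_errors=pd.Series(np.sqrt(np.diag(cov_o)), index=names),
        log_likelihood=float(pll),
        aic=float(-2.0 * pll + 2.0 * k),
        fitted=p,
        auc=auc(p, y) if 0 < y.sum() < len(y) else None,
        converged=converged,
    )


def auc(fitted_probabilities, y) -> float:
    """Rank-statistic AUC; tied scores between classes count one half."""
    y = np.asarray(y)
    scores = np.asarray(fitted_probabilities, dtype=float)
    pos, neg = scores[y == 1], scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2)
                 / (pos.size * neg.size))


def all_subsets_aic(
    data: pd.DataFrame,
    response: str,
    predictor_pool=ENV_FACTORS,
    fitter=None,
) -> tuple[GlmFit, pd.DataFrame]:
    """Fit every subset of the predictor pool; rank by AIC.

    Ties are broken by fewer parameters, then by lexicographic predictor
    tuple.  Individual fit failures are recorded and skipped.  ``fitter``
    defaults to :func:`firth_logistic`; any callable with the signature
    ``fitter(y, data, predictors)`` returning a :class:`GlmFit` works (the
    richness GLMM reuses this machinery).
    """
    pool = tuple(predictor_pool)
    if len(pool) > 15:
        raise ValueError("exhaustive search limited to 15 predictors")
    fitter = fitter or (lambda y, d, preds: firth_logistic(y, d, preds))
    y = data[response].to_numpy(dtype=float)
    rows = []
    fits = {}
    for r in range(len(pool) + 1):
        for subset in itertools.combinations(pool, r):
            try:
                fit = fitter(y, data, subset)
            except Exception as exc:  # recorded, excluded, run continues
                rows.append({"predictors": subset, "aic": np.nan,
                             "n_parameters": r + 1, "error": str(exc)})
                continue
            fits[subset] = fit
            rows.append({"predictors": subset, "aic": fit.aic,
                         "n_parameters": fit.n_parameters, "error": ""})
    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""].copy()
    if ok.empty:
        raise RuntimeError("every candidate model failed to fit")
    ok = ok.sort_values(
        by=["aic", "n_parameters", "predictors"],
        key=lambda col: col.map(tuple) if col.name == "predictors" else col,
    )
    best = fits[tuple(ok.iloc[0]["predictors"])]
    return best, table.sort_values("aic", na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Poisson GLMM (random intercept per river, adaptive Gauss-Hermite)


def _cluster_loglik(eta, y, sigma, gh_x, gh_w):
    """Adaptive GH log integral for one cluster's random intercept."""
    sy = y.sum()
    # mode of f(z) = sum_i [y_i (eta_i + s z) - exp(eta_i + s z)] - z^2/2
    z = 0.0
    for _ in range(50):
        ez = np.exp(eta + sigma * z).sum()
        g = sigma * sy - sigma * ez - z
        hcurv = -(sigma**2) * ez - 1.0
        step = g / hcurv
        z -= step
        if abs(step) < 1e-12:
            break
    tau = 1.0 / np.sqrt((sigma**2) * np.exp(eta + sigma * z).sum() + 1.0)
    nodes = z + np.sqrt(2.0) * tau * gh_x
    f = (
        (y[:, None] * (eta[:, None] + sigma * nodes[None, :])).sum(axis=0)
        - np.exp(eta[:, None] + sigma * nodes[None, :]).sum(axis=0)
        - nodes**2 / 2.0
    )
    log_int = logsumexp(f + gh_x**2 + np.log(gh_w)) + 0.5 * np.log(2.0) + np.log(tau)
    return log_int - 0.5 * np.log(2.0 * np.pi) - gammaln(y + 1).sum()


def poisson_glmm_loglik(beta, sigma, y, X, group_index, n_nodes=8) -> float:
    """Marginal log-likelihood of the Poisson random-intercept model."""
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_nodes)
    eta = X @ beta
    total = 0.0
    for g in np.unique(group_index):
        sel = group_index == g
        total += _cluster_loglik(eta[sel], y[sel], sigma, gh_x, gh_w)
    return float(total)


def poisson_glmm(
    counts,
    data: pd.DataFrame,
    predictors,
    groups,
    n_nodes: int = 8,
) -> GlmFit:
    """Poisson GLMM: log link, Gaussian random intercept per group (river).

    The marginal likelihood integrates the random intercept by adaptive
    Gauss–Hermite quadrature (``n_nodes`` nodes centred and scaled at each
    cluster's conditional mode) and is maximised over the fixed effects and
    the random-intercept SD.  With a single group, or SD driven to zero, the
    fit coincides with a plain Poisson GLM.
    """
    y = np.asarray(counts, dtype=float)
    if not np.allclose(y, np.round(y)) or (y < 0).any():
        raise ValueError("counts must be non-negative integers")
    predictors = tuple(predictors)
    X, means, scales = _design(data, predictors)
    group_index = pd.factorize(np.asarray(groups))[0]
    k = X.shape[1]

    def negll(theta):
        beta, sigma = theta[:k], abs(theta[k])
        try:
            return -poisson_glmm_loglik(beta, sigma, y, X, group_index, n_nodes)
        except FloatingPointError:
            return np.inf

    start = np.zeros(k + 1)
    start[0] = np.log(max(y.mean(), 0.1))
    start[k] = 0.1
    with np.errstate(over="raise"):
        res = minimize(negll, start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
        res = minimize(negll, res.x, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 20000})
    beta, sigma = res.x[:k], abs(res.x[k])
    ll = -res.fun
    beta_o, _ = _unstandardize(beta, np.eye(k), means, scales)
    names = ["intercept", *predictors]
    fitted = np.exp(X @ beta)
    return GlmFit(
        predictors=predictors,
        coefficients=pd.Series(beta_o, index=names),
        std_errors=pd.Series(np.full(k, np.nan), index=names),
        log_likelihood=float(ll),
        aic=float(-2.0 * ll + 2.0 * (k + 1)),
        fitted=fitted,
        converged=bool(res.success),
        random_effect_sd=float(sigma),
    )


def glmm_fitter(groups, n_nodes: int = 8):
    """Adapter so :func:`all_subsets_aic` can rank Poisson GLMM subsets."""

    def fit(y, data, predictors):
        return poisson_glmm(y, data, predictors, groups, n_nodes=n_nodes)

    return fit


# ---------------------------------------------------------------------------
# MANOVA


@dataclass
class ManovaResult:
    wilks_lambda: float
    F: float
    df: tuple[int, int]
    p: float


def manova_wilks(env: pd.DataFrame | np.ndarray, labels) -> ManovaResult:
    """Wilks lambda MANOVA for a two-group comparison of a multivariate mean.

    ``lambda = det(W)/det(T)`` with W the pooled within-group and T the total
    scatter matrix; with two groups Rao's F transformation is exact:
    ``F = ((1-lambda)/lambda) * (n-p-1)/p`` on (p, n-p-1) df.
    """
    x = np.asarray(env, dtype=float)
    labels = np.asarray(labels)
    n, p = x.shape
    groups = [x[labels == g] for g in pd.unique(labels)]
    if len(groups) != 2:
        raise ValueError("two groups required")
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    xc = x - x.mean(axis=0)
    T = xc.T @ xc
    W = np.zeros((p, p))
    for g in groups:
        gc = g - g.mean(axis=0)
        W += gc.T @ gc
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0:
        raise ValueError("singular total scatter matrix")
    lam = 0.0 if sign_w <= 0 else float(np.exp(logdet_w - logdet_t))
    df = (p, n - p - 1)
    if lam == 0.0:
        return ManovaResult(0.0, float("inf"), df, 0.0)
    F = (1.0 - lam) / lam * df[1] / df[0]
    return ManovaResult(lam, float(F), df, float(f_dist.sf(F, *df)))
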