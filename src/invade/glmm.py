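"""Univariate binomial GLMM screen of invasion-intensity predictors.

Each candidate predictor (a life-history trait, ED, or BL) is fitted in
its own logistic mixed model

    logit P(y_ij = 1) = b0 + b1 * x_ij + u_j,   u_j ~ N(0, sigma^2)

with a family-level random intercept u_j.  The marginal likelihood is
maximized with the random effect integrated out by adaptive
Gauss-Hermite quadrature (each group's integrand is re-centered at its
conditional mode and rescaled by its curvature before applying the
quadrature rule), the same integral approximation used by standard
mixed-model software.  Standard errors come from the observed
information (numerical Hessian of the negative marginal log-likelihood),
and p-values from the two-sided normal tail of z = estimate / SE.

After the per-predictor fits, significant predictors are pruned for
redundancy: while any retained pair is correlated beyond a threshold
(default |r| >= 0.7, Pearson on pairwise-complete data), the member with
the larger p-value is dropped, largest p first, ties broken by name.

Predictors are used on their raw scale, so estimates are per predictor
unit on the logit scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess

from .tables import StatusTable, TraitTable

__all__ = ["GLMMResult", "ScreenResult", "fit_binomial_glmm", "screen_traits",
           "redundancy_filter"]

log = logging.getLogger(__name__)

_THETA_MIN, _THETA_MAX = -8.0, 3.0  # bounds on log(sigma)


@dataclass
class GLMMResult:
    predictor: str
    estimate: float
    se: float
    z: float
    p: float
    n_used: int
    n_groups: int
    sigma: float
    intercept: float
    converged: bool
    message: str = ""

    def to_row(self) -> dict:
        return {
            "predictor": self.predictor, "estimate": self.estimate,
            "se": self.se, "z": self.z, "p": self.p,
            "n_used": self.n_used, "n_groups": self.n_groups,
            "sigma": self.sigma, "converged": self.converged,
        }


@dataclass
class ScreenResult:
    results: pd.DataFrame
    significant: list[str]
    correlations: pd.DataFrame | None
    retained: list[str]
    alpha: float
    corr_threshold: float
    skipped: dict[str, str] = field(default_factory=dict)


def _pad_by_group(y: np.ndarray, x: np.ndarray, codes: np.ndarray):
    """Reshape observation vectors into (n_groups, max_group_size) padded
    arrays plus a validity mask, for vectorized per-group likelihoods."""
    n_groups = codes.max() + 1
    counts = np.bincount(codes, minlength=n_groups)
    nmax = counts.max()
    Y = np.zeros((n_groups, nmax))
    X = np.zeros((n_groups, nmax))
    M = np.zeros((n_groups, nmax))
    slot = np.zeros(n_groups, dtype=np.intp)
    for i, g in enumerate(codes):
        j = slot[g]
        Y[g, j] = y[i]
        X[g, j] = x[i]
        M[g, j] = 1.0
        slot[g] += 1
    return Y, X, M


def _group_modes(eta0, Y, M, sigma, n_newton=50, tol=1e-10):
    """Conditional modes u_g of log f(y_g|u) + log phi(u) per group, with the
    curvature -g'' at the mode.  The integrand is log-concave in u, so
    undamped Newton from 0 converges quadratically."""
    G = eta0.shape[0]
    u = np.zeros(G)
    for _ in range(n_newton):
        eta = eta0 + sigma * u[:, None]
        p = special.expit(eta)
        grad = sigma * (M * (Y - p)).sum(axis=1) - u
        hess = -(sigma**2) * (M * p * (1 - p)).sum(axis=1) - 1.0
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta0 + sigma * u[:, None]
    p = special.expit(eta)
    curv = (sigma**2) * (M * p * (1 - p)).sum(axis=1) + 1.0
    return u, curv


def _marginal_nll(params, Y, X, M, z_q, w_log):
    """Negative marginal log-likelihood via adaptive Gauss-Hermite quadrature."""
    b0, b1, theta = params
    sigma = np.exp(theta)
    eta0 = b0 + b1 * X
    u_hat, curv = _group_modes(eta0, Y, M, sigma)
    tau = 1.0 / np.sqrt(curv)                       # (G,)
    u_q = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * z_q[None, :]   # (G, Q)
    eta = eta0[:, None, :] + sigma * u_q[:, :, None]                    # (G, Q, n)
    loglik_obs = M[:, None, :] * (Y[:, None, :] * eta - np.logaddexp(0.0, eta))
    g = loglik_obs.sum(axis=2) - 0.5 * u_q**2       # (G, Q): log f + log-kernel of phi
    terms = w_log[None, :] + z_q[None, :] ** 2 + g
    ll_g = (special.logsumexp(terms, axis=1)
            + 0.5 * np.log(2.0) + np.log(tau) - 0.5 * np.log(2.0 * np.pi))
    return -ll_g.sum()


def _logistic_start(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Crude IRLS logistic fit for starting values."""
    Xd = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(25):
        p = special.expit(Xd @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        try:
            delta = np.linalg.solve(Xd.T @ (w[:, None] * Xd), Xd.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < 1e-8:
            break
        if np.max(np.abs(beta)) > 50:
            break
    return float(beta[0]), float(beta[1])


def fit_binomial_glmm(y, x, group, predictor: str = "x",
                      n_quad: int = 15) -> GLMMResult:
    """Fit ``logit P(y=1) = b0 + b1 x + u_group`` by adaptive quadrature ML.

    Parameters
    ----------
    y, x, group
        Equal-length sequences: binary response, numeric predictor, and a
        grouping factor (the family).  Rows are assumed complete.
    n_quad
        Number of Gauss-Hermite nodes (15 is accurate well past the
        1e-3 contract used in the tests).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    codes, groups = pd.factorize(np.asarray(group))
    if y.size != x.size or y.size != codes.size:
        raise ValueError("y, x and group must have equal length")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("response has a single class among complete cases")
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    Y, X, M = _pad_by_group(y, x, codes)
    z_q, w_q = hermgauss(n_quad)
    w_log = np.log(w_q)
    nll = lambda params: _marginal_nll(params, Y, X, M, z_q, w_log)

    b0_0, b1_0 = _logistic_start(y, x)
    best = None
    for theta0 in (-0.5, -3.0):
        res = optimize.minimize(
            nll, x0=np.array([b0_0, b1_0, theta0]), method="L-BFGS-B",
            bounds=[(None, None), (None, None), (_THETA_MIN, _THETA_MAX)],
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    b0, b1, theta = best.x
    sigma = float(np.exp(theta))

    message = "" if best.success else str(best.message)
    # observed information; drop the variance parameter when it sits on the
    # sigma ~ 0 boundary (the model has collapsed to plain logistic).
    try:
        if theta <= _THETA_MIN + 0.5:
            h = approx_hess(np.array([b0, b1]),
                            lambda b: nll(np.array([b[0], b[1], theta])))
            cov = np.linalg.inv(h)
            se = float(np.sqrt(cov[1, 1]))
        else:
            h = approx_hess(best.x, nll)
            cov = np.linalg.inv(h)
            se = float(np.sqrt(cov[1, 1]))
    except (np.linalg.LinAlgError, ValueError):
        se = np.nan
        message = (message + "; " if message else "") + "singular information matrix"

    converged = bool(best.success) and np.isfinite(se) and se > 0
    if abs(b1) > 30 or (np.isfinite(se) and se > 1e3):
        converged = False
        message = (message + "; " if message else "") + "possible separation"
    z = float(b1 / se) if np.isfinite(se) and se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return GLMMResult(predictor, float(b1), se, z, p, int(y.size),
                      int(len(groups)), sigma, float(b0), converged, message)


def screen_traits(status: StatusTable, traits: TraitTable | None = None,
                  metrics: pd.DataFrame | None = None,
                  alpha: float = 0.05, corr_threshold: float = 0.7,
                  min_n: int = 10, n_quad: int = 15) -> ScreenResult:
    """One univariate GLMM per predictor; prune correlated significant ones.

    Predictors are every trait column plus the ED and BL columns of
    ``metrics`` when supplied.  Each model uses the complete cases for
    its own predictor (so the usable n varies by predictor).  Predictors
    with fewer than ``min_n`` complete cases, a constant value, or a
    single response class are skipped with a logged reason.
    """
    base = status.data.set_index("species")[["y", "family"]]
    pred_tables = []
    if traits is not None:
        pred_tables.append(traits.data)
    if metrics is not None:
        pred_tables.append(metrics[["ED", "BL"]]
                           if {"ED", "BL"} <= set(metrics.columns) else metrics)
    if not pred_tables:
        raise ValueError("no predictors: supply traits and/or metrics")
    preds = pd.concat(pred_tables, axis=1)
    preds = preds.loc[preds.index.intersection(base.index)]
    joined = base.join(preds, how="left")

    rows, skipped = [], {}
    for col in preds.columns:
        sub = joined[["y", "family", col]].dropna()
        if len(sub) < min_n:
            skipped[col] = f"only {len(sub)} complete cases (< {min_n})"
        elif sub[col].nunique() < 2:
            skipped[col] = "constant predictor"
        elif sub["y"].nunique() < 2:
            skipped[col] = "single response class among complete cases"
        elif sub["family"].nunique() < 2:
            skipped[col] = "fewer than 2 families among complete cases"
        else:
            try:
                rows.append(fit_binomial_glmm(sub["y"], sub[col], sub["family"],
                                              predictor=col, n_quad=n_quad))
            except (ValueError, np.linalg.LinAlgError) as exc:
                skipped[col] = str(exc)
    for col, why in skipped.items():
        log.warning("skipping predictor %s: %s", col, why)

    results = pd.DataFrame([r.to_row() for r in rows])
    if results.empty:
        return ScreenResult(results, [], None, [], alpha, corr_threshold, skipped)
    significant = results.loc[results["p"] < alpha, "predictor"].tolist()
    corr = None
    retained = list(significant)
    if len(significant) >= 2:
        corr = joined[significant].corr(method="pearson", min_periods=3)
        retained = redundancy_filter(results, joined[significant],
                                     threshold=corr_threshold)
        log.info("redundancy filter: kept %d of %d significant predictors "
                 "(dropped %s)", len(retained), len(significant),
                 sorted(set(significant) - set(retained)))
    return ScreenResult(results, significant, corr, retained, alpha,
                        corr_threshold, skipped)


def redundancy_filter(results: pd.DataFrame, data: pd.DataFrame,
                      threshold: float = 0.7) -> list[str]:
    """Drop correlated predictors, least significant first.

    ``results`` must contain ``predictor`` and ``p`` columns for the
    significant set; ``data`` holds their values (rows = species).  While
    any retained pair has |Pearson r| >= ``threshold`` on
    pairwise-complete observations, the member of any offending pair with
    the largest p-value is dropped (ties broken alphabetically).  The
    procedure is deterministic.
    """
    pvals = results.set_index("predictor")["p"].to_dict()
    retained = [c for c in data.columns if c in pvals]
    while len(retained) >= 2:
        corr = data[retained].corr(method="pearson", min_periods=3).abs()
        np.fill_diagonal(corr.values, 0.0)
        offenders = sorted(
            {c for c in retained if (corr.loc[c] >= threshold).any()},
            key=lambda c: (-pvals[c], c),
        )
        if not offenders:
            break
        retained.remove(offenders[0])
    return retained
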