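"""Confirmation stage: pairwise random-intercept logistic mixed model.

For a pair of sequential items (q, q') every starter contributes two binary
observations, y_i1 = answered(i, q) and y_i2 = answered(i, q'), modeled as

    logit P(y_ik = 1 | u_i) = beta0 + beta1 * I(k = 2) + u_i,
    u_i ~ Normal(0, sigma_u^2),

where the subject-level random intercept u_i absorbs the within-subject
dependence between answering adjacent items (a subject who has already
dropped out answers neither).  The null hypothesis "the response proportion
is equal between the two items" is beta1 = 0.

Estimation is maximum likelihood with adaptive Gauss-Hermite quadrature:
because each subject contributes only the pair (y_i1, y_i2), subjects
collapse onto the four response patterns (0,0), (0,1), (1,0), (1,1), and
the marginal likelihood is evaluated per pattern with the quadrature rule
re-centered at each pattern's posterior mode.  The fitted logit-scale
parameters are transformed to subject-specific (u = 0) response
proportions p1 = expit(beta0), p2 = expit(beta0 + beta1), and the
difference p1 - p2 gets a standard error by the multivariate delta method;
a population-averaged transform (integrating expit over the frailty) is
available as an option.

Quasi-separation — an item answered by everyone, so the raw proportion is
exactly 1 — is handled by plain ML under a logit-scale cap, reproducing
the characteristic unstable estimate with an extremely wide confidence
interval, and flagged via ``separation_warning``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, roots_hermite

from surveyattrition.survey_data import DataError, ResponseMatrix

logger = logging.getLogger(__name__)

_BETA_CAP = 15.0          # |logit| cap signalling (quasi-)separation
_LOG_SIGMA_MIN = math.log(1e-6)
_SIGMA_BOUNDARY = 1e-3    # below this the variance component sits at zero


class NumericError(ArithmeticError):
    """A numerical contract was violated (e.g. non-PSD covariance)."""


@dataclass(frozen=True)
class PairwiseGlmmResult:
    """Fitted pairwise model plus the delta-method proportion difference.

    ``p1``/``p2`` are the subject-specific (random effect 0) response
    proportions; ``diff = p1 - p2``; ``ci95`` is diff ± 1.96·se and is
    deliberately **not** clipped to [-1, 1] (a separated fit legitimately
    reports a CI wider than the proportion scale).
    """

    item_pair: tuple[str, str]
    beta0: float
    beta1: float
    sigma_u: float
    cov_beta: np.ndarray
    p1: float
    p2: float
    diff: float
    se_diff: float
    ci95: tuple[float, float]
    p_value: float
    loglik: float
    converged: bool
    separation_warning: bool
    sigma_boundary: bool
    n_subjects: int
    scale: str = "conditional"

    def row(self) -> dict:
        """Flat dict mirroring a results-table row."""
        return {
            "pair": f"{self.item_pair[0]} to {self.item_pair[1]}",
            "p1": self.p1,
            "p2": self.p2,
            "diff": self.diff,
            "se": self.se_diff,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "p_value": self.p_value,
            "sigma_u": self.sigma_u,
            "converged": self.converged,
            "separation_warning": self.separation_warning,
        }


def _pattern_counts(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Counts of the four (y1, y2) response patterns 00, 01, 10, 11."""
    code = 2 * y1 + y2
    return np.bincount(code.astype(np.int64), minlength=4).astype(float)


# pattern order: (y1, y2) = (0,0), (0,1), (1,0), (1,1)
_PAT_Y = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])


def _pattern_loglik(theta: np.ndarray, counts: np.ndarray, nodes: np.ndarray,
                    weights: np.ndarray) -> float:
    """Marginal log-likelihood via adaptive (mode-centered) quadrature.

    For each response pattern the integrand log f(u) + log phi(u; sigma) is
    maximized by Newton's method (it is strictly concave), and the
    Gauss-Hermite rule is rescaled to the mode and curvature.
    """
    beta0, beta1, log_sigma = theta
    sigma = math.exp(log_sigma)
    eta0 = np.array([beta0, beta0 + beta1])
    total = 0.0
    for pat in range(4):
        if counts[pat] == 0:
            continue
        y = _PAT_Y[pat]
        # Newton for the mode of g(u) = sum_k [y eta - log(1+e^eta)] - u^2/(2 s^2)
        u = 0.0
        for _ in range(50):
            p = expit(eta0 + u)
            g1 = float(np.sum(y - p)) - u / sigma**2
            g2 = -float(np.sum(p * (1.0 - p))) - 1.0 / sigma**2
            step = g1 / g2
            u -= step
            if abs(step) < 1e-12:
                break
        p = expit(eta0 + u)
        tau = 1.0 / math.sqrt(float(np.sum(p * (1.0 - p))) + 1.0 / sigma**2)
        z = u + math.sqrt(2.0) * tau * nodes
        eta = eta0[None, :] + z[:, None]
        # log Bernoulli likelihood of the pattern at each node
        ll = np.sum(y[None, :] * eta - np.logaddexp(0.0, eta), axis=1)
        log_phi = -0.5 * (z / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)
        log_integrand = ll + log_phi + nodes**2 + math.log(math.sqrt(2.0) * tau)
        m = log_integrand.max()
        total += counts[pat] * (m + math.log(float(np.dot(weights, np.exp(log_integrand - m)))))
    return total


def _loglik_logistic(theta2: np.ndarray, counts: np.ndarray) -> float:
    """Log-likelihood with sigma_u = 0 (independent Bernoulli pair)."""
    beta0, beta1 = theta2
    eta = np.array([beta0, beta0 + beta1])
    ll_pat = (_PAT_Y * eta[None, :] - np.logaddexp(0.0, eta)[None, :]).sum(axis=1)
    return float(np.dot(counts, ll_pat))


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def marginal_loglik_grid(beta0: float, beta1: float, sigma: float,
                         y1: np.ndarray, y2: np.ndarray,
                         n_grid: int = 2001, half_width: float = 8.0) -> float:
    """Trapezoidal-grid evaluation of the same marginal log-likelihood.

    Integrates the per-pattern integrand on a dense grid over
    ``u in [-half_width*sigma, half_width*sigma]``.  Slow but free of
    quadrature adaptivity — used as an independent numerical cross-check
    of the Gauss-Hermite evaluation.
    """
    counts = _pattern_counts(np.asarray(y1), np.asarray(y2))
    if sigma <= 0:
        return _loglik_logistic(np.array([beta0, beta1]), counts)
    u = np.linspace(-half_width * sigma, half_width * sigma, n_grid)
    eta = np.array([beta0, beta0 + beta1])[None, :] + u[:, None]
    phi = np.exp(-0.5 * (u / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    total = 0.0
    for pat in range(4):
        if counts[pat] == 0:
            continue
        y = _PAT_Y[pat]
        ll = np.sum(y[None, :] * eta - np.logaddexp(0.0, eta), axis=1)
        total += counts[pat] * math.log(float(np.trapezoid(np.exp(ll) * phi, u)))
    return total


def delta_method_difference(
    beta0: float, beta1: float, cov_beta: np.ndarray
) -> tuple[float, float, tuple[float, float]]:
    """Difference in proportions with delta-method SE and 95% CI.

    g(beta) = expit(beta0) - expit(beta0 + beta1); the gradient is
    [p1(1-p1) - p2(1-p2), -p2(1-p2)] and se = sqrt(grad' Cov grad).
    The CI is g ± 1.96·se, not clipped to the proportion scale.
    """
    cov = np.asarray(cov_beta, dtype=float)
    if cov.shape != (2, 2):
        raise NumericError("cov_beta must be 2x2")
    if not np.all(np.isfinite([beta0, beta1])) or not np.isfinite(cov).all():
        raise NumericError("non-finite parameters or covariance")
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise NumericError("cov_beta is not positive semidefinite")
    p1 = float(expit(beta0))
    p2 = float(expit(beta0 + beta1))
    grad = np.array([p1 * (1 - p1) - p2 * (1 - p2), -p2 * (1 - p2)])
    var = float(grad @ cov @ grad)
    se = math.sqrt(max(var, 0.0))
    diff = p1 - p2
    return diff, se, (diff - 1.96 * se, diff + 1.96 * se)


def _population_averaged(beta0: float, beta1: float, sigma: float,
                         nodes: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Population-averaged proportions: E_u[expit(beta + u)]."""
    z = math.sqrt(2.0) * sigma * nodes
    w = weights / math.sqrt(math.pi)
    return (float(w @ expit(beta0 + z)), float(w @ expit(beta0 + beta1 + z)))


def fit_pairwise_glmm(
    rm: ResponseMatrix,
    q: int | str,
    q_prime: int | str,
    n_quad: int = 25,
    scale: str = "conditional",
    sigma_fixed: float | None = None,
) -> PairwiseGlmmResult:
    """Fit the random-intercept logistic model to one item pair.

    Parameters
    ----------
    rm
        Response matrix; **all** starters contribute both indicators, so
        the fitted proportions are monotone fractions of the full cohort.
    q, q_prime
        Item labels or 1-based positions; ``q`` must precede ``q_prime``.
        Non-sequential pairs are allowed but logged, since the scan
        workflow analyzes sequential pairs.
    n_quad
        Number of adaptive Gauss-Hermite nodes.
    scale
        ``"conditional"`` (default) reports p1, p2 at random effect 0;
        ``"population"`` integrates expit over the fitted frailty.
    sigma_fixed
        Fix the random-intercept SD instead of estimating it; 0 reduces
        the model to ordinary logistic regression on the stacked pair.
    """
    i1, i2 = _item_position(rm, q), _item_position(rm, q_prime)
    if i1 >= i2:
        raise DataError(f"item {q!r} must precede {q_prime!r}")
    if i2 != i1 + 1:
        logger.info("fitting non-sequential pair (%s, %s)", q, q_prime)
    if rm.n_subjects < 2:
        raise DataError("need at least 2 subjects")

    y1 = rm.answered[:, i1 - 1].astype(float)
    y2 = rm.answered[:, i2 - 1].astype(float)
    counts = _pattern_counts(y1, y2)
    n = float(rm.n_subjects)
    m1, m2 = y1.mean(), y2.mean()
    raw_separated = m1 in (0.0, 1.0) or m2 in (0.0, 1.0)

    nodes, weights = roots_hermite(n_quad)

    clip = lambda p: min(max(p, 0.5 / n), 1 - 0.5 / n)
    b0_start = float(np.clip(logit(clip(m1)), -_BETA_CAP, _BETA_CAP))
    b1_start = float(np.clip(logit(clip(m2)) - b0_start, -_BETA_CAP, _BETA_CAP))

    if sigma_fixed is not None and sigma_fixed <= 0:
        # independent-pair likelihood: the MLE is the marginal proportions
        eta1 = float(np.clip(logit(clip(m1)), -_BETA_CAP, _BETA_CAP))
        eta2 = float(np.clip(logit(clip(m2)), -_BETA_CAP, _BETA_CAP))
        beta0, beta1 = eta1, eta2 - eta1
        sigma = 0.0
        loglik = _loglik_logistic(np.array([beta0, beta1]), counts)
        converged = True
        nll2 = lambda t: -_loglik_logistic(t, counts)
        cov_beta = _safe_inverse(_numeric_hessian(nll2, np.array([beta0, beta1])))
        sigma_boundary = True
    else:
        if sigma_fixed is not None:
            ls_fixed = math.log(sigma_fixed)
            nll = lambda t: -_pattern_loglik(
                np.array([t[0], t[1], ls_fixed]), counts, nodes, weights)
            x0 = np.array([b0_start, b1_start])
            bounds = [(-_BETA_CAP, _BETA_CAP)] * 2
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500})
        else:
            nll = lambda t: -_pattern_loglik(t, counts, nodes, weights)
            x0 = np.array([b0_start, b1_start, math.log(0.5)])
            bounds = [(-_BETA_CAP, _BETA_CAP)] * 2 + [(_LOG_SIGMA_MIN, 5.0)]
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500})
            # Thin discordance (few (0,1) or (1,0) subjects) puts the ML on
            # a near-flat sigma ridge where a single cold start is
            # unreliable: profile over a sigma grid with warm-started
            # two-parameter fits, then polish jointly, and keep the best.
            thin = min(counts[1], counts[2]) < 5
            if thin or not res.success:
                bounds2 = [(-_BETA_CAP, _BETA_CAP)] * 2
                warm = np.array([b0_start, b1_start])
                best_grid: tuple[float, np.ndarray] | None = None
                for ls in np.log(np.geomspace(0.1, 40.0, 12)):
                    inner = minimize(
                        lambda t, ls=ls: -_pattern_loglik(
                            np.array([t[0], t[1], ls]), counts, nodes, weights),
                        warm, method="L-BFGS-B", bounds=bounds2,
                        options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 300},
                    )
                    warm = inner.x
                    cand = (inner.fun, np.array([*inner.x, ls]))
                    if best_grid is None or cand[0] < best_grid[0]:
                        best_grid = cand
                polish = minimize(nll, best_grid[1], method="L-BFGS-B",
                                  bounds=bounds,
                                  options={"ftol": 1e-12, "gtol": 1e-10,
                                           "maxiter": 500})
                if polish.fun < res.fun:
                    res = polish
        converged = bool(res.success)
        loglik = -res.fun
        if sigma_fixed is not None:
            beta0, beta1 = res.x
            sigma = float(sigma_fixed)
            H = _numeric_hessian(nll, res.x)
            cov_beta = _safe_inverse(H)
            sigma_boundary = sigma < _SIGMA_BOUNDARY
        else:
            beta0, beta1, log_sigma = res.x
            sigma = math.exp(log_sigma)
            sigma_boundary = sigma < _SIGMA_BOUNDARY
            if sigma_boundary:
                # profile out the boundary variance: 2-parameter information
                nll2 = lambda t: -_pattern_loglik(
                    np.array([t[0], t[1], log_sigma]), counts, nodes, weights)
                cov_beta = _safe_inverse(_numeric_hessian(nll2, res.x[:2]))
            else:
                H = _numeric_hessian(nll, res.x)
                cov_full = _safe_inverse(H)
                cov_beta = cov_full[:2, :2]

    separation = raw_separated or max(abs(beta0), abs(beta0 + beta1)) >= _BETA_CAP - 1e-6

    diff, se, ci = delta_method_difference(beta0, beta1, cov_beta)
    p1 = float(expit(beta0))
    p2 = float(expit(beta0 + beta1))
    if scale == "population" and sigma > 0:
        p1, p2 = _population_averaged(beta0, beta1, sigma, nodes, weights)
        diff = p1 - p2
        # SE on the population scale propagates the same 2x2 covariance
        # through the averaged transform (numerical gradient).
        eps = 1e-6
        g = []
        for k in range(2):
            b = np.array([beta0, beta1]); b[k] += eps
            pa = _population_averaged(b[0], b[1], sigma, nodes, weights)
            g.append(((pa[0] - pa[1]) - diff) / eps)
        g = np.array(g)
        se = math.sqrt(max(float(g @ cov_beta @ g), 0.0))
        ci = (diff - 1.96 * se, diff + 1.96 * se)

    se_b1 = math.sqrt(max(cov_beta[1, 1], 0.0))
    if se_b1 > 0:
        from scipy.stats import norm
        z = beta1 / se_b1
        p_value = float(2 * norm.sf(abs(z)))
    else:
        p_value = float("nan")

    return PairwiseGlmmResult(
        item_pair=(str(rm.item_labels[i1 - 1]), str(rm.item_labels[i2 - 1])),
        beta0=float(beta0), beta1=float(beta1), sigma_u=float(sigma),
        cov_beta=np.asarray(cov_beta), p1=p1, p2=p2, diff=diff, se_diff=se,
        ci95=ci, p_value=p_value, loglik=float(loglik), converged=converged,
        separation_warning=bool(separation), sigma_boundary=bool(sigma_boundary),
        n_subjects=rm.n_subjects, scale=scale,
    )


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    """Invert an observed information matrix, projecting to PSD.

    Near a boundary or separated fit the finite-difference information is
    nearly singular and its inverse can pick up small negative eigenvalues
    from rounding; those are clipped so downstream delta-method variances
    stay valid (they are effectively infinite-variance directions anyway).
    """
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    cov = (cov + cov.T) / 2
    eig, vec = np.linalg.eigh(cov)
    if eig.min() < 0:
        eig = np.clip(eig, 0.0, None)
        cov = vec @ np.diag(eig) @ vec.T
        cov = (cov + cov.T) / 2
    return cov


def _item_position(rm: ResponseMatrix, q: int | str) -> int:
    """Resolve an item label or 1-based position to a 1-based position."""
    if isinstance(q, str):
        try:
            return rm.item_labels.index(q) + 1
        except ValueError:
            raise DataError(f"unknown item label {q!r}") from None
    q = int(q)
    if not 1 <= q <= rm.n_items:
        raise DataError(f"item position {q} out of range 1..{rm.n_items}")
    return q


def sequential_attrition_scan(
    rm: ResponseMatrix,
    alpha: float = 0.05,
    n_quad: int = 25,
    multiplicity: str | None = None,
    scale: str = "conditional",
) -> pd.DataFrame:
    """Fit the pairwise model to every adjacent item pair.

    Returns a DataFrame with one row per sequential pair in analyzed
    order, carrying the fitted proportions, delta-method difference, SE,
    CI, p-value, and a ``significant`` flag at level ``alpha``.  No
    multiplicity adjustment is applied by default; ``multiplicity`` may be
    ``"bonferroni"`` or ``"holm"``.  A pair whose fit fails is reported
    with ``converged = False`` rather than aborting the scan.
    """
    if rm.n_items < 2:
        raise DataError("scan needs at least 2 items")
    if not 0 < alpha < 1:
        raise DataError("alpha must be in (0, 1)")
    results = []
    for pos in range(1, rm.n_items):
        try:
            r = fit_pairwise_glmm(rm, pos, pos + 1, n_quad=n_quad, scale=scale)
            results.append(r.row())
        except (DataError, NumericError) as exc:  # pragma: no cover - defensive
            logger.warning("pair %d->%d failed: %s", pos, pos + 1, exc)
            results.append({
                "pair": f"{rm.item_labels[pos - 1]} to {rm.item_labels[pos]}",
                "p1": np.nan, "p2": np.nan, "diff": np.nan, "se": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                "sigma_u": np.nan, "converged": False,
                "separation_warning": False,
            })
    df = pd.DataFrame(results)
    pvals = df["p_value"].to_numpy(dtype=float)
    if multiplicity is None:
        adj = pvals
    else:
        from statsmodels.stats.multitest import multipletests
        method = {"bonferroni": "bonferroni", "holm": "holm"}.get(multiplicity)
        if method is None:
            raise DataError(f"unknown multiplicity adjustment {multiplicity!r}")
        mask = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        if mask.any():
            adj[mask] = multipletests(pvals[mask], alpha=alpha, method=method)[1]
    df["p_adjusted"] = adj
    df["significant"] = (adj < alpha) & np.isfinite(adj)
    return df
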