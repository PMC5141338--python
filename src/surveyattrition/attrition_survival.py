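"""Whole-survey attrition compared between groups as discrete survival.

Dropout is treated as the event and "survival" as continued participation:
a subject's event time is their dropout point (the first item after the
last answered one) and completers are censored after the final analyzed
item.  Because dropout can only happen at item boundaries, event times are
heavily tied, so the Cox partial likelihood uses Efron's tie correction by
default (Breslow available for cross-checks against other software).

The log-rank test and the Cox model are implemented directly here — the
log-rank from the standard observed-minus-expected hypergeometric sums,
the Cox fit by Newton–Raphson on the partial likelihood with standard
errors from the observed information — so the test suite can compare both
against an independent established implementation.  The proportional-
hazards assumption is checked per covariate by adding a covariate × log(t)
interaction (a time-varying column evaluated at each event time) and Wald-
testing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from surveyattrition.survey_data import (
    ResponseMatrix,
    SubjectCovariates,
    classify_cells,
)
from surveyattrition.attrition_summary import ConfigError

logger = logging.getLogger(__name__)


class RankDeficientError(ValueError):
    """The design matrix has linearly dependent columns."""


@dataclass(frozen=True)
class DropoutSurvivalData:
    """Per-subject discrete dropout time, event flag, and covariates.

    ``time`` lies in [2, n_items]; ``event`` is 1 for dropouts and 0 for
    completers, who are censored at ``n_items``.
    """

    table: pd.DataFrame  # index subject_id; columns time, event, covariates...
    n_items: int

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


@dataclass(frozen=True)
class LogRankResult:
    """k-sample log-rank comparison of dropout-time distributions."""

    statistic: float
    df: int
    p_value: float
    observed: pd.Series
    expected: pd.Series
    km_curves: dict = field(repr=False, default_factory=dict)


@dataclass(frozen=True)
class CoxFit:
    """Cox proportional-hazards fit on the dropout times.

    ``summary`` has one row per design column: coef (log hazard ratio),
    hazard ratio, SE, Wald z and p.  ``ph_check`` maps each covariate to
    the Wald p-value of its log(time) interaction (small p = evidence
    against proportional hazards).
    """

    summary: pd.DataFrame
    loglik: float
    loglik_null: float
    tie_method: str
    converged: bool
    n: int
    n_events: int
    ph_check: dict[str, float] = field(default_factory=dict)
    cov: np.ndarray = field(repr=False, default=None)

    @property
    def coefs(self) -> pd.Series:
        return self.summary["coef"]


def build_survival_data(
    rm: ResponseMatrix, covs: SubjectCovariates | None = None
) -> DropoutSurvivalData:
    """Derive (time, event) per subject from the classified response matrix."""
    grid = classify_cells(rm)
    event = (grid.dropout_point <= rm.n_items).astype(int)
    time = np.minimum(grid.dropout_point, rm.n_items)
    df = pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index(rm.subject_ids, name="subject_id"),
    )
    if covs is not None:
        df = df.join(covs.aligned_to(rm))
    return DropoutSurvivalData(df, rm.n_items)


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit estimate as a step-function coordinate table."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = [{"time": 0.0, "n_at_risk": len(times), "n_events": 0, "survival": 1.0}]
    surv = 1.0
    for t in np.unique(times):
        at_risk = int((times >= t).sum())
        d = int(events[times == t].sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
        out.append({"time": float(t), "n_at_risk": at_risk, "n_events": d,
                    "survival": surv})
    return pd.DataFrame(out)


def logrank_test(sd: DropoutSurvivalData, group: str) -> LogRankResult:
    """Log-rank comparison of dropout patterns between mutually exclusive groups.

    Tied events at an item boundary are pooled per time point, as usual.
    Also returns the per-group Kaplan–Meier curves for plotting.
    """
    if group not in sd.table.columns:
        raise ConfigError(f"unknown group column {group!r}")
    labels = sd.table[group]
    groups = [g for g in labels.unique() if (labels == g).any()]
    if len(groups) < 2:
        raise ConfigError("log-rank needs at least 2 nonempty groups")

    times, events = sd.time, sd.event
    k = len(groups)
    masks = {g: (labels == g).to_numpy() for g in groups}
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k - 1, k - 1))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = float(at_risk.sum())
        d = float(((times == t) & (events == 1)).sum())
        n_g = np.array([float((at_risk & masks[g]).sum()) for g in groups])
        d_g = np.array(
            [float(((times == t) & (events == 1) & masks[g]).sum()) for g in groups]
        )
        O += d_g
        E += d * n_g / n
        if n > 1:
            c = d * (n - d) / (n - 1.0)
            p = n_g / n
            V += c * (np.diag(p[: k - 1]) - np.outer(p[: k - 1], p[: k - 1]))

    diff = (O - E)[: k - 1]
    try:
        stat = float(diff @ np.linalg.solve(V, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(V) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    km = {g: kaplan_meier(times[masks[g]], events[masks[g]]) for g in groups}
    return LogRankResult(
        statistic=stat, df=df, p_value=p,
        observed=pd.Series(O, index=groups, name="observed"),
        expected=pd.Series(E, index=groups, name="expected"),
        km_curves=km,
    )


def _encode_covariates(
    table: pd.DataFrame, covariates: list[str],
    interactions: list[tuple[str, str]] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Design matrix with dummy coding and optional pairwise interactions.

    Returns the matrix, column names, and a map covariate → column indices
    (interaction terms get their own "a:b" entry).
    """
    blocks: dict[str, pd.DataFrame] = {}
    for name in covariates:
        if name not in table.columns:
            raise ConfigError(f"unknown covariate {name!r}")
        col = table[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            blocks[name] = col.to_frame(name).astype(float)
        elif pd.api.types.is_numeric_dtype(col):
            blocks[name] = col.to_frame(name).astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            if dummies.shape[1] == 0:
                raise ConfigError(f"covariate {name!r} is constant")
            blocks[name] = dummies.astype(float)
    pieces = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    for name, block in blocks.items():
        groups[name] = list(range(len(names), len(names) + block.shape[1]))
        names.extend(block.columns)
        pieces.append(block.to_numpy())
    for a, b in interactions or []:
        if a not in blocks or b not in blocks:
            raise ConfigError(f"interaction ({a}, {b}) uses an unlisted covariate")
        cols = []
        cnames = []
        for ca in blocks[a].columns:
            for cb in blocks[b].columns:
                cols.append(blocks[a][ca].to_numpy() * blocks[b][cb].to_numpy())
                cnames.append(f"{ca}:{cb}")
        groups[f"{a}:{b}"] = list(range(len(names), len(names) + len(cnames)))
        names.extend(cnames)
        pieces.append(np.column_stack(cols))
    X = np.column_stack(pieces) if pieces else np.empty((len(table), 0))
    return X, names, groups


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        raise ConfigError("empty design matrix")
    from scipy.linalg import qr

    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.shape[1]:
        _, _, piv = qr(Xc, pivoting=True)
        dependent = [names[j] for j in piv[rank:]]
        raise RankDeficientError(
            f"collinear design columns: {', '.join(map(str, dependent))}"
        )


def _partial_loglik(beta, times, events, X, Xtv, tie_method):
    """Cox partial log-likelihood, gradient, Hessian.

    ``Xtv`` columns enter as time-varying terms x * log(t), evaluated at
    each event time for everyone then at risk; this is what the
    proportional-hazards check uses.  With heavy ties, Efron's correction
    subtracts the tied subjects' risk mass in fractions.
    """
    n, p_fix = X.shape
    p_tv = 0 if Xtv is None else Xtv.shape[1]
    p = p_fix + p_tv
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    event_times = np.unique(times[events == 1])
    for t in event_times:
        at_risk = times >= t
        if Xtv is None:
            Z = X[at_risk]
        else:
            Z = np.column_stack([X[at_risk], Xtv[at_risk] * np.log(t)])
        eta = Z @ beta
        m = float(eta.max())
        w = np.exp(eta - m)  # shifted; log S0_true = log S0_shifted + m
        tied = ((times == t) & (events == 1))[at_risk]
        d = int(tied.sum())
        Zd = Z[tied]
        wd = w[tied]
        S0_R, S0_D = float(w.sum()), float(wd.sum())
        S1_R, S1_D = w @ Z, wd @ Zd
        S2_R = (w[:, None] * Z).T @ Z
        S2_D = (wd[:, None] * Zd).T @ Zd
        ll += float((Zd @ beta).sum()) - d * m
        for l in range(d):
            frac = l / d if tie_method == "efron" else 0.0
            S0 = S0_R - frac * S0_D
            S1 = S1_R - frac * S1_D
            S2 = S2_R - frac * S2_D
            ll -= np.log(S0)
            mu = S1 / S0
            grad -= mu
            hess -= S2 / S0 - np.outer(mu, mu)
        grad += Zd.sum(axis=0)
    return ll, grad, hess


def _newton_cox(times, events, X, Xtv, tie_method, max_iter=100, tol=1e-10):
    p = X.shape[1] + (0 if Xtv is None else Xtv.shape[1])
    beta = np.zeros(p)
    ll, grad, hess = _partial_loglik(beta, times, events, X, Xtv, tie_method)
    ll0 = ll
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # damped Newton: halve until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_ll, new_grad, new_hess = _partial_loglik(
                new_beta, times, events, X, Xtv, tie_method
            )
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        improvement = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if abs(improvement) < tol * (abs(ll) + 1.0) and np.abs(grad).max() < 1e-5:
            converged = True
            break
    cov = np.linalg.pinv(-hess)
    return beta, ll, ll0, cov, converged


def cox_fit(
    sd: DropoutSurvivalData,
    covariates: list[str],
    interactions: list[tuple[str, str]] | None = None,
    tie_method: str = "efron",
    ph_check: bool = True,
) -> CoxFit:
    """Cox proportional-hazards regression of dropout on covariates.

    Categorical covariates are dummy-coded against their first level;
    ``interactions`` are pairs of covariate names whose encoded columns
    are multiplied.  ``ph_check`` adds, one covariate at a time, a
    covariate × log(time) interaction and reports its Wald p-value.
    """
    if tie_method not in ("efron", "breslow"):
        raise ConfigError(f"unknown tie method {tie_method!r}")
    if not covariates:
        raise ConfigError("need at least one covariate")
    times, events = sd.time, sd.event
    n_events = int(events.sum())
    X, names, groups = _encode_covariates(sd.table, covariates, interactions)
    if n_events < X.shape[1] + 1:
        raise ConfigError(
            f"{n_events} events cannot support {X.shape[1]} coefficients"
        )
    _check_rank(X, names)

    beta, ll, ll0, cov, converged = _newton_cox(times, events, X, None, tie_method)
    if not converged:
        logger.warning("Cox Newton-Raphson did not converge")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hazard_ratio": np.exp(beta),
            "se": se,
            "z": z,
            "p_value": 2 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(names, name="term"),
    )

    ph: dict[str, float] = {}
    if ph_check:
        for name in covariates:
            idx = groups[name]
            Xtv = X[:, idx]
            b, ll_tv, _, cov_tv, conv_tv = _newton_cox(
                times, events, X, Xtv, tie_method
            )
            k = len(idx)
            b_int = b[-k:]
            V = cov_tv[-k:, -k:]
            try:
                w = float(b_int @ np.linalg.solve(V, b_int))
            except np.linalg.LinAlgError:
                w = float(b_int @ np.linalg.pinv(V) @ b_int)
            ph[name] = float(stats.chi2.sf(max(w, 0.0), k)) if conv_tv else float("nan")

    return CoxFit(
        summary=summary, loglik=float(ll), loglik_null=float(ll0),
        tie_method=tie_method, converged=converged, n=len(times),
        n_events=n_events, ph_check=ph, cov=cov,
    )


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the screen-then-adjust workflow.

    ``labels`` classifies each screened-in covariate as
    ``"effect modifier"`` (significant exposure interaction) or
    ``"confounding candidate"`` (significant main effect, interaction
    dropped); these are descriptive labels, not causal claims.
    """

    exposure: str
    unadjusted: CoxFit
    screening: pd.DataFrame
    retained: list[str]
    interaction_fit: CoxFit | None
    final: CoxFit
    labels: dict[str, str]
    alpha: float


def screen_then_adjust(
    sd: DropoutSurvivalData,
    exposure: str,
    candidates: list[str],
    alpha: float = 0.05,
    tie_method: str = "efron",
) -> ScreenResult:
    """Bivariate screening, then multivariate adjustment with interactions.

    Each candidate covariate is first tested alone against dropout time;
    those significant at ``alpha`` enter a multivariate model with the
    exposure and exposure × candidate interactions.  Non-significant
    interactions are then dropped, and the final model reports the
    exposure adjusted for the retained main effects.
    """

    def _min_p(fit: CoxFit, name: str) -> float:
        cols = [c for c in fit.summary.index if c == name or c.startswith(f"{name}_")]
        return float(fit.summary.loc[cols, "p_value"].min())

    unadjusted = cox_fit(sd, [exposure], tie_method=tie_method, ph_check=False)
    rows = []
    retained = []
    for cand in candidates:
        f = cox_fit(sd, [cand], tie_method=tie_method, ph_check=False)
        p = _min_p(f, cand)
        rows.append({"covariate": cand, "p_value": p, "retained": p < alpha})
        if p < alpha:
            retained.append(cand)
    screening = pd.DataFrame(rows)

    labels: dict[str, str] = {}
    if retained:
        inter = [(exposure, c) for c in retained]
        fit_int = cox_fit(sd, [exposure] + retained, interactions=inter,
                          tie_method=tie_method, ph_check=False)
        keep_int = []
        for c in retained:
            int_terms = [t for t in fit_int.summary.index if ":" in t and c in t]
            p_int = float(fit_int.summary.loc[int_terms, "p_value"].min())
            if p_int < alpha:
                keep_int.append((exposure, c))
                labels[c] = "effect modifier"
        final = cox_fit(sd, [exposure] + retained,
                        interactions=keep_int or None, tie_method=tie_method,
                        ph_check=False)
        for c in retained:
            if c not in labels and _min_p(final, c) < alpha:
                labels[c] = "confounding candidate"
    else:
        fit_int = None
        final = unadjusted
    return ScreenResult(
        exposure=exposure, unadjusted=unadjusted, screening=screening,
        retained=retained, interaction_fit=fit_int, final=final,
        labels=labels, alpha=alpha,
    )
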