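"""Prognosis stage: Kaplan-Meier, log-rank, and Cox proportional hazards.

The marker of interest is dichotomized at its median (">= median" is the
high group), survival curves are estimated by the product-limit method
with Greenwood variance, groups are compared by the two-sample log-rank
test, and hazards are modelled by Cox regression maximizing the Breslow
partial likelihood with Newton-Raphson.  Multivariate models are built
Table-2 style: a univariate screen at alpha, then stepwise addition and
removal driven by Wald p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SurvivalTable

log = logging.getLogger("mirmeta")

MAX_ITER = 50
SCORE_TOL = 1e-8
LOGLIK_RTOL = 1e-10
SEPARATION_BOUND = 20.0


def median_dichotomize(marker) -> np.ndarray:
    """Split at the median: value >= median -> "high", else "low"."""
    x = np.asarray(marker, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 subjects")
    if np.ptp(x) == 0:
        raise ValueError("all marker values identical: degenerate split")
    med = np.median(x)
    return np.where(x >= med, "high", "low")


@dataclass
class KMCurve:
    event_times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of the product-limit estimate at time t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(table: SurvivalTable) -> KMCurve:
    """Product-limit survival estimate with Greenwood standard errors."""
    t = table.time
    d = table.event
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    ev_times = np.unique(t[d == 1])
    n = t.size
    n_risk = np.array([(t >= u).sum() for u in ev_times], dtype=int)
    n_event = np.array([((t == u) & (d == 1)).sum() for u in ev_times], dtype=int)
    frac = 1.0 - n_event / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gterm = np.where(
            n_risk > n_event,
            n_event / (n_risk * (n_risk - n_event).astype(float)),
            np.inf,
        )
        var = surv**2 * np.cumsum(gterm)
    se = np.sqrt(np.where(surv > 0, var, 0.0))
    return KMCurve(
        event_times=ev_times,
        n_risk=n_risk,
        n_event=n_event,
        survival=surv,
        greenwood_se=se,
    )


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic and its 1-df p."""
    ta, da = group_a.time, group_a.event
    tb, db = group_b.time, group_b.event
    if da.sum() + db.sum() == 0:
        raise ValueError("no events in either group")
    ev_times = np.unique(np.concatenate([ta[da == 1], tb[db == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for u in ev_times:
        n1 = (ta >= u).sum()
        n2 = (tb >= u).sum()
        nt = n1 + n2
        d1 = ((ta == u) & (da == 1)).sum()
        dt = d1 + ((tb == u) & (db == 1)).sum()
        o_minus_e += d1 - dt * n1 / nt
        if nt > 1:
            var += dt * (n1 / nt) * (1 - n1 / nt) * (nt - dt) / (nt - 1)
    if var == 0:
        raise ValueError("log-rank variance is zero: no comparable risk sets")
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)

@dataclass
class CoxFit:
    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    wald_p: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    n_iter: int
    flagged_separation: bool = False

    def summary(self) -> pd.DataFrame:
        """Table-2 style layout: covariate, HR (95% CI), p."""
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
                "wald_p": self.wald_p,
            }
        )


def _breslow_quantities(
    t: np.ndarray, d: np.ndarray, X: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood, score vector and observed information."""
    order = np.argsort(t, kind="stable")
    t, d, X = t[order], d[order], X[order]
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard exp overflow; partial lik is shift-invariant
    w = np.exp(eta)
    c0 = np.cumsum(w[::-1])[::-1]
    c1 = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]
    xxw = np.einsum("ij,ik,i->ijk", X, X, w)
    c2 = np.cumsum(xxw[::-1], axis=0)[::-1]
    # each subject's risk set starts at the first index of its time group
    starts = np.r_[True, t[1:] != t[:-1]]
    gs = np.maximum.accumulate(np.where(starts, np.arange(n), 0))
    ev = d == 1
    gse = gs[ev]
    s0 = c0[gse]
    r = c1[gse] / s0[:, None]
    ll = float(eta[ev].sum() - np.log(s0).sum())
    score = (X[ev] - r).sum(axis=0)
    info = (c2[gse] / s0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", r, r)
    return ll, score, info


def cox_fit(table: SurvivalTable, covariate_names: list[str]) -> CoxFit:
    """Newton-Raphson Cox fit from beta = 0 with Breslow tie handling.

    Convergence at max |score| < 1e-8 or relative log-likelihood change
    < 1e-10; standard errors from the inverse observed information;
    monotone likelihood (|beta| > 20) is flagged, non-convergence in 50
    iterations is an error.
    """
    names = list(covariate_names)
    t = table.time
    d = table.event
    if d.sum() == 0:
        raise ValueError("no events: Cox model undefined")
    if not names:
        ll0, _, _ = _breslow_quantities(t, d, np.zeros((len(table), 1)), np.zeros(1))
        empty = np.array([])
        return CoxFit(
            covariates=[], beta=empty, se=empty, hr=empty,
            ci95_low=empty, ci95_high=empty, wald_p=empty,
            loglik=ll0, loglik_null=ll0,
            n=len(table), n_events=int(d.sum()), n_iter=0,
        )
    X = table.covariate_matrix(names)
    if np.any(np.ptp(X, axis=0) == 0):
        bad = [names[j] for j in np.where(np.ptp(X, axis=0) == 0)[0]]
        raise ValueError(f"degenerate (constant) covariates: {bad}")
    p = X.shape[1]
    beta = np.zeros(p)
    ll_null, _, _ = _breslow_quantities(t, d, X, beta)
    ll_prev = ll_null
    flagged = False
    for it in range(1, MAX_ITER + 1):
        ll, score, info = _breslow_quantities(t, d, X, beta)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix for {names}") from exc
        beta = beta + step
        if np.abs(beta).max() > SEPARATION_BOUND:
            flagged = True
            break
        ll_new, score_new, _ = _breslow_quantities(t, d, X, beta)
        if np.abs(score_new).max() < SCORE_TOL:
            break
        if abs(ll_new - ll_prev) < LOGLIK_RTOL * (abs(ll_prev) + 1e-12):
            break
        ll_prev = ll_new
    else:
        raise ValueError(
            f"Cox fit did not converge in {MAX_ITER} iterations; last beta={beta}"
        )
    ll, score, info = _breslow_quantities(t, d, X, beta)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        covariates=names,
        beta=beta,
        se=se,
        hr=np.exp(beta),
        ci95_low=np.exp(beta - 1.96 * se),
        ci95_high=np.exp(beta + 1.96 * se),
        wald_p=wald_p,
        loglik=ll,
        loglik_null=ll_null,
        n=len(table),
        n_events=int(d.sum()),
        n_iter=it,
        flagged_separation=flagged,
    )


def cox_score_test(table: SurvivalTable, covariate: str) -> float:
    """Efficient-score chi-square at beta = 0 for a single covariate.

    On tie-free data with a binary covariate this equals the two-group
    log-rank chi-square (the classical identity).
    """
    X = table.covariate_matrix([covariate])
    _, score, info = _breslow_quantities(table.time, table.event, X, np.zeros(1))
    return float(score[0] ** 2 / info[0, 0])


def univariate_screen(
    table: SurvivalTable, covariates: list[str], alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate Cox fits; returns covariates with Wald p < alpha
    plus the full per-covariate HR/CI/p table."""
    rows = []
    selected = []
    for cov in covariates:
        fit = cox_fit(table, [cov])
        rows.append(fit.summary().iloc[0])
        if fit.wald_p[0] < alpha and not fit.flagged_separation:
            selected.append(cov)
    full = pd.DataFrame(rows).reset_index(drop=True) if rows else pd.DataFrame(
        columns=["covariate", "beta", "se", "hr", "ci95_low", "ci95_high", "wald_p"]
    )
    return selected, full


def stepwise_cox(
    table: SurvivalTable,
    candidate_covariates: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.05,
) -> CoxFit:
    """Forward-backward stepwise Cox selection driven by Wald p-values.

    Forward: among candidates not in the model, add the one with the
    smallest in-model Wald p < p_enter (ties by covariate name).
    Backward: drop any included covariate whose Wald p exceeds p_remove
    (largest first).  Iterates to a fixed point; candidates that make
    the design singular are skipped.
    """
    candidates = sorted(candidate_covariates)
    included: list[str] = []
    max_rounds = max(2 * len(candidates), 2)
    for _ in range(max_rounds):
        changed = False
        # forward
        best: tuple[float, str] | None = None
        for cov in candidates:
            if cov in included:
                continue
            try:
                fit = cox_fit(table, included + [cov])
            except ValueError:
                continue  # singular / degenerate with this candidate
            if fit.flagged_separation:
                continue
            p = fit.wald_p[fit.covariates.index(cov)]
            if p < p_enter and (best is None or (p, cov) < best):
                best = (p, cov)
        if best is not None:
            included = sorted(included + [best[1]])
            changed = True
        # backward
        while included:
            fit = cox_fit(table, included)
            worst_idx = int(np.argmax(fit.wald_p))
            if fit.wald_p[worst_idx] > p_remove:
                included = [c for c in included if c != fit.covariates[worst_idx]]
                changed = True
            else:
                break
        if not changed:
            break
    else:
        raise ValueError("stepwise selection oscillated without converging")
    log.info("stepwise_cox: selected %s from %d candidates", included, len(candidates))
    return cox_fit(table, included)
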