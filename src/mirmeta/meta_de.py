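"""Integrated differential-expression meta-analysis.

Per-study moderated t-statistics (a pooled-variance t with a fudge
constant s0 added to the denominator, the SAM formulation) are referenced
to a within-study label-permutation null; per-study p-values are combined
across studies by Fisher's statistic S = sum_k -2 ln p_k, whose
significance is again assessed against the combined statistics of the
same permutations.  One-sided p-value sets are combined separately to
classify features as up- or downregulated.  In parallel, per-study
standardized mean differences (Hedges' g) are pooled under fixed- and
random-effects (DerSimonian-Laird) models with Q and I2 heterogeneity
statistics.

Permutation p-values use the rank of a statistic within the pooled set
that contains the observed statistic itself — (1 + #{permuted >= obs}) /
(B + 1) — so they are strictly positive and exactly discrete-uniform
under the null.  When the requested number of permutations reaches the
number of distinct label assignments, full enumeration replaces sampling
and the p-values are exact.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import zlib

import numpy as np
import pandas as pd
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datatypes import MetaDataset, StudyMatrix

log = logging.getLogger("mirmeta")


# ---------------------------------------------------------------------------
# moderated t-statistic and the fudge constant

def moderated_t(case, control, s0: float) -> tuple[float, float]:
    """Moderated two-sample t: (mean1 - mean2) / (se_pooled + s0).

    Returns ``(t_mod, mean_diff)``.  With s0 = 0 this is exactly the
    pooled-variance Student t.  If the denominator is zero (constant data
    and s0 = 0) the statistic is undefined and NaN is returned.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("need >= 2 values per group")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    n1, n2 = case.size, control.size
    mean_diff = case.mean() - control.mean()
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    denom = math.sqrt(sp2) * math.sqrt(1.0 / n1 + 1.0 / n2) + s0
    if denom == 0.0:
        return float("nan"), float(mean_diff)
    return float(mean_diff / denom), float(mean_diff)


def _se_terms(X: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Per-feature pooled standard errors s_pooled * sqrt(1/n1 + 1/n2)."""
    case = X[:, case_mask]
    ctrl = X[:, ~case_mask]
    n1, n2 = case.shape[1], ctrl.shape[1]
    sp2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    return np.sqrt(sp2) * math.sqrt(1.0 / n1 + 1.0 / n2)


def estimate_fudge(study: StudyMatrix, quantile: float = 0.5, case_class=None) -> float:
    """Fudge constant s0: a quantile (default median) of the per-feature
    standard-error terms across all features of the study."""
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    mask = _case_mask(study, case_class)
    se = _se_terms(study.values.to_numpy(dtype=float), mask)
    return float(np.quantile(se, quantile))


def _case_mask(study: StudyMatrix, case_class) -> np.ndarray:
    if case_class is None:
        case_class = sorted(study.sample_classes.unique())[-1]
    return study.class_mask(case_class)


# ---------------------------------------------------------------------------
# permutation machinery

def _t_for_assignments(
    X: np.ndarray, masks: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t for every case-assignment column of ``masks`` (S x B).

    Returns (t, mean_diff), each features x B.  Undefined statistics
    (zero denominator) are mapped to 0, which prices constant features at
    p = 1 downstream.
    """
    M = masks.astype(float)
    n1 = masks[:, 0].sum()
    n = X.shape[1]
    n2 = n - n1
    X2 = X * X
    sum1 = X @ M
    ss1 = X2 @ M
    tot = X.sum(axis=1, keepdims=True)
    sstot = X2.sum(axis=1, keepdims=True)
    sum2 = tot - sum1
    ss2 = sstot - ss1
    sp2 = (ss1 - sum1**2 / n1 + ss2 - sum2**2 / n2) / (n - 2)
    np.clip(sp2, 0.0, None, out=sp2)
    mean_diff = sum1 / n1 - sum2 / n2
    denom = np.sqrt(sp2) * math.sqrt(1.0 / n1 + 1.0 / n2) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, mean_diff / denom, 0.0)
    return t, mean_diff


def _count_tail(pool: np.ndarray, queries: np.ndarray, side: str) -> np.ndarray:
    """#{pool[f] >= q} (side='ge') or #{pool[f] <= q} (side='le') per row.

    Values are rounded to 10 decimals first so that exact permutation
    ties (e.g. complementary label assignments, whose statistics are
    equal in magnitude) are counted as ties despite float round-off.
    """
    pool = np.round(pool, 10)
    queries = np.round(queries, 10)
    F, P = pool.shape
    out = np.empty_like(queries, dtype=float)
    for f in range(F):
        row = np.sort(pool[f])
        if side == "ge":
            out[f] = P - np.searchsorted(row, queries[f], side="left")
        else:
            out[f] = np.searchsorted(row, queries[f], side="right")
    return out


@dataclass
class StudyPermutation:
    """Permutation results for one study (all features)."""

    study_id: str
    s0: float
    n_case: int
    n_control: int
    exact: bool
    n_pool: int  # pool size the p-values are ranks within
    t_obs: np.ndarray
    mean_diff: np.ndarray
    p_two: np.ndarray
    p_up: np.ndarray
    p_down: np.ndarray
    # -2 ln p of each sampled permutation's statistic (features x B),
    # priced against the same pool as the observed statistic
    logp2_two: np.ndarray
    logp2_up: np.ndarray
    logp2_down: np.ndarray


def permute_study(
    study: StudyMatrix,
    B: int,
    s0: float,
    seed: int,
    case_class=None,
) -> StudyPermutation:
    """Permutation-null moderated-t p-values for one study.

    The pool defining the p-value ranks is the full set of distinct
    case-assignments when B reaches that count (exact enumeration,
    announced with a warning), otherwise {observed} U {B sampled
    permutations}.  The same permutation stream is shared by all features
    of the study.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    mask_obs = _case_mask(study, case_class)
    X = study.values.to_numpy(dtype=float)
    n = X.shape[1]
    n1 = int(mask_obs.sum())
    rng = np.random.default_rng([zlib.crc32(study.study_id.encode()), seed])

    n_assign = int(comb(n, n1, exact=True))
    exact = B >= n_assign
    if exact:
        warnings.warn(
            f"study {study.study_id}: B={B} >= {n_assign} distinct label "
            "assignments; using exact enumeration",
            stacklevel=2,
        )
        masks = np.zeros((n, n_assign), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n1)):
            masks[list(idx), b] = True
        pool_t, _ = _t_for_assignments(X, masks, s0)
        samp_cols = rng.integers(0, n_assign, size=B)
        t_samp = pool_t[:, samp_cols]
    else:
        masks = np.zeros((n, B), dtype=bool)
        for b in range(B):
            masks[rng.permutation(n)[:n1], b] = True
        t_samp, _ = _t_for_assignments(X, masks, s0)
        pool_t = None  # built below from obs + sampled

    t_obs, md_obs = _t_for_assignments(X, mask_obs[:, None], s0)
    t_obs, md_obs = t_obs[:, 0], md_obs[:, 0]

    pool = pool_t if exact else np.hstack([t_obs[:, None], t_samp])
    P = pool.shape[1]

    def price(q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p_two = _count_tail(np.abs(pool), np.abs(q), "ge") / P
        p_up = _count_tail(pool, q, "ge") / P
        p_down = _count_tail(pool, q, "le") / P
        return p_two, p_up, p_down

    p_two, p_up, p_down = price(t_obs[:, None])
    s_two, s_up, s_down = price(t_samp)
    return StudyPermutation(
        study_id=study.study_id,
        s0=s0,
        n_case=n1,
        n_control=n - n1,
        exact=exact,
        n_pool=P,
        t_obs=t_obs,
        mean_diff=md_obs,
        p_two=p_two[:, 0],
        p_up=p_up[:, 0],
        p_down=p_down[:, 0],
        logp2_two=-2.0 * np.log(s_two),
        logp2_up=-2.0 * np.log(s_up),
        logp2_down=-2.0 * np.log(s_down),
    )


def permutation_null(
    meta: MetaDataset,
    B: int,
    s0_per_study: list[float] | None = None,
    seed: int = 0,
    case_class=None,
    fudge_quantile: float = 0.5,
) -> list[StudyPermutation]:
    """Permutation p-values for every study of a MetaDataset.

    Labels permute within each study only, preserving study effects; each
    study gets an independent permutation stream derived from ``seed``.
    """
    if s0_per_study is None:
        s0_per_study = [
            estimate_fudge(s, fudge_quantile, case_class) for s in meta.studies
        ]
    if len(s0_per_study) != len(meta.studies):
        raise ValueError("s0_per_study length must match the number of studies")
    return [
        permute_study(s, B, s0, seed, case_class)
        for s, s0 in zip(meta.studies, s0_per_study)
    ]


# ---------------------------------------------------------------------------
# Fisher combination

def fisher_combine(p_values) -> float:
    """Fisher's combined statistic S = sum_k -2 ln p_k over studies."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum())


# ---------------------------------------------------------------------------
# standardized mean differences and meta-analytic pooling

def hedges_g(case, control) -> tuple[float, float]:
    """Hedges' g and its sampling variance.

    g = J * (mean1 - mean2) / s_pooled with the small-sample correction
    J = 1 - 3/(4(n1+n2) - 9); v = (n1+n2)/(n1*n2) + g^2 / (2(n1+n2)).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("need >= 2 values per group")
    n1, n2 = case.size, control.size
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD: standardized effect undefined")
    d = (case.mean() - control.mean()) / math.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = J * d
    v = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return float(g), float(v)


def _hedges_g_study(study: StudyMatrix, case_class=None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-feature (g, v) for one study."""
    mask = _case_mask(study, case_class)
    X = study.values.to_numpy(dtype=float)
    case, ctrl = X[:, mask], X[:, ~mask]
    n1, n2 = case.shape[1], ctrl.shape[1]
    sp2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sp2 > 0, (case.mean(axis=1) - ctrl.mean(axis=1)) / np.sqrt(sp2), np.nan)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = J * d
    v = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return g, v


@dataclass
class PooledEffect:
    """Fixed- and random-effects (DerSimonian-Laird) pooled SMD."""

    mu_fixed: float
    se_fixed: float
    mu_random: float
    se_random: float
    tau2: float
    Q: float
    I2: float  # percent
    ci95_low: float  # random-effects CI
    ci95_high: float


def combine_effects(g_list, v_list) -> PooledEffect:
    """Inverse-variance pooling with a DerSimonian-Laird tau^2."""
    g = np.asarray(g_list, dtype=float)
    v = np.asarray(v_list, dtype=float)
    if g.size == 0 or g.size != v.size:
        raise ValueError("need matching, non-empty g and v lists")
    if (v <= 0).any():
        raise ValueError("all effect variances must be > 0")
    K = g.size
    w = 1.0 / v
    mu_fixed = float((w * g).sum() / w.sum())
    se_fixed = float(1.0 / math.sqrt(w.sum()))
    Q = float((w * (g - mu_fixed) ** 2).sum())
    if K > 1:
        denom = w.sum() - (w * w).sum() / w.sum()
        tau2 = max(0.0, (Q - (K - 1)) / denom)
    else:
        tau2 = 0.0
    ws = 1.0 / (v + tau2)
    mu_random = float((ws * g).sum() / ws.sum())
    se_random = float(1.0 / math.sqrt(ws.sum()))
    I2 = max(0.0, (Q - (K - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return PooledEffect(
        mu_fixed=mu_fixed,
        se_fixed=se_fixed,
        mu_random=mu_random,
        se_random=se_random,
        tau2=tau2,
        Q=Q,
        I2=float(I2),
        ci95_low=mu_random - 1.96 * se_random,
        ci95_high=mu_random + 1.96 * se_random,
    )


# ---------------------------------------------------------------------------
# the integrated test

@dataclass
class MetaDEResult:
    """Per-feature integrated-analysis results.

    ``table`` has one row per feature: the combined Fisher statistic
    S_obs, its permutation p and BH q, one-sided permutation p-values,
    the direction call (up / down / inconsistent / ns), and the pooled
    effect-size fields.  ``study_effects`` holds the per-study Hedges' g
    rows (forest-plot content); ``study_stats`` the per-study moderated-t
    results.
    """

    table: pd.DataFrame
    study_effects: pd.DataFrame
    study_stats: pd.DataFrame
    alpha: float

    def significant(self, use_fdr: bool = True) -> pd.DataFrame:
        col = "q_bh" if use_fdr else "p_perm"
        return self.table[self.table[col] < self.alpha]

    def fisher_list(self, use_fdr: bool = True) -> list[str]:
        """Features significant under the permutation-Fisher test."""
        return sorted(self.significant(use_fdr)["feature_id"])

    def effect_list(self) -> list[str]:
        """Features whose random-effects 95% CI excludes zero."""
        t = self.table
        mask = (t["ci95_low"] > 0) | (t["ci95_high"] < 0)
        return sorted(t.loc[mask, "feature_id"])

    def concordant_list(self, use_fdr: bool = True) -> list[str]:
        """Intersection of the Fisher and effect-size significant lists."""
        return sorted(set(self.fisher_list(use_fdr)) & set(self.effect_list()))


def _combined_p(
    perms: list[StudyPermutation], which: str, B: int
) -> tuple[np.ndarray, np.ndarray]:
    """Observed combined statistic and its permutation p for one tail."""
    obs_attr = {"two": "p_two", "up": "p_up", "down": "p_down"}[which]
    samp_attr = {"two": "logp2_two", "up": "logp2_up", "down": "logp2_down"}[which]
    S_obs = np.zeros_like(perms[0].p_two)
    S_samp = np.zeros_like(perms[0].logp2_two)
    for sp in perms:
        S_obs += -2.0 * np.log(getattr(sp, obs_attr))
        S_samp += getattr(sp, samp_attr)
    count = (S_samp >= S_obs[:, None]).sum(axis=1)
    p = (1.0 + count) / (B + 1.0)
    return S_obs, p


def meta_significance(
    meta: MetaDataset,
    config: PipelineConfig | None = None,
) -> MetaDEResult:
    """Run the full integrated test on a preprocessed MetaDataset.

    Combines two-sided per-study permutation p-values into S_obs, prices
    it against the combined statistics of the same permutations, applies
    Benjamini-Hochberg across features, classifies direction from the
    separately combined one-sided p-value sets (requiring sign agreement
    with the fixed-effect pooled SMD), and attaches fixed-/random-effects
    pooled Hedges' g with heterogeneity statistics.
    """
    config = config or PipelineConfig()
    B = config.n_permutations
    perms = permutation_null(
        meta,
        B,
        seed=config.random_seed,
        case_class=config.case_class,
        fudge_quantile=config.fudge_quantile,
    )
    features = meta.feature_ids.to_numpy()
    S_obs, p_perm = _combined_p(perms, "two", B)
    S_up, p_up = _combined_p(perms, "up", B)
    S_down, p_down = _combined_p(perms, "down", B)
    q_bh = multipletests(p_perm, method="fdr_bh")[1]

    # per-study standardized effects and pooling
    g_mat = np.empty((len(meta.studies), meta.n_features))
    v_mat = np.empty_like(g_mat)
    for k, s in enumerate(meta.studies):
        g_mat[k], v_mat[k] = _hedges_g_study(s, config.case_class)
    pooled = [
        combine_effects(g_mat[:, j], v_mat[:, j]) for j in range(meta.n_features)
    ]

    alpha = config.alpha
    direction = []
    for j in range(meta.n_features):
        up = p_up[j] < alpha
        down = p_down[j] < alpha
        mu = pooled[j].mu_fixed
        if up and not down and mu > 0:
            direction.append("up")
        elif down and not up and mu < 0:
            direction.append("down")
        elif up or down or p_perm[j] < alpha:
            direction.append("inconsistent")
        else:
            direction.append("ns")

    table = pd.DataFrame(
        {
            "feature_id": features,
            "S_obs": S_obs,
            "p_perm": p_perm,
            "q_bh": q_bh,
            "p_perm_up": p_up,
            "p_perm_down": p_down,
            "direction": direction,
            "mu_fixed": [e.mu_fixed for e in pooled],
            "se_fixed": [e.se_fixed for e in pooled],
            "mu_random": [e.mu_random for e in pooled],
            "se_random": [e.se_random for e in pooled],
            "tau2": [e.tau2 for e in pooled],
            "Q": [e.Q for e in pooled],
            "I2": [e.I2 for e in pooled],
            "ci95_low": [e.ci95_low for e in pooled],
            "ci95_high": [e.ci95_high for e in pooled],
        }
    )

    eff_rows = []
    stat_rows = []
    for k, sp in enumerate(perms):
        w = 1.0 / v_mat[k]
        eff_rows.append(
            pd.DataFrame(
                {
                    "study": sp.study_id,
                    "feature_id": features,
                    "g": g_mat[k],
                    "v": v_mat[k],
                    "ci_low": g_mat[k] - 1.96 * np.sqrt(v_mat[k]),
                    "ci_high": g_mat[k] + 1.96 * np.sqrt(v_mat[k]),
                    "weight": w,
                }
            )
        )
        stat_rows.append(
            pd.DataFrame(
                {
                    "study": sp.study_id,
                    "feature_id": features,
                    "t_mod": sp.t_obs,
                    "p_two": sp.p_two,
                    "p_up": sp.p_up,
                    "p_down": sp.p_down,
                    "mean_diff": sp.mean_diff,
                    "n_case": sp.n_case,
                    "n_control": sp.n_control,
                    "s0": sp.s0,
                }
            )
        )
    n_sig = int((p_perm < alpha).sum())
    log.info(
        "meta_significance: %d features, B=%d, %d significant at raw alpha=%g "
        "(%d up, %d down)",
        meta.n_features, B, n_sig,
        alpha, direction.count("up"), direction.count("down"),
    )
    return MetaDEResult(
        table=table,
        study_effects=pd.concat(eff_rows, ignore_index=True),
        study_stats=pd.concat(stat_rows, ignore_index=True),
        alpha=alpha,
    )
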