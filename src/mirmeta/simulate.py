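"""Synthetic multi-study expression data, survival cohorts and target sets.

The generators emulate the statistical structure the downstream analysis
assumes — several microarray cohorts on a shared miRNA namespace with
study-specific baseline shifts and heterogeneous per-feature noise, a
minority of planted directional differentially-expressed features,
exponentially censored survival outcomes whose hazard depends on
covariates, and prediction-source gene sets sharing a planted core.
Ground truth is always returned alongside the data, and every generator
is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneSetDB, MetaDataset, StudyMatrix, SurvivalTable

CASE = "T"
CONTROL = "N"


@dataclass
class SimulationSpec:
    """Design of a synthetic multi-study two-class expression dataset.

    Control values of feature j in study k are Normal(mu_j + b_k, sigma_j^2);
    case values are shifted by delta_jk * sigma_j with
    delta_jk = g_j + Normal(0, tau^2) for planted DE features and 0
    otherwise, so effects are planted in standardized (per-sigma) units
    and the realized Hedges' g is comparable across features.  All values
    are on the log2 scale.

    Defaults are desk-scale stand-ins for a seven-cohort tumour/normal
    compendium: 7 studies of 30+30 samples, 1000 features of which 50 are
    DE at |g| = 1.5 (half up), baseline means Uniform(6, 12) log2 units,
    study shifts Normal(0, 0.5^2), per-feature SD Uniform(0.3, 1.2), and
    between-study effect heterogeneity tau = 0.2.
    """

    n_studies: int = 7
    n_features: int = 1000
    n_case: int = 30
    n_control: int = 30
    n_de: int = 50
    effect_g: float = 1.5
    frac_up: float = 0.5
    study_shift_sd: float = 0.5
    feature_sd_range: tuple[float, float] = (0.3, 1.2)
    baseline_range: tuple[float, float] = (6.0, 12.0)
    tau: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_features < 1:
            raise ValueError("n_studies and n_features must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("n_case and n_control must be >= 2 per study")
        if not 0 <= self.n_de <= self.n_features:
            raise ValueError("n_de must satisfy 0 <= n_de <= n_features")
        if not 0 <= self.frac_up <= 1:
            raise ValueError("frac_up must be in [0, 1]")
        if self.study_shift_sd < 0 or self.tau < 0:
            raise ValueError("study_shift_sd and tau must be >= 0")
        lo, hi = self.feature_sd_range
        if not 0 < lo <= hi:
            raise ValueError("feature_sd_range must satisfy 0 < low <= high")


@dataclass
class SurvivalSimSpec:
    """Design of an exponential survival cohort with independent censoring.

    Event times are Exp(rate = baseline_rate * exp(x . beta)); censoring
    times are independent Exp(censor_rate); the observed time is the
    minimum and the event indicator is 1 iff the event came first.
    Rates are events per month; the defaults give a median follow-up of
    roughly one year with about 60% observed events, in line with a
    240-subject colorectal tumour registry cohort.
    """

    n_subjects: int = 240
    beta: tuple[float, ...] = (0.7,)
    baseline_rate: float = 0.05
    censor_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


def _feature_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"mir-{i:0{width}d}" for i in range(1, n + 1)]


def simulate_meta_dataset(spec: SimulationSpec) -> tuple[MetaDataset, pd.DataFrame]:
    """Generate a MetaDataset plus its ground-truth table.

    Returns the dataset and a DataFrame with one row per planted DE
    feature: feature_id, g_true (signed standardized effect), sign, and
    the realized per-study true effects delta_<study>.
    """
    rng = np.random.default_rng(spec.seed)
    features = _feature_names(spec.n_features)
    mu = rng.uniform(*spec.baseline_range, size=spec.n_features)
    sigma = rng.uniform(*spec.feature_sd_range, size=spec.n_features)
    shifts = rng.normal(0.0, spec.study_shift_sd, size=spec.n_studies)

    de_idx = rng.choice(spec.n_features, size=spec.n_de, replace=False)
    de_idx.sort()
    n_up = int(round(spec.frac_up * spec.n_de))
    signs = np.ones(spec.n_de)
    signs[n_up:] = -1.0
    g_true = np.zeros(spec.n_features)
    g_true[de_idx] = signs * spec.effect_g

    # per-study true standardized effects (zero for non-DE features)
    delta = np.zeros((spec.n_studies, spec.n_features))
    delta[:, de_idx] = g_true[de_idx] + rng.normal(
        0.0, spec.tau, size=(spec.n_studies, spec.n_de)
    )

    studies = []
    study_ids = [f"study{k + 1}" for k in range(spec.n_studies)]
    for k, sid in enumerate(study_ids):
        base = mu + shifts[k]
        ctrl = rng.normal(
            base[:, None], sigma[:, None], size=(spec.n_features, spec.n_control)
        )
        case = rng.normal(
            (base + delta[k] * sigma)[:, None],
            sigma[:, None],
            size=(spec.n_features, spec.n_case),
        )
        values = pd.DataFrame(
            np.hstack([case, ctrl]),
            index=pd.Index(features, name="feature_id"),
            columns=[f"{sid}_s{j + 1:03d}" for j in range(spec.n_case + spec.n_control)],
        )
        classes = pd.Series(
            [CASE] * spec.n_case + [CONTROL] * spec.n_control,
            index=values.columns,
            name="class",
        )
        studies.append(StudyMatrix(study_id=sid, values=values, sample_classes=classes))

    truth = pd.DataFrame(
        {
            "feature_id": [features[i] for i in de_idx],
            "g_true": g_true[de_idx],
            "sign": np.where(g_true[de_idx] > 0, "up", "down"),
        }
    )
    for k, sid in enumerate(study_ids):
        truth[f"delta_{sid}"] = delta[k, de_idx]
    return MetaDataset(studies=studies), truth


def simulate_survival_cohort(
    spec: SurvivalSimSpec, covariates: pd.DataFrame | np.ndarray
) -> SurvivalTable:
    """Draw censored exponential survival times for given covariates."""
    if isinstance(covariates, np.ndarray):
        covariates = pd.DataFrame(
            covariates, columns=[f"x{j + 1}" for j in range(covariates.shape[1])]
        )
    if len(covariates) != spec.n_subjects:
        raise ValueError(
            f"covariate matrix has {len(covariates)} rows, spec says {spec.n_subjects}"
        )
    beta = np.asarray(spec.beta, dtype=float)
    if covariates.shape[1] != beta.size:
        raise ValueError("beta length must match the number of covariate columns")
    rng = np.random.default_rng(spec.seed)
    hazard = spec.baseline_rate * np.exp(covariates.to_numpy(dtype=float) @ beta)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=spec.n_subjects)
    else:
        t_cens = np.full(spec.n_subjects, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    data = covariates.copy()
    data.insert(0, "event", event)
    data.insert(0, "time", time)
    return SurvivalTable(data.reset_index(drop=True))


def simulate_target_db(
    n_sources: int,
    core_set: list[str],
    jitter: float,
    universe_size: int,
    seed: int = 0,
) -> GeneSetDB:
    """Prediction-source gene sets sharing a planted core.

    Each source starts from ``core_set`` and swaps a ``jitter`` fraction
    of its members for random genes outside the core, so at jitter = 0
    every source equals the core exactly and the all-source intersection
    recovers it.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be positive")
    if not 0 <= jitter < 1:
        raise ValueError("jitter must be in [0, 1)")
    core = sorted(set(core_set))
    if len(core) > universe_size:
        raise ValueError("core_set larger than the universe")
    width = max(4, len(str(universe_size)))
    universe = [f"gene{i:0{width}d}" for i in range(1, universe_size + 1)]
    known = set(core) - set(universe)
    if known:
        raise ValueError(f"core genes outside the synthetic universe: {sorted(known)[:5]}")
    rng = np.random.default_rng(seed)
    outside = sorted(set(universe) - set(core))
    n_swap = int(round(jitter * len(core)))
    sets: dict[str, tuple] = {}
    for s in range(n_sources):
        members = set(core)
        if n_swap:
            drop = rng.choice(sorted(members), size=n_swap, replace=False)
            add = rng.choice(outside, size=min(n_swap, len(outside)), replace=False)
            members = (members - set(drop)) | set(add)
        sets[f"source{s + 1}"] = tuple(sorted(members))
    return GeneSetDB(sets=sets, universe=tuple(universe))


def simulate_pathway_db(
    n_sets: int,
    universe: list[str],
    set_size_range: tuple[int, int] = (10, 40),
    enriched_set: tuple[str, list[str]] | None = None,
    seed: int = 0,
) -> GeneSetDB:
    """Random pathway-style gene sets over a universe, optionally with one
    set seeded from a given gene list (to plant a true enrichment)."""
    rng = np.random.default_rng(seed)
    universe = sorted(set(universe))
    lo, hi = set_size_range
    sets: dict[str, tuple] = {}
    if enriched_set is not None:
        name, members = enriched_set
        sets[name] = tuple(sorted(set(members)))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"pathway{i + 1:03d}"] = tuple(
            sorted(rng.choice(universe, size=size, replace=False))
        )
    return GeneSetDB(sets=sets, universe=tuple(universe))
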