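"""Feature-namespace harmonization and mean/SD fraction filtering.

Before meta-analysis each study's probe identifiers are mapped to a
canonical miRNA namespace, studies are restricted to their shared
features, and weakly expressed / weakly varying features are dropped by
rank filters: features are ranked per study by mean (then, on the
survivors, by SD), ranks are averaged across studies and the lowest
fraction removed.  Fractions mean "drop the bottom X%".
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import MetaDataset, StudyMatrix

log = logging.getLogger("mirmeta")


def standardize_ids(
    matrix: StudyMatrix,
    id_map: dict[str, str],
    collapse: str = "mean",
) -> StudyMatrix:
    """Rename features to canonical IDs, dropping unmapped probes.

    When several source probes map to one canonical ID their per-sample
    values are collapsed to a single row: the probe mean by default, or
    the maximum-variance probe with ``collapse="max_var"``.
    """
    if collapse not in ("mean", "max_var"):
        raise ValueError("collapse must be 'mean' or 'max_var'")
    mapped = matrix.values.index.map(id_map.get)
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError(f"study {matrix.study_id}: no features map to canonical IDs")
    values = matrix.values.loc[keep].copy()
    values.index = pd.Index(mapped[keep], name="feature_id")
    if values.index.duplicated().any():
        if collapse == "mean":
            values = values.groupby(level=0, sort=True).mean()
        else:
            var = values.var(axis=1, ddof=1)
            order = np.argsort(-var.to_numpy(), kind="stable")
            values = values.iloc[order]
            values = values[~values.index.duplicated(keep="first")].sort_index()
    else:
        values = values.sort_index()
    log.info(
        "standardize_ids[%s]: %d features in, %d unmapped dropped, %d canonical out",
        matrix.study_id, len(matrix.values), n_dropped, len(values),
    )
    return StudyMatrix(
        study_id=matrix.study_id,
        values=values,
        sample_classes=matrix.sample_classes,
        pair_id=matrix.pair_id,
    )


def intersect_features(studies: list[StudyMatrix]) -> MetaDataset:
    """Restrict all studies to their common features, in sorted order."""
    if len(studies) < 2:
        raise ValueError("need at least 2 studies to intersect")
    shared = set(studies[0].feature_ids)
    for s in studies[1:]:
        shared &= set(s.feature_ids)
    if not shared:
        raise ValueError("no features shared by all studies")
    order = sorted(shared)
    aligned = [
        StudyMatrix(
            study_id=s.study_id,
            values=s.values.loc[order],
            sample_classes=s.sample_classes,
            pair_id=s.pair_id,
        )
        for s in studies
    ]
    log.info("intersect_features: %d shared features across %d studies",
             len(order), len(studies))
    return MetaDataset(studies=aligned)


def _mean_rank(meta: MetaDataset, stat: str) -> pd.Series:
    """Average across studies of per-study ascending ranks of a feature
    statistic (mean or SD); ties get average ranks."""
    ranks = np.zeros(meta.n_features)
    for s in meta.studies:
        if stat == "mean":
            vals = s.values.mean(axis=1).to_numpy()
        else:
            vals = s.values.std(axis=1, ddof=1).to_numpy()
        ranks += rankdata(vals, method="average")
    return pd.Series(ranks / len(meta.studies), index=meta.feature_ids)


def _keep_top(meta: MetaDataset, frac: float, stat: str) -> MetaDataset:
    n = meta.n_features
    n_keep = math.ceil((1.0 - frac) * n)
    if n_keep < 1:
        raise ValueError(f"{stat} filter at fraction {frac} would drop every feature")
    avg_rank = _mean_rank(meta, stat)
    # lowest average rank is dropped first; boundary ties broken by ID
    order = sorted(meta.feature_ids, key=lambda f: (-avg_rank[f], f))
    keep = sorted(order[:n_keep])
    return MetaDataset(
        studies=[
            StudyMatrix(
                study_id=s.study_id,
                values=s.values.loc[keep],
                sample_classes=s.sample_classes,
                pair_id=s.pair_id,
            )
            for s in meta.studies
        ]
    )


def filter_mean_sd(
    meta: MetaDataset, mean_frac: float, sd_frac: float
) -> tuple[MetaDataset, pd.DataFrame]:
    """Two-step rank filter; returns the reduced dataset and a funnel report.

    Step 1 removes the ``mean_frac`` fraction of features with the lowest
    cross-study average mean-rank; step 2 repeats on the survivors with
    per-study SD ranks and ``sd_frac``.  The funnel report lists the
    feature count entering and leaving each step.
    """
    for name, frac in (("mean_frac", mean_frac), ("sd_frac", sd_frac)):
        if not 0 <= frac < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    n0 = meta.n_features
    after_mean = _keep_top(meta, mean_frac, "mean") if mean_frac > 0 else meta
    n1 = after_mean.n_features
    after_sd = _keep_top(after_mean, sd_frac, "sd") if sd_frac > 0 else after_mean
    n2 = after_sd.n_features
    funnel = pd.DataFrame(
        {
            "stage": ["input", "mean_filter", "sd_filter"],
            "n_features": [n0, n1, n2],
        }
    )
    log.info("filter_mean_sd funnel: %d -> %d -> %d", n0, n1, n2)
    return after_sd, funnel
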