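"""Core in-memory containers shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StudyMatrix:
    """One cohort's log2 expression values with two-class sample labels.

    ``values`` is features x samples; ``sample_classes`` maps each sample
    (same order as the columns) to one of exactly two class tokens.
    """

    study_id: str
    values: pd.DataFrame
    sample_classes: pd.Series
    pair_id: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated feature ID: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"study {self.study_id}: non-finite expression values")
        missing = self.values.columns.difference(self.sample_classes.index)
        if len(missing):
            raise ValueError(
                f"study {self.study_id}: samples missing from labels: {list(missing)}"
            )
        self.sample_classes = self.sample_classes.loc[self.values.columns]
        counts = self.sample_classes.value_counts()
        if len(counts) != 2:
            raise ValueError(
                f"study {self.study_id}: expected exactly 2 classes, got {len(counts)}"
            )
        if (counts < 2).any():
            small = counts[counts < 2].index[0]
            raise ValueError(
                f"study {self.study_id}: class {small!r} has fewer than 2 samples"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def classes(self) -> list:
        return sorted(self.sample_classes.unique())

    def class_counts(self) -> dict:
        return self.sample_classes.value_counts().to_dict()

    def class_mask(self, token) -> np.ndarray:
        """Boolean mask over columns for samples of the given class."""
        mask = (self.sample_classes == token).to_numpy()
        if not mask.any():
            raise ValueError(f"study {self.study_id}: no samples of class {token!r}")
        return mask


@dataclass
class MetaDataset:
    """Several studies aligned on a single canonical feature list."""

    studies: list[StudyMatrix]

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("MetaDataset requires at least one study")
        ref = self.studies[0].feature_ids
        for s in self.studies[1:]:
            if not ref.equals(s.feature_ids):
                raise ValueError(
                    f"study {s.study_id}: feature list differs from "
                    f"{self.studies[0].study_id}"
                )

    @property
    def feature_ids(self) -> pd.Index:
        return self.studies[0].feature_ids

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def __len__(self) -> int:
        return len(self.studies)


@dataclass
class SurvivalTable:
    """Per-subject follow-up time (months), event indicator and covariates."""

    data: pd.DataFrame
    time_col: str = "time"
    event_col: str = "event"

    def __post_init__(self) -> None:
        for col in (self.time_col, self.event_col):
            if col not in self.data.columns:
                raise ValueError(f"survival table lacks required column {col!r}")
        t = self.data[self.time_col].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValueError("times must be finite and >= 0")
        ev = self.data[self.event_col].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def time(self) -> np.ndarray:
        return self.data[self.time_col].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data[self.event_col].to_numpy(dtype=int)

    def covariate_matrix(self, names: list[str]) -> np.ndarray:
        sub = self.data[list(names)]
        if sub.isna().any().any():
            raise ValueError("missing covariate values in fitted model")
        return sub.to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "SurvivalTable":
        return SurvivalTable(
            self.data.loc[np.asarray(mask)].reset_index(drop=True),
            self.time_col,
            self.event_col,
        )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetDB:
    """Named gene sets (pathways or prediction sources) over a universe.

    Every set is stored as a sorted, deduplicated tuple and must be a
    subset of the universe; empty sets are rejected.
    """

    sets: dict[str, tuple]
    universe: tuple = field(default=())

    def __post_init__(self) -> None:
        clean: dict[str, tuple] = {}
        for name, members in self.sets.items():
            uniq = tuple(sorted(set(members)))
            if not uniq:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = uniq
        self.sets = clean
        union = sorted(set().union(*map(set, clean.values())))
        if not self.universe:
            self.universe = tuple(union)
        else:
            self.universe = tuple(sorted(set(self.universe)))
            stray = set(union) - set(self.universe)
            if stray:
                raise ValueError(
                    f"set members outside the stated universe: {sorted(stray)[:5]}"
                )

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)
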