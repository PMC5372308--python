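"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Settings shared by all pipeline stages.

    Defaults mirror the integrated-analysis protocol: drop the bottom 10%
    of features by mean and then by SD, 300 label permutations for the
    null distribution, and a 0.05 significance level.

    Attributes
    ----------
    mean_filter_frac, sd_filter_frac:
        Fractions in [0, 1) of features dropped by the mean and SD
        rank filters.
    n_permutations:
        Number of within-study label permutations (B).
    fudge_quantile:
        Quantile of the per-feature standard-error distribution used as
        the fudge constant s0 of the moderated t (median by default,
        the SAM convention).
    alpha:
        Significance level for direction calls and the raw-p cutoff.
    fdr_method:
        Multiple-testing correction; only "bh" (Benjamini-Hochberg) is
        supported.
    min_consensus_sources:
        Number of prediction sources a gene must appear in to enter the
        consensus target list.  0 means "all sources" (strict
        intersection).
    case_class:
        Token of the case (tumour) class in the label files.
    tie_method:
        Tie handling of the Cox partial likelihood; only "breslow".
    """

    mean_filter_frac: float = 0.10
    sd_filter_frac: float = 0.10
    n_permutations: int = 300
    fudge_quantile: float = 0.5
    alpha: float = 0.05
    fdr_method: str = "bh"
    min_consensus_sources: int = 0
    random_seed: int = 0
    case_class: str = "T"
    tie_method: str = "breslow"

    def __post_init__(self) -> None:
        if not 0 <= self.mean_filter_frac < 1:
            raise ValueError("mean_filter_frac must be in [0, 1)")
        if not 0 <= self.sd_filter_frac < 1:
            raise ValueError("sd_filter_frac must be in [0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be a positive integer")
        if not 0 <= self.fudge_quantile <= 1:
            raise ValueError("fudge_quantile must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fdr_method != "bh":
            raise ValueError("fdr_method must be 'bh'")
        if self.min_consensus_sources < 0:
            raise ValueError("min_consensus_sources must be >= 0")
        if self.tie_method != "breslow":
            raise ValueError("tie_method must be 'breslow'")

    def to_yaml(self, path: str | Path) -> None:
        """Serialize to a plain-text YAML file."""
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config written by :meth:`to_yaml`; unknown keys are an error."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
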