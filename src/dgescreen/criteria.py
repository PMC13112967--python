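"""Classification of genes as differentially higher expressed targets (DHETGs).

A gene qualifies under a :class:`CriteriaConfig` when, for the contrast at
hand, all of the following hold (strict inequalities throughout; boundary
genes are excluded):

* adjusted p < ``alpha``;
* ``diff_mean`` > log2(``fold``) — positive direction only;
* optionally ``beta`` > ``min_beta_points`` (percentage points);
* optionally ``ge_c`` < ``max_contrast_ge`` (log2 units).

log2(fold) is evaluated at full floating-point precision, not at a rounded
printed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError
from .stats import adjust_p

_REQUIRED = ("gene", "p_adj", "diff_mean")


@dataclass(frozen=True)
class CriteriaConfig:
    alpha: float = 0.05
    correction: str = "bonferroni"
    fold: float = 3.0
    min_beta_points: float | None = None
    max_contrast_ge: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise SchemaError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.correction not in ("bonferroni", "bh"):
            raise SchemaError(f"unknown correction {self.correction!r}")
        if self.fold <= 1:
            raise SchemaError(f"fold threshold must exceed 1, got {self.fold}")
        if self.min_beta_points is not None and not 0 < self.min_beta_points <= 100:
            raise SchemaError("min_beta_points must be in (0, 100]")
        if self.max_contrast_ge is not None and self.max_contrast_ge < 0:
            raise SchemaError("max_contrast_ge must be >= 0")

    @property
    def log2_fold(self) -> float:
        """The Diff_Mean cutoff implied by the linear fold threshold."""
        return math.log2(self.fold)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "CriteriaConfig":
        allowed = {"alpha", "correction", "fold", "min_beta_points", "max_contrast_ge"}
        unknown = set(data) - allowed
        if unknown:
            raise SchemaError(f"unknown criteria keys: {sorted(unknown)}")
        return cls(**data)


def apply_correction(stats: pd.DataFrame, method: str, m: int) -> pd.DataFrame:
    """Return a copy of a stats table with ``p_adj`` recomputed from ``p_raw``."""
    out = stats.copy()
    out["p_adj"] = adjust_p(stats["p_raw"].to_numpy(), method, m=m)
    return out


def classify_dhetg(stats: pd.DataFrame, cfg: CriteriaConfig) -> set[str]:
    """Genes passing the criteria regime for one contrast's stats table.

    ``stats`` must carry ``p_adj`` computed with ``cfg.correction`` (use
    :func:`apply_correction` when switching regimes).
    """
    required = list(_REQUIRED)
    if cfg.min_beta_points is not None:
        required.append("beta")
    if cfg.max_contrast_ge is not None:
        required.append("ge_c")
    missing = [c for c in required if c not in stats.columns]
    if missing:
        raise SchemaError(f"stats table missing columns {missing}")

    mask = (stats["p_adj"] < cfg.alpha) & (stats["diff_mean"] > cfg.log2_fold)
    if cfg.min_beta_points is not None:
        mask &= stats["beta"] > cfg.min_beta_points
    if cfg.max_contrast_ge is not None:
        mask &= stats["ge_c"] < cfg.max_contrast_ge
    return set(stats.loc[mask, "gene"])


def fold_sensitivity(
    stats: pd.DataFrame, cfg: CriteriaConfig, folds: Iterable[float]
) -> dict[float, set[str]]:
    """Classification at each fold threshold; lower folds give supersets."""
    return {f: classify_dhetg(stats, replace(cfg, fold=f)) for f in folds}
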