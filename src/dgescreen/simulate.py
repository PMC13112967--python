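"""Synthetic expression datasets with planted differential genes.

Generative model, per gene and cell: the cell expresses the gene with
probability pi (zero-inflation); if expressed, CPM = 2**X with
X ~ Normal(mu, sd) on the log2 scale, otherwise CPM = 0.  Baselines for pi
and mu are global; planted effects shift them in a target cell group:

* ``fully_selective`` — non-target cells never express the gene; target
  cells get ``+log2_effect`` on mu and ``+beta_shift`` points on pi;
* ``relative_selective`` — baseline everywhere, target cells shifted as
  above;
* ``ladder`` — listed cell groups take absolute per-group log2 levels
  (graded expression across groups);
* ``beta_only`` — only the expressing probability is shifted.

The log-normal expressed-level choice (rather than count models) is
deliberate: the pipeline consumes CPM and the rank-sum test is invariant
under monotone transforms, so the distributional shape does not affect
test validity.

Seeding: one master seed; each gene draws from its own stream keyed by
(seed, gene index), so adding genes never perturbs existing ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import IDG_CLASSES, TargetGene
from .core import ExpressionDataset
from .criteria import CriteriaConfig
from .contrasts import ComparisonPlan
from .errors import SchemaError

PATTERNS = ("fully_selective", "relative_selective", "ladder", "beta_only")

_HERMGAUSS_N = 64


@dataclass(frozen=True)
class PlantedEffect:
    gene: str
    pattern: str
    target_subclass: str
    target_region: str | None = None
    log2_effect: float = 0.0
    beta_shift: float = 0.0
    ladder_levels: tuple[tuple[str, str | None, float], ...] | None = None
    #: ladder_levels entries are (subclass, region-or-None, log2 level)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise SchemaError(f"unknown planted pattern {self.pattern!r}")
        if self.log2_effect < 0:
            raise SchemaError("log2_effect must be >= 0")
        if self.pattern == "ladder" and not self.ladder_levels:
            raise SchemaError(f"ladder gene {self.gene!r} needs ladder_levels")
        if self.ladder_levels is not None:
            object.__setattr__(
                self, "ladder_levels", tuple(tuple(lv) for lv in self.ladder_levels)
            )


@dataclass
class SimConfig:
    n_regions: int = 2
    subclasses: tuple[tuple[str, str], ...] = (
        ("Pvalb", "GABAergic"),
        ("Sst", "GABAergic"),
        ("L23", "glutamatergic"),
        ("L5", "glutamatergic"),
    )
    cells_per_type_per_region: int = 50
    n_genes: int = 100
    idg_class_proportions: dict[str, float] | None = None
    baseline_log2_mean: float = 5.0
    baseline_sd: float = 1.0
    expressing_prob_baseline: float = 0.6
    planted: tuple[PlantedEffect, ...] = ()
    seed: int = 0
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_regions <= 0 or self.cells_per_type_per_region <= 0 or self.n_genes <= 0:
            raise SchemaError("counts must be positive")
        if not 0 <= self.expressing_prob_baseline <= 1:
            raise SchemaError("expressing_prob_baseline must be in [0, 1]")
        self.subclasses = tuple((str(a), str(b)) for a, b in self.subclasses)
        self.planted = tuple(
            p if isinstance(p, PlantedEffect) else PlantedEffect(**p) for p in self.planted
        )
        if self.region_labels is None:
            self.region_labels = tuple(f"R{i + 1}" for i in range(self.n_regions))
        elif len(self.region_labels) != self.n_regions:
            raise SchemaError("region_labels length must equal n_regions")
        if self.idg_class_proportions is not None:
            unknown = set(self.idg_class_proportions) - set(IDG_CLASSES)
            if unknown:
                raise SchemaError(f"unknown target classes in proportions: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Answer key: the planted effects plus per-contrast expectations."""

    planted: tuple[PlantedEffect, ...]
    expected: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [asdict(p) for p in self.planted],
            "expected": self.expected,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=list) + "\n")


def gene_names(cfg: SimConfig) -> list[str]:
    return [f"g{i:05d}" for i in range(cfg.n_genes)]


def _cell_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for region in cfg.region_labels:
        for subclass, class_label in cfg.subclasses:
            tag = "".join(ch if ch.isalnum() else "-" for ch in subclass)
            for i in range(cfg.cells_per_type_per_region):
                rows.append(
                    (f"{region}_{tag}_{i:04d}", region, subclass, class_label)
                )
    return pd.DataFrame(
        rows, columns=["sample_name", "region_label", "subclass_label", "class_label"]
    )


def _validate_labels(cfg: SimConfig) -> None:
    subclass_labels = {s for s, _ in cfg.subclasses}
    names = set(gene_names(cfg))
    for p in cfg.planted:
        if p.gene not in names:
            raise SchemaError(f"planted gene {p.gene!r} not among generated genes")
        if p.target_subclass not in subclass_labels:
            raise SchemaError(f"planted effect references unknown subclass {p.target_subclass!r}")
        if p.target_region is not None and p.target_region not in cfg.region_labels:
            raise SchemaError(f"planted effect references unknown region {p.target_region!r}")
        for sub, reg, _level in p.ladder_levels or ():
            if sub not in subclass_labels:
                raise SchemaError(f"ladder level references unknown subclass {sub!r}")
            if reg is not None and reg not in cfg.region_labels:
                raise SchemaError(f"ladder level references unknown region {reg!r}")


def _gene_params(
    cfg: SimConfig, meta: pd.DataFrame, effect: PlantedEffect | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (pi, mu) for one gene under the generative model."""
    n = len(meta)
    pi = np.full(n, cfg.expressing_prob_baseline)
    mu = np.full(n, cfg.baseline_log2_mean)
    if effect is None:
        return pi, mu
    in_sub = (meta["subclass_label"] == effect.target_subclass).to_numpy()
    if effect.target_region is not None:
        in_sub &= (meta["region_label"] == effect.target_region).to_numpy()

    if effect.pattern == "fully_selective":
        pi[~in_sub] = 0.0
        pi[in_sub] += effect.beta_shift / 100.0
        mu[in_sub] += effect.log2_effect
    elif effect.pattern == "relative_selective":
        pi[in_sub] += effect.beta_shift / 100.0
        mu[in_sub] += effect.log2_effect
    elif effect.pattern == "beta_only":
        pi[in_sub] += effect.beta_shift / 100.0
    elif effect.pattern == "ladder":
        for sub, reg, level in effect.ladder_levels:
            mask = (meta["subclass_label"] == sub).to_numpy()
            if reg is not None:
                mask &= (meta["region_label"] == reg).to_numpy()
            mu[mask] = level
        pi[in_sub] += effect.beta_shift / 100.0

    if np.any(pi > 1) or np.any(pi < 0):
        warnings.warn(
            f"planted effect on {effect.gene!r} clipped expressing probability to [0, 1]",
            stacklevel=3,
        )
        pi = np.clip(pi, 0.0, 1.0)
    return pi, mu


def simulate_dataset(cfg: SimConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a dataset from the generative model; fully reproducible from the seed."""
    _validate_labels(cfg)
    meta = _cell_table(cfg)
    names = gene_names(cfg)
    by_gene = {p.gene: p for p in cfg.planted}
    if len(by_gene) != len(cfg.planted):
        raise SchemaError("a planted gene appears more than once")

    n_cells = len(meta)
    matrix = np.zeros((n_cells, cfg.n_genes))
    for gidx, name in enumerate(names):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(gidx,)))
        pi, mu = _gene_params(cfg, meta, by_gene.get(name))
        expressed = rng.random(n_cells) < pi
        levels = rng.normal(mu, cfg.baseline_sd)
        matrix[:, gidx] = np.where(expressed, np.exp2(levels), 0.0)

    ds = ExpressionDataset(
        cpm=matrix,
        gene_names=names,
        cell_ids=meta["sample_name"],
        cell_meta=meta.set_index("sample_name", drop=False),
    )
    return ds, GroundTruth(planted=cfg.planted)


def simulate_catalog(cfg: SimConfig) -> list[TargetGene]:
    """Assign every simulated gene a target class (given or uniform proportions)."""
    props = cfg.idg_class_proportions or {c: 1.0 for c in IDG_CLASSES}
    classes = [c for c in IDG_CLASSES if props.get(c, 0.0) > 0]
    weights = np.array([props[c] for c in classes], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2**31,)))
    assigned = rng.choice(len(classes), size=cfg.n_genes, p=weights)
    return [
        TargetGene(name, classes[k], name)
        for name, k in zip(gene_names(cfg), assigned)
    ]


# ---------------------------------------------------------------------------
# Population-level expectations (the analytic side of the answer key)

def expected_log_expression(pi: float, mu: float, sd: float) -> float:
    """E[log2(1 + CPM)] = pi * E[log2(1 + 2**X)], X ~ N(mu, sd), by quadrature."""
    nodes, weights = np.polynomial.hermite.hermgauss(_HERMGAUSS_N)
    x = mu + np.sqrt(2.0) * sd * nodes
    inner = np.log2(1.0 + np.exp2(x))
    return float(pi * np.sum(weights * inner) / np.sqrt(np.pi))


def _expected_log_expression_cells(pi: np.ndarray, mu: np.ndarray, sd: float) -> np.ndarray:
    """Vectorised per-cell expectation; computed once per distinct (pi, mu)."""
    pairs = {}
    for p, m in zip(pi, mu):
        pairs.setdefault((p, m), expected_log_expression(p, m, sd))
    return np.array([pairs[(p, m)] for p, m in zip(pi, mu)])


def population_mean(cfg: SimConfig, meta: pd.DataFrame, gene: str, cells: np.ndarray) -> float:
    """Population mean of log2(1+CPM) for a gene over a boolean cell mask."""
    by_gene = {p.gene: p for p in cfg.planted}
    pi, mu = _gene_params(cfg, meta, by_gene.get(gene))
    return float(np.mean(_expected_log_expression_cells(pi[cells], mu[cells], cfg.baseline_sd)))


def expected_qualification(
    cfg: SimConfig, criteria: CriteriaConfig, plan: ComparisonPlan
) -> dict[str, dict[str, dict]]:
    """Per planted gene and contrast: does the *population* pass the criteria?

    Uses the generative parameters only (never sampled data): population
    diff_mean from the quadrature expectation and population beta from the
    expressing probabilities.  Significance is not predicted — it depends
    on sample size — so qualification covers the fold and beta criteria.
    """
    meta = _cell_table(cfg)
    meta_idx = meta.set_index("sample_name")
    by_gene = {p.gene: p for p in cfg.planted}
    out: dict[str, dict[str, dict]] = {}
    for p in cfg.planted:
        pi, mu = _gene_params(cfg, meta, by_gene.get(p.gene))
        per_contrast = {}
        for contrast in plan.contrasts:
            t_mask = meta["sample_name"].isin(contrast.target_cells).to_numpy()
            c_mask = meta["sample_name"].isin(contrast.contrast_cells).to_numpy()
            ge_t = np.mean(
                _expected_log_expression_cells(pi[t_mask], mu[t_mask], cfg.baseline_sd)
            )
            ge_c = np.mean(
                _expected_log_expression_cells(pi[c_mask], mu[c_mask], cfg.baseline_sd)
            )
            diff = float(ge_t - ge_c)
            beta = float((np.mean(pi[t_mask]) - np.mean(pi[c_mask])) * 100.0)
            passes_fold = diff > criteria.log2_fold
            passes_beta = (
                True if criteria.min_beta_points is None else beta > criteria.min_beta_points
            )
            passes_ge_c = (
                True if criteria.max_contrast_ge is None else ge_c < criteria.max_contrast_ge
            )
            per_contrast[contrast.label] = {
                "diff_mean": diff,
                "beta": beta,
                "ge_c": float(ge_c),
                "expected_pass": bool(passes_fold and passes_beta and passes_ge_c),
            }
        out[p.gene] = per_contrast
    return out
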