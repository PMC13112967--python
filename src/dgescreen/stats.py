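"""Per-gene differential-expression statistics between two cell sets.

Quantities per gene and contrast:

* ``ge_t`` / ``ge_c`` — mean of log2(1 + CPM) over the target / contrast set;
* ``diff_mean`` — ``ge_t - ge_c`` (difference of log-scale set means, so a
  three-fold ratio criterion corresponds to a cutoff of log2(3) ~ 1.585);
* ``p_raw`` — two-sided Wilcoxon rank-sum p-value with midranks for ties,
  exact enumeration at small group sizes, normal approximation with tie
  and continuity correction otherwise;
* ``p_adj`` — Bonferroni or Benjamini–Hochberg adjusted p over a
  configurable multiplicity ``m`` (default: all genes in the dataset);
* ``beta_t`` / ``beta_c`` / ``beta`` — expressing-cell fractions and their
  difference in percentage points.

Degenerate genes (all pooled values identical) get ``p = 1``: no evidence,
and they must never pass selection.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .core import ContrastSpec, ExpressionDataset
from .errors import IntegrityError, SchemaError

#: exact enumeration is used when min(n_t, n_c) <= EXACT_MIN_N and the
#: number of arrangements C(n_t + n_c, min) does not exceed EXACT_MAX_COMB
EXACT_MIN_N = 8
EXACT_MAX_COMB = 1_000_000

GENESTATS_COLUMNS = (
    "gene", "ge_t", "ge_c", "diff_mean", "p_raw", "p_adj", "beta_t", "beta_c", "beta",
)


def log_cpm(x):
    """log2(1 + x); zero CPM maps to exactly 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise IntegrityError("negative CPM value passed to log_cpm")
    return np.log2(1.0 + x)


def mean_expression(ds: ExpressionDataset, gene: str, cells: Sequence[str]) -> float:
    """Arithmetic mean of log2(1 + CPM) of one gene over a cell list."""
    if len(cells) == 0:
        raise IntegrityError("mean_expression: empty cell list")
    return float(np.mean(log_cpm(ds.values(gene, cells))))


def expressing_fraction(
    ds: ExpressionDataset, gene: str, cells: Sequence[str], expr_threshold: float = 0.0
) -> float:
    """Fraction of cells with CPM strictly above ``expr_threshold``."""
    if len(cells) == 0:
        raise IntegrityError("expressing_fraction: empty cell list")
    return float(np.mean(ds.values(gene, cells) > expr_threshold))


def _use_exact(n_t: int, n_c: int) -> bool:
    k = min(n_t, n_c)
    if k > EXACT_MIN_N:
        return False
    return math.comb(n_t + n_c, k) <= EXACT_MAX_COMB


def _exact_combinations(n: int, k: int) -> np.ndarray:
    combs = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), k)),
        dtype=np.intp,
    )
    return combs.reshape(-1, k)


def _exact_p_from_ranks(ranks: np.ndarray, combs: np.ndarray, w_obs: float) -> float:
    """Two-sided permutation p for the rank sum of the enumerated group.

    ``combs`` enumerates every way of assigning k of the n pooled ranks to
    the smaller group; the p-value is the fraction of assignments whose
    rank sum deviates from its null mean at least as much as observed.
    """
    k = combs.shape[1]
    n = ranks.size
    expected = k * (n + 1) / 2.0
    sums = ranks[combs].sum(axis=1)
    dev = abs(w_obs - expected)
    return float(np.mean(np.abs(sums - expected) >= dev - 1e-9))


def rank_sum_p(values_t: Sequence[float], values_c: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value with midranks.

    Exact enumeration for small groups (see module constants), otherwise a
    normal approximation with tie and continuity correction.  All pooled
    values identical yields p = 1.
    """
    t = np.asarray(values_t, dtype=float)
    c = np.asarray(values_c, dtype=float)
    if t.size == 0 or c.size == 0:
        raise IntegrityError("rank_sum_p: empty group")
    pooled = np.concatenate([t, c])
    if np.min(pooled) == np.max(pooled):
        return 1.0
    if _use_exact(t.size, c.size):
        ranks = scipy.stats.rankdata(pooled)
        if t.size <= c.size:
            w_obs = float(ranks[: t.size].sum())
            k = t.size
        else:
            w_obs = float(ranks[t.size:].sum())
            k = c.size
        combs = _exact_combinations(pooled.size, k)
        return _exact_p_from_ranks(ranks, combs, w_obs)
    res = scipy.stats.mannwhitneyu(
        t, c, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def adjust_p(p_values: Sequence[float], method: str, m: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment over multiplicity ``m`` (>= list length).

    ``bonferroni``: min(1, p * m) elementwise.  ``bh``: Benjamini–Hochberg
    step-up, i.e. sort ascending, scale p_(i) by m / i, then enforce
    monotonicity from the largest p downwards and cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise IntegrityError("p-values outside [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise SchemaError(f"multiplicity m={m} smaller than number of p-values {p.size}")
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="mergesort")
        scaled = p[order] * m / np.arange(1, p.size + 1)
        adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
        out = np.empty_like(adj)
        out[order] = adj
        return out
    raise SchemaError(f"unknown correction method {method!r}")


def _rank_sum_p_matrix(mat_t: np.ndarray, mat_c: np.ndarray) -> np.ndarray:
    """Column-wise rank-sum p-values for two (cells x genes) blocks."""
    n_t, n_c = mat_t.shape[0], mat_c.shape[0]
    n_genes = mat_t.shape[1]
    p = np.empty(n_genes)
    degenerate = (
        np.min(np.vstack([mat_t, mat_c]), axis=0)
        == np.max(np.vstack([mat_t, mat_c]), axis=0)
    )
    if _use_exact(n_t, n_c):
        k = min(n_t, n_c)
        combs = _exact_combinations(n_t + n_c, k)
        for j in range(n_genes):
            if degenerate[j]:
                p[j] = 1.0
                continue
            ranks = scipy.stats.rankdata(np.concatenate([mat_t[:, j], mat_c[:, j]]))
            w_obs = float(ranks[:n_t].sum() if n_t <= n_c else ranks[n_t:].sum())
            p[j] = _exact_p_from_ranks(ranks, combs, w_obs)
        return p
    with warnings.catch_warnings():
        # all-tied columns trip a zero-variance warning; patched below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.mannwhitneyu(
            mat_t, mat_c, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=0,
        )
        p = np.asarray(res.pvalue, dtype=float)
    p[degenerate] = 1.0
    if np.any(np.isnan(p)):
        raise IntegrityError("rank-sum p-value NaN for a non-degenerate gene")
    return p


def contrast_stats(
    ds: ExpressionDataset,
    contrast: ContrastSpec,
    genes: Sequence[str],
    correction: str = "bonferroni",
    m: int | None = None,
    expr_threshold: float = 0.0,
) -> pd.DataFrame:
    """Full per-gene statistics table for one contrast.

    ``m`` is the correction multiplicity; by default the number of genes in
    the whole dataset (genome-wide correction), configurable down to the
    requested gene list.  Rows are sorted by gene symbol.
    """
    genes = list(genes)
    if not genes:
        raise SchemaError("contrast_stats: empty gene list")
    contrast.validate_against(ds)
    gene_idx = np.array([ds.gene_index(g) for g in genes])
    rows_t = ds.cell_indices(contrast.target_cells)
    rows_c = ds.cell_indices(contrast.contrast_cells)
    cpm_t = ds.cpm[np.ix_(rows_t, gene_idx)]
    cpm_c = ds.cpm[np.ix_(rows_c, gene_idx)]
    log_t = np.log2(1.0 + cpm_t)
    log_c = np.log2(1.0 + cpm_c)

    ge_t = log_t.mean(axis=0)
    ge_c = log_c.mean(axis=0)
    beta_t = (cpm_t > expr_threshold).mean(axis=0)
    beta_c = (cpm_c > expr_threshold).mean(axis=0)
    # rank-sum is invariant under the monotone log transform; use CPM as-is
    p_raw = _rank_sum_p_matrix(cpm_t, cpm_c)
    if m is None:
        m = ds.n_genes
    p_adj = adjust_p(p_raw, correction, m=m)

    table = pd.DataFrame(
        {
            "gene": genes,
            "ge_t": ge_t,
            "ge_c": ge_c,
            "diff_mean": ge_t - ge_c,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "beta_t": beta_t,
            "beta_c": beta_c,
            "beta": (beta_t - beta_c) * 100.0,
        }
    )
    return table.sort_values("gene", kind="mergesort", ignore_index=True)
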