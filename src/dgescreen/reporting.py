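"""Aggregate reporting over DHETG results.

Two reports:

* class shares — per target class, hit count over catalogue class size as
  a percentage, plus an ``all`` row for the whole catalogue;
* multiplicity — across cell types, how many genes recur in 2, 3, ... of
  the per-cell-type hit sets.  Shared percentages are emitted under both
  plausible denominators (total hit occurrences and distinct-gene union),
  explicitly labelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import IDG_CLASSES, TargetGene
from .errors import IntegrityError, SchemaError


@dataclass
class MultiplicityReport:
    total_hits: int                      # sum of per-cell-type set sizes (occurrences)
    n_distinct_genes: int
    counts_by_multiplicity: dict[int, int]
    shared_gene_count: int               # distinct genes in >= 2 cell types
    shared_pct_of_hits: float            # 100 * shared_gene_count / total_hits
    shared_pct_of_genes: float           # 100 * shared_gene_count / n_distinct_genes

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts_by_multiplicity.items())
        return pd.DataFrame(rows, columns=["multiplicity", "gene_count"])


def class_share(
    hits: set[str],
    catalog: list[TargetGene],
    class_totals: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Hit share per target class, in percent of the class's catalogue size.

    Returns one row per class plus a final ``all`` row (total hits over the
    whole catalogue).  Percentages are carried at full precision; rendering
    to 3 decimals is left to the writer.  Hit genes absent from the
    catalogue are an error.
    """
    by_symbol = {g.symbol: g.idg_class for g in catalog}
    unknown = sorted(h for h in hits if h not in by_symbol)
    if unknown:
        raise IntegrityError(f"hit genes absent from catalogue: {unknown[:10]}")
    if class_totals is None:
        class_totals = {c: 0 for c in IDG_CLASSES}
        for g in catalog:
            class_totals[g.idg_class] += 1
    missing = [c for c in IDG_CLASSES if c not in class_totals]
    if missing:
        raise SchemaError(f"class_totals missing classes: {missing}")

    counts = {c: 0 for c in IDG_CLASSES}
    for h in hits:
        counts[by_symbol[h]] += 1

    rows = []
    for cls in IDG_CLASSES:
        n, total = counts[cls], class_totals[cls]
        if n > total:
            raise IntegrityError(f"class {cls!r}: {n} hits exceed class total {total}")
        rows.append((cls, n, total, 100.0 * n / total if total else 0.0))
    grand_total = sum(class_totals[c] for c in IDG_CLASSES)
    rows.append(
        ("all", len(hits), grand_total, 100.0 * len(hits) / grand_total if grand_total else 0.0)
    )
    return pd.DataFrame(rows, columns=["idg_class", "n_hits", "class_total", "share_pct"])


def overall_share(n_hits: int, total: int) -> float:
    """Plain percentage n_hits / total * 100 (catalogue- or genome-wide)."""
    if n_hits < 0 or total <= 0 or n_hits > total:
        raise IntegrityError(f"invalid share arithmetic: {n_hits}/{total}")
    return 100.0 * n_hits / total


def multiplicity_report(per_celltype_hits: dict[str, set[str]]) -> MultiplicityReport:
    """Cross-cell-type recurrence of hit genes.

    A gene's multiplicity is the number of cell-type sets containing it;
    ``total_hits`` counts (cell type, gene) occurrences, conserving
    sum_k k * counts_by_multiplicity[k].
    """
    if not per_celltype_hits:
        raise SchemaError("multiplicity_report: no cell types")
    union: set[str] = set().union(*per_celltype_hits.values())
    multiplicity = {
        g: sum(1 for s in per_celltype_hits.values() if g in s) for g in union
    }
    counts: dict[int, int] = {}
    for k in multiplicity.values():
        counts[k] = counts.get(k, 0) + 1
    total_hits = sum(len(s) for s in per_celltype_hits.values())
    shared = sum(v for k, v in counts.items() if k >= 2)
    return MultiplicityReport(
        total_hits=total_hits,
        n_distinct_genes=len(union),
        counts_by_multiplicity=counts,
        shared_gene_count=shared,
        shared_pct_of_hits=100.0 * shared / total_hits if total_hits else 0.0,
        shared_pct_of_genes=100.0 * shared / len(union) if union else 0.0,
    )
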