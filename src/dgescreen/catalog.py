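"""Druggable-target catalogue construction.

Pipeline: human target list (symbol, class) -> orthologue mapping to mouse
symbols -> deduplication -> alignment against the expression dataset's
gene index with single-hop alias resolution.  A :class:`CatalogBuildReport`
audits the count at every stage.

The nine target classes are fixed; membership is validated on input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .errors import IntegrityError, SchemaError

log = logging.getLogger(__name__)

IDG_CLASSES = (
    "GPCR",
    "ion channel",
    "transporter",
    "kinase",
    "enzyme",
    "nuclear receptor",
    "transcription factor",
    "transcription factor-epigenetic",
    "epigenetic",
)


@dataclass(frozen=True)
class TargetGene:
    symbol: str
    idg_class: str
    source_symbol: str

    def __post_init__(self) -> None:
        if not self.symbol:
            raise IntegrityError("target gene with empty symbol")
        if self.idg_class not in IDG_CLASSES:
            raise SchemaError(
                f"unknown target class {self.idg_class!r} for {self.symbol!r}"
            )


@dataclass
class CatalogBuildReport:
    n_input: int = 0
    n_after_orthology: int = 0
    n_unmatched: int = 0
    n_alias_resolved: int = 0
    n_dropped: int = 0
    n_final: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in asdict(self).values()):
            raise IntegrityError(f"negative count in catalogue report: {self}")
        if self.n_final != self.n_after_orthology - self.n_dropped:
            raise IntegrityError(
                f"report arithmetic broken: {self.n_final} != "
                f"{self.n_after_orthology} - {self.n_dropped}"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def map_orthologues(
    human_genes: list[tuple[str, str]],
    orthology: dict[str, list[str]],
) -> tuple[list[TargetGene], CatalogBuildReport]:
    """Translate a human target list into a mouse list via an orthology map.

    Rules: humans without an orthologue are dropped; multiple orthologues
    are each added separately; mouse symbols reached from several human
    genes are kept once, with the first-encountered class (conflicting
    classes are logged).
    """
    if not human_genes:
        raise SchemaError("empty human target list")
    symbols = [s for s, _ in human_genes]
    if len(set(symbols)) != len(symbols):
        raise IntegrityError("duplicate symbols in human target list")

    seen: dict[str, TargetGene] = {}
    report = CatalogBuildReport(n_input=len(human_genes))
    for human_symbol, idg_class in human_genes:
        mouse_symbols = orthology.get(human_symbol, [])
        if not mouse_symbols:
            continue
        for mouse_symbol in mouse_symbols:
            if mouse_symbol in seen:
                prev = seen[mouse_symbol]
                if prev.idg_class != idg_class:
                    log.warning(
                        "class conflict for %s: keeping %r (from %s), ignoring %r (from %s)",
                        mouse_symbol, prev.idg_class, prev.source_symbol,
                        idg_class, human_symbol,
                    )
                continue
            seen[mouse_symbol] = TargetGene(mouse_symbol, idg_class, human_symbol)
    genes = list(seen.values())
    report.n_after_orthology = len(genes)
    report.n_final = len(genes)
    report.validate()
    return genes, report


def resolve_aliases(
    genes: list[TargetGene],
    dataset_genes: set[str],
    aliases: dict[str, str],
    report: CatalogBuildReport | None = None,
) -> tuple[list[TargetGene], list[str], CatalogBuildReport]:
    """Align catalogue symbols with the dataset's gene index.

    Symbols already present pass through; absent symbols with an alias
    resolving to a dataset gene are renamed (single hop, no chains);
    anything else is dropped and returned in the ``dropped`` list.  An
    alias pointing outside the dataset counts as unresolved.
    """
    if report is None:
        report = CatalogBuildReport(
            n_input=len(genes), n_after_orthology=len(genes), n_final=len(genes)
        )
    resolved: dict[str, TargetGene] = {}
    dropped: list[str] = []
    n_unmatched = 0
    n_alias = 0
    for gene in genes:
        if gene.symbol in dataset_genes:
            symbol = gene.symbol
        else:
            n_unmatched += 1
            alias = aliases.get(gene.symbol)
            if alias is not None and alias in dataset_genes:
                symbol = alias
                n_alias += 1
            else:
                if alias is not None:
                    log.warning(
                        "alias %s -> %s does not resolve to a dataset gene",
                        gene.symbol, alias,
                    )
                dropped.append(gene.symbol)
                continue
        if symbol not in resolved:
            resolved[symbol] = TargetGene(symbol, gene.idg_class, gene.source_symbol)
    out = list(resolved.values())
    report.n_unmatched = n_unmatched
    report.n_alias_resolved = n_alias
    report.n_dropped = report.n_after_orthology - len(out)
    report.n_final = len(out)
    report.validate()
    return out, dropped, report


def class_totals(genes: list[TargetGene]) -> dict[str, int]:
    """Catalogue size per target class, with zero rows for absent classes."""
    totals = {c: 0 for c in IDG_CLASSES}
    for gene in genes:
        totals[gene.idg_class] += 1
    return totals


# ---------------------------------------------------------------------------
# Tabular I/O (TSV in, TSV + JSON out)

def read_target_list(path: str | Path) -> list[tuple[str, str]]:
    frame = _read_tsv(path, ("symbol", "idg_class"))
    return list(frame.itertuples(index=False, name=None))


def read_orthology(path: str | Path) -> dict[str, list[str]]:
    frame = _read_tsv(path, ("human_symbol", "mouse_symbol"))
    table: dict[str, list[str]] = {}
    for human, mouse in frame.itertuples(index=False, name=None):
        table.setdefault(human, [])
        if mouse and mouse not in table[human]:
            table[human].append(mouse)
    return table


def read_aliases(path: str | Path) -> dict[str, str]:
    frame = _read_tsv(path, ("catalog_symbol", "dataset_symbol"))
    return dict(frame.itertuples(index=False, name=None))


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for line_no, row in enumerate(frame.itertuples(index=False), start=2):
        if not getattr(row, required[0]):
            raise SchemaError(f"{path}: empty {required[0]} at line {line_no}")
    return frame[list(required)]


def write_catalog(genes: list[TargetGene], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(g.symbol, g.idg_class, g.source_symbol) for g in genes],
        columns=["symbol", "idg_class", "source_symbol"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> list[TargetGene]:
    frame = _read_tsv(path, ("symbol", "idg_class"))
    full = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    sources = full["source_symbol"] if "source_symbol" in full.columns else frame["symbol"]
    return [
        TargetGene(sym, cls, src)
        for (sym, cls), src in zip(frame.itertuples(index=False, name=None), sources)
    ]
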