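"""Config-driven screening runs: load -> catalogue -> contrasts -> criteria
-> combination -> reports, with a manifest for reproducibility.

The run configuration (JSON or YAML) has this shape::

    dataset:
      matrix: cpm.csv            # or .mtx with genes/cells index files
      meta: meta.tsv
      format: dense-delimited    # or matrix-market
      genes: genes.txt           # matrix-market only
      cells: cells.txt           # matrix-market only
    catalog: catalog.tsv         # optional; default: every dataset gene
    multiplicity: dataset        # correction multiplicity: dataset | catalog
    plans:
      - name: pv_intra
        mode: intra_conservative
        target: Pvalb
        region: {regions: [ACA]}
        contrast_types: [Sst, L23, L5]
        exclude_subclasses: {}   # optional, per contrast type
      - name: pv_onevsall
        mode: intra_onevsall
        target: Pvalb
        region: {regions: [ACA]}
        target_class: GABAergic
      - name: pv_inter
        mode: inter_regional
        target: Pvalb
        home_region: {regions: [ACA]}
        groups: {Mo: [{regions: [MOp]}, {regions: [MOs]}]}
        group_class_restrictions: {}     # optional, group -> [classes]
    criteria:
      default: {alpha: 0.05, correction: bonferroni, fold: 3}
      fdr: {correction: bh}
    out_dir: out/
    seed: 0
"""

from __future__ import annotations

import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .catalog import read_catalog
from .contrasts import (
    ComparisonPlan,
    combine,
    plan_inter_regional,
    plan_intra_conservative,
    plan_intra_onevsall,
    result_to_jsonable,
)
from .core import CellSelector, ExpressionDataset, load_expression
from .criteria import CriteriaConfig, apply_correction, classify_dhetg
from .errors import SchemaError
from .stats import contrast_stats

log = logging.getLogger(__name__)


def load_run_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        config = yaml.safe_load(text)
    else:
        config = json.loads(text)
    if not isinstance(config, dict):
        raise SchemaError(f"run config {path} is not a mapping")
    _validate_run_config(config, base=Path(path).parent)
    return config


def _validate_run_config(config: dict, base: Path) -> None:
    for key in ("dataset", "plans", "criteria", "out_dir"):
        if key not in config:
            raise SchemaError(f"run config missing key {key!r}")
    dataset = config["dataset"]
    for key in ("matrix", "meta"):
        if key not in dataset:
            raise SchemaError(f"dataset section missing {key!r}")
    for key in ("matrix", "meta", "genes", "cells"):
        if key in dataset:
            dataset[key] = str((base / dataset[key]))
            if not Path(dataset[key]).exists():
                raise SchemaError(f"dataset file does not exist: {dataset[key]}")
    if "catalog" in config and config["catalog"]:
        config["catalog"] = str(base / config["catalog"])
        if not Path(config["catalog"]).exists():
            raise SchemaError(f"catalogue file does not exist: {config['catalog']}")
    config["out_dir"] = str(base / config["out_dir"])
    names = [p.get("name") for p in config["plans"]]
    if len(set(names)) != len(names) or None in names:
        raise SchemaError("every plan needs a unique 'name'")
    if len(set(config["criteria"])) != len(config["criteria"]):
        raise SchemaError("criteria regime names must be unique")
    if config.get("multiplicity", "dataset") not in ("dataset", "catalog"):
        raise SchemaError("multiplicity must be 'dataset' or 'catalog'")


def _selector(data: dict) -> CellSelector:
    return CellSelector(
        regions=frozenset(data["regions"]) if data.get("regions") else None,
        subclasses=frozenset(data["subclasses"]) if data.get("subclasses") else None,
        classes=frozenset(data["classes"]) if data.get("classes") else None,
        exclude_subclasses=(
            frozenset(data["exclude_subclasses"]) if data.get("exclude_subclasses") else None
        ),
    )


def build_plan(ds: ExpressionDataset, spec: dict) -> ComparisonPlan:
    mode = spec.get("mode")
    if mode == "intra_conservative":
        return plan_intra_conservative(
            ds,
            _selector(spec["region"]),
            spec["target"],
            list(spec["contrast_types"]),
            {k: set(v) for k, v in spec.get("exclude_subclasses", {}).items()} or None,
        )
    if mode == "intra_onevsall":
        return plan_intra_onevsall(
            ds, _selector(spec["region"]), spec["target"], spec["target_class"]
        )
    if mode == "inter_regional":
        groups = {
            label: [_selector(s) for s in sels] for label, sels in spec["groups"].items()
        }
        restrictions = {
            k: set(v) for k, v in spec.get("group_class_restrictions", {}).items()
        }
        return plan_inter_regional(
            ds, spec["target"], _selector(spec["home_region"]), groups, restrictions or None
        )
    raise SchemaError(f"unknown plan mode {mode!r}")


def run_screen(config: dict) -> dict:
    """Execute a full screening run; returns the manifest (also written to disk)."""
    t0 = time.time()
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    def stage(name: str) -> None:
        stages.append(name)
        log.info("stage %s (%.1fs elapsed)", name, time.time() - t0)

    stage("load")
    dataset = config["dataset"]
    ds = load_expression(
        dataset["matrix"],
        dataset["meta"],
        dataset.get("format", "dense-delimited"),
        genes_path=dataset.get("genes"),
        cells_path=dataset.get("cells"),
    )

    stage("catalog")
    if config.get("catalog"):
        catalog = read_catalog(config["catalog"])
        symbols = [g.symbol for g in catalog]
        missing = sorted(set(symbols) - set(ds.gene_names))
        if missing:
            raise SchemaError(
                f"catalogue genes absent from dataset (align it first): {missing[:10]}"
            )
    else:
        symbols = list(ds.gene_names)
    multiplicity = ds.n_genes if config.get("multiplicity", "dataset") == "dataset" else len(symbols)

    regimes = {
        name: CriteriaConfig.from_mapping(vals or {})
        for name, vals in config["criteria"].items()
    }

    results: dict[str, dict] = {}
    for plan_spec in config["plans"]:
        name = plan_spec["name"]
        stage(f"plan:{name}")
        plan = build_plan(ds, plan_spec)
        tables = {}
        for contrast in plan.contrasts:
            table = contrast_stats(ds, contrast, symbols, m=multiplicity)
            table.to_csv(out_dir / f"stats_{name}_{contrast.label}.csv", index=False)
            tables[contrast.label] = table

        stage(f"classify:{name}")
        per_regime = {}
        for regime_name, cfg in regimes.items():
            sets = {
                label: classify_dhetg(
                    apply_correction(table, cfg.correction, multiplicity), cfg
                )
                for label, table in tables.items()
            }
            combined = combine(sets)
            payload = result_to_jsonable(combined)
            path = out_dir / f"selection_{name}_{regime_name}.json"
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            per_regime[regime_name] = payload
        results[name] = per_regime

    stage("manifest")
    manifest = {
        "config": {k: v for k, v in config.items()},
        "seed": config.get("seed"),
        "stages": stages,
        "versions": {
            "dgescreen": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "n_cells": ds.n_cells,
        "n_genes": ds.n_genes,
        "n_catalog_genes": len(symbols),
        "multiplicity": multiplicity,
        "wall_clock_s": round(time.time() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
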