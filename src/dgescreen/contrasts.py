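"""Contrast plans and combination of per-contrast gene sets.

Plans
-----
* intra-regional conservative (one-vs-one): the target cell type against
  every other cell type of the same region, one contrast each; the DHETG
  list is the intersection across all of them.
* intra-regional one-vs-all: the target against the pooled GABAergic and
  pooled glutamatergic cells of the region (target cells removed from
  their own pool), two contrasts, intersected.
* inter-regional: the same cell type in the home region against its
  counterpart in each pooled region group (cells pooled before testing).

Combination
-----------
:func:`combine` materialises the full intersection, exclusive Venn cells
and cumulative subset intersections (both emitted, named distinctly), and
majority-rule sets for every quorum k.  Venn decomposition is capped at
6 input sets; beyond that only intersection and majority are computed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

from .core import CellSelector, ContrastSpec, ExpressionDataset, pool_cells, select_cells
from .errors import IntegrityError, SchemaError

VENN_CAP = 6


@dataclass(frozen=True)
class ComparisonPlan:
    target_label: str
    contrasts: tuple[ContrastSpec, ...]
    mode: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "contrasts", tuple(self.contrasts))
        if not self.contrasts:
            raise SchemaError(f"plan {self.target_label!r}: no contrasts")
        labels = [c.label for c in self.contrasts]
        if len(set(labels)) != len(labels):
            raise SchemaError(f"plan {self.target_label!r}: duplicate contrast labels")
        first = self.contrasts[0].target_cells
        for c in self.contrasts[1:]:
            if c.target_cells != first:
                raise IntegrityError(
                    f"plan {self.target_label!r}: contrasts disagree on the target set"
                )


@dataclass
class IntersectionResult:
    per_contrast_sets: dict[str, set[str]]
    full_intersection: set[str]
    venn_cells: dict[frozenset[str], set[str]] | None
    subset_intersections: dict[frozenset[str], set[str]] | None
    majority_sets: dict[int, set[str]]


def _resolve(ds: ExpressionDataset, sel: CellSelector, what: str) -> list[str]:
    cells = select_cells(ds, sel)
    if not cells:
        raise IntegrityError(f"{what}: selector matched no cells ({sel.describe()})")
    return cells


def plan_intra_conservative(
    ds: ExpressionDataset,
    region: CellSelector,
    target_type: str,
    contrast_types: list[str],
    exclude_subclasses: dict[str, set[str]] | None = None,
) -> ComparisonPlan:
    """One contrast per other cell type of the region (one-vs-one).

    ``exclude_subclasses`` maps a contrast type to subclasses dropped from
    *both* sides of that comparison (e.g. a combined subclass shared by
    two very similar types).
    """
    if target_type in contrast_types:
        raise SchemaError(f"target type {target_type!r} listed among contrast types")
    if not contrast_types:
        raise SchemaError("no contrast types given")
    exclude_subclasses = exclude_subclasses or {}

    contrasts = []
    for ct in contrast_types:
        excl = frozenset(exclude_subclasses.get(ct, ()))
        tgt_sel = replace(
            region, subclasses=frozenset({target_type}), exclude_subclasses=excl or None
        )
        con_sel = replace(
            region, subclasses=frozenset({ct}), exclude_subclasses=excl or None
        )
        target = _resolve(ds, tgt_sel, f"target {target_type!r} vs {ct!r}")
        contrast = _resolve(ds, con_sel, f"contrast {ct!r}")
        contrasts.append(ContrastSpec(f"{target_type}_vs_{ct}", tuple(target), tuple(contrast)))
    return ComparisonPlan(target_type, tuple(contrasts), "intra_conservative")


def plan_intra_onevsall(
    ds: ExpressionDataset,
    region: CellSelector,
    target_type: str,
    class_of_target: str,
) -> ComparisonPlan:
    """Target vs pooled GABAergic and vs pooled glutamatergic cells.

    The target type's own cells are removed from the pools (a no-op for
    the class it does not belong to).
    """
    target_sel = replace(region, subclasses=frozenset({target_type}))
    target = _resolve(ds, target_sel, f"target {target_type!r}")
    target_set = set(target)
    observed_classes = set(ds.cell_meta.loc[list(target), "class_label"])
    if observed_classes != {class_of_target}:
        raise IntegrityError(
            f"target {target_type!r} annotated as {sorted(observed_classes)}, "
            f"expected {class_of_target!r}"
        )
    contrasts = []
    for cls in ("GABAergic", "glutamatergic"):
        pool_sel = replace(region, subclasses=None, classes=frozenset({cls}))
        pool = [c for c in select_cells(ds, pool_sel) if c not in target_set]
        if not pool:
            raise IntegrityError(
                f"one-vs-all pool {cls!r} empty after removing target {target_type!r}"
            )
        contrasts.append(ContrastSpec(f"{target_type}_vs_all_{cls}", tuple(target), tuple(pool)))
    return ComparisonPlan(target_type, tuple(contrasts), "intra_onevsall")


def plan_inter_regional(
    ds: ExpressionDataset,
    target_type: str,
    home_region: CellSelector,
    region_groups: dict[str, list[CellSelector]],
    group_class_restrictions: dict[str, set[str]] | None = None,
) -> ComparisonPlan:
    """The target cell type at home vs its counterpart in each region group.

    Group selectors are pooled *before* testing (one contrast per group).
    ``group_class_restrictions`` optionally limits a group to target cell
    classes (e.g. a hippocampal group valid only for GABAergic targets);
    a violating request is a configuration error.
    """
    if not region_groups:
        raise SchemaError("no region groups given")
    target_sel = replace(home_region, subclasses=frozenset({target_type}))
    target = _resolve(ds, target_sel, f"target {target_type!r} in home region")
    restrictions = group_class_restrictions or {}
    target_classes = set(ds.cell_meta.loc[list(target), "class_label"])

    contrasts = []
    for group_label, selectors in region_groups.items():
        allowed = restrictions.get(group_label)
        if allowed is not None and not target_classes <= set(allowed):
            raise SchemaError(
                f"group {group_label!r} is restricted to classes {sorted(allowed)}; "
                f"target {target_type!r} is {sorted(target_classes)}"
            )
        typed = [replace(sel, subclasses=frozenset({target_type})) for sel in selectors]
        pool = pool_cells(ds, typed)
        pool = [c for c in pool if c not in set(target)]
        if not pool:
            raise IntegrityError(
                f"target type {target_type!r} absent from region group {group_label!r}"
            )
        contrasts.append(
            ContrastSpec(f"{target_type}_vs_{group_label}", tuple(target), tuple(pool))
        )
    return ComparisonPlan(target_type, tuple(contrasts), "inter_regional")


def combine(sets: dict[str, set[str]], venn_cap: int = VENN_CAP) -> IntersectionResult:
    """Full intersection, Venn decomposition, and majority-rule sets.

    ``venn_cells`` are exclusive (a gene appears in exactly the named
    sets); ``subset_intersections`` are cumulative (at least the named
    sets).  Both are omitted with a warning above ``venn_cap`` inputs.
    ``majority_sets[k]`` holds genes present in at least k input sets.
    """
    if not sets:
        raise SchemaError("combine: no input sets")
    labels = list(sets)
    n = len(labels)
    universe = set().union(*sets.values())
    membership = {g: frozenset(l for l in labels if g in sets[l]) for g in universe}

    full = set(universe)
    for label in labels:
        full &= sets[label]

    majority = {
        k: {g for g, mem in membership.items() if len(mem) >= k} for k in range(1, n + 1)
    }

    venn_cells = None
    subset_intersections = None
    if n <= venn_cap:
        venn_cells = {
            frozenset(sub): set()
            for r in range(1, n + 1)
            for sub in itertools.combinations(labels, r)
        }
        for g, mem in membership.items():
            venn_cells[mem].add(g)
        subset_intersections = {
            key: {g for g, mem in membership.items() if key <= mem}
            for key in venn_cells
        }
    else:
        warnings.warn(
            f"{n} contrasts exceed the Venn cap ({venn_cap}); "
            "emitting intersection and majority sets only",
            stacklevel=2,
        )
    return IntersectionResult(
        per_contrast_sets={l: set(s) for l, s in sets.items()},
        full_intersection=full,
        venn_cells=venn_cells,
        subset_intersections=subset_intersections,
        majority_sets=majority,
    )


def combine_intra_inter(
    intra: set[str], inter: IntersectionResult
) -> dict[frozenset[str], set[str]]:
    """Intersect the intra-regional DHETG set with every inter-regional Venn cell."""
    if inter.venn_cells is None:
        raise SchemaError("inter-regional result has no Venn decomposition")
    return {labels: cell & intra for labels, cell in inter.venn_cells.items()}


def result_to_jsonable(result: IntersectionResult) -> dict:
    """Serialise an IntersectionResult with sorted gene lists and string keys."""
    def key(labels: frozenset[str]) -> str:
        return " & ".join(sorted(labels))

    out = {
        "per_contrast": {l: sorted(s) for l, s in result.per_contrast_sets.items()},
        "full_intersection": sorted(result.full_intersection),
        "majority": {str(k): sorted(s) for k, s in result.majority_sets.items()},
    }
    if result.venn_cells is not None:
        out["venn_exclusive"] = {key(k): sorted(v) for k, v in result.venn_cells.items()}
        out["venn_cumulative"] = {
            key(k): sorted(v) for k, v in result.subset_intersections.items()
        }
    return out
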