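import numpy as np
import pandas as pd
import pytest

from dgescreen.core import ExpressionDataset

COMBINED_SUBCLASS = "CA1sp/SUB-sp Kcnip1"


def make_dataset(records, gene_names, cpm):
    """Build an ExpressionDataset from (cell, region, subclass, class) rows."""
    meta = pd.DataFrame(
        records, columns=["sample_name", "region_label", "subclass_label", "class_label"]
    )
    return ExpressionDataset(
        cpm=np.asarray(cpm, dtype=float),
        gene_names=gene_names,
        cell_ids=meta["sample_name"],
        cell_meta=meta.set_index("sample_name", drop=False),
    )


@pytest.fixture
def toy_ds():
    """8 cells x 3 genes spanning 4 regions, 2 classes, a combined subclass."""
    records = [
        ("c1", "ACA", "Pvalb", "GABAergic"),
        ("c2", "ACA", "Sst", "GABAergic"),
        ("c3", "ACA", "L23", "glutamatergic"),
        ("c4", "ACA", "L5", "glutamatergic"),
        ("c5", "MOp", "Pvalb", "GABAergic"),
        ("c6", "MOs", "Pvalb", "GABAergic"),
        ("c7", "HIP", "CA1sp", "glutamatergic"),
        ("c8", "HIP", COMBINED_SUBCLASS, "glutamatergic"),
    ]
    cpm = [
        [0.0, 10.0, 3.0],
        [1.0, 0.0, 7.0],
        [3.0, 2.5, 0.0],
        [7.0, 0.0, 1.0],
        [0.5, 4.0, 0.0],
        [2.0, 0.0, 9.0],
        [0.0, 1.0, 2.0],
        [4.0, 0.0, 0.0],
    ]
    return make_dataset(records, ["gA", "gB", "gC"], cpm)


@pytest.fixture
def tiny_ds():
    """3 cells x 2 genes; the minimal loader round-trip fixture."""
    records = [
        ("c1", "ACA", "Pvalb", "GABAergic"),
        ("c2", "ACA", "Sst", "GABAergic"),
        ("c3", "ACA", "L23", "glutamatergic"),
    ]
    cpm = [[0.0, 1.5], [2.25, 0.0], [3.0, 4.125]]
    return make_dataset(records, ["gA", "gB"], cpm)
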