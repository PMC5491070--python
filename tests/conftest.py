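"""Shared fixtures: small synthetic surveys and hand-built toy objects."""

import numpy as np
import pandas as pd
import pytest

from orofaecal.core_tables import (CountTable, PhyloTree, SampleMetadata,
                                   TaxonomyTable)
from orofaecal.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Survey-preset paired design scaled to 120 OTUs (fast)."""
    return generate_dataset(SyntheticSpec(n_otus=120, seed=11))


@pytest.fixture(scope="session")
def tiny_table():
    counts = np.array([
        [10, 0, 3, 1],
        [2, 5, 0, 4],
        [0, 1, 8, 2],
    ])
    return CountTable(("s1", "s2", "s3"), ("A", "B", "C", "D"), counts)


@pytest.fixture(scope="session")
def tiny_meta():
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "individual_id": ["i1", "i1", "i2"],
        "region": ["oral", "faecal", "oral"],
        "sex": ["M", "M", "F"],
        "body_mass": [18.0, 18.0, 17.2],
        "tarsus": [19.5, 19.5, 20.1],
    }))


@pytest.fixture(scope="session")
def quartet_tree():
    """((A:1,B:1):1,(C:1,D:1):1); the standard worked UniFrac example."""
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def paired_design():
    """8 paired individuals + 12 oral-only + 9 faecal-only (study layout)."""
    ind = [f"b{k}" for k in range(8) for _ in range(2)] \
        + [f"s{k}" for k in range(21)]
    reg = ["oral", "faecal"] * 8 + ["oral"] * 12 + ["faecal"] * 9
    sids = [f"smp{k}" for k in range(len(ind))]
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": sids, "individual_id": ind, "region": reg}))
    return meta


def make_taxonomy(otu_ids, flagged=()):
    """Bacterial taxonomy with selected OTUs flagged as contaminants.

    ``flagged`` maps OTU id -> one of {"chloroplast", "streptophyta",
    "nophylum"}.
    """
    flagged = dict(flagged)
    rows = {}
    for o in otu_ids:
        kind = flagged.get(o)
        if kind == "chloroplast":
            rows[o] = ("Bacteria", "Cyanobacteria", "Chloroplast", "", "", "")
        elif kind == "streptophyta":
            rows[o] = ("Bacteria", "Cyanobacteria", "Chloroplastida",
                       "Streptophyta", "", "")
        elif kind == "nophylum":
            rows[o] = ("Bacteria", "", "", "", "", "")
        else:
            rows[o] = ("Bacteria", "Firmicutes", "Bacilli",
                       "Lactobacillales", "Lactobacillaceae", "Lactobacillus")
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["kingdom", "phylum", "class", "order", "family", "genus"])
    df.index.name = "otu_id"
    return TaxonomyTable(df)
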