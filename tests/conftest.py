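import numpy as np
import pandas as pd
import pytest

from palynostats import (CountTable, TaxonCatalogue, TiePointTable,
                         default_catalogue)
from palynostats.taxonomy import _row


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture
def toy_catalogue():
    """Minimal catalogue with one taxon per functional group."""
    return TaxonCatalogue(pd.DataFrame.from_dict({
        "Pinus": _row("tree_shrub", arboreal=True),
        "Artemisia": _row("herb"),
        "Poaceae": _row("herb", poaceae=True, edible=True, organ="seed"),
        "Cerealia-type": _row("herb", poaceae=True, cereal=True,
                              edible=True, organ="seed"),
        "Filicophyta": _row("fern"),
        "Sporormiella": _row("npp", copro=True),
    }, orient="index"))


@pytest.fixture
def toy_counts(toy_catalogue):
    counts = pd.DataFrame(
        {"Pinus": [50, 0], "Artemisia": [130, 0], "Poaceae": [15, 0],
         "Cerealia-type": [5, 0], "Filicophyta": [10, 2],
         "Sporormiella": [20, 40]},
        index=["s1", "s2"],
    )
    meta = pd.DataFrame({"depth_m": [1.0, 2.0], "weight_g": [10.0, 11.24],
                         "counted_fraction": [0.5, 1.0]},
                        index=["s1", "s2"])
    return CountTable(counts=counts, meta=meta)


@pytest.fixture
def toy_ties():
    return TiePointTable(pd.DataFrame({
        "depth_m": [0.0, 100.0], "age_ma": [0.0, 0.5],
        "label": ["top", "base"],
    }))


def random_count_table(rng, n_samples=5, taxa=None):
    """Random valid CountTable over the default-catalogue taxa."""
    cat = default_catalogue()
    if taxa is None:
        taxa = list(cat.taxa[:12])
    counts = pd.DataFrame(
        rng.integers(0, 200, size=(n_samples, len(taxa))),
        index=[f"s{i}" for i in range(n_samples)], columns=taxa,
    )
    meta = pd.DataFrame({
        "depth_m": np.sort(rng.uniform(0, 500, n_samples)),
        "weight_g": rng.uniform(4, 16, n_samples),
        "counted_fraction": rng.uniform(0.2, 1.0, n_samples),
    }, index=counts.index)
    return CountTable(counts=counts, meta=meta)
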