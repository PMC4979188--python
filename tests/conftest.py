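import numpy as np
import pandas as pd
import pytest

from dgetag.simulate import ReferenceCatalog, generate_reference, plan_truth
from dgetag.tags import GeneCountTable


@pytest.fixture(scope="session")
def small_catalog() -> ReferenceCatalog:
    return generate_reference(n_genes=60, length_range=(120, 400), seed=11)


@pytest.fixture(scope="session")
def small_truth(small_catalog):
    return plan_truth(
        small_catalog,
        class_sizes={"microcycle_up": 5, "sucrose_specific": 3},
        fold_change=8.0,
        depths=40_000,
        seed=11,
    )


def make_table(counts: dict[str, dict[str, int]], sizes: dict[str, int]) -> GeneCountTable:
    """Build a GeneCountTable from {condition: {gene: count}}."""
    df = pd.DataFrame(counts).fillna(0).astype(int)
    df.index.name = "gene_id"
    return GeneCountTable(counts=df, library_sizes=pd.Series(sizes))


@pytest.fixture
def toy_table():
    return make_table(
        {
            "A": {"g1": 200, "g2": 50, "g3": 3},
            "B": {"g1": 10, "g2": 50, "g3": 5},
        },
        {"A": 100_000, "B": 100_000},
    )
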