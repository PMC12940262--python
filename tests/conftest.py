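import numpy as np
import pandas as pd
import pytest

from canine_lag.phylogeny import build_tree


def lineage_frame(rows):
    return pd.DataFrame(rows, columns=["child", "parent", "divergence_time_years"])


@pytest.fixture
def two_tip_split_tree():
    """Two tips at depth 10 whose split is 4 units below the root:
    V = [[10, 4], [4, 10]]."""
    rows = [("root", "", 10.0), ("mrca", "root", 6.0),
            ("A", "mrca", 0.0), ("B", "mrca", 0.0)]
    return build_tree(lineage_frame(rows), [], modern_clade="none")


@pytest.fixture
def three_tip_tree():
    """((A,B) split 6 before present, C basal) with root at 10."""
    rows = [("root", "", 10.0), ("mrca", "root", 6.0),
            ("A", "mrca", 0.0), ("B", "mrca", 0.0), ("C", "root", 0.0)]
    return build_tree(lineage_frame(rows), [], modern_clade="none")


@pytest.fixture
def small_mixed_tree():
    """2 ancient tips on deep lineages + 4 modern tips on a 200-yr star."""
    rows = [
        ("root", "", 8000.0),
        ("ancient_1", "root", 0.0),
        ("inner", "root", 4000.0),
        ("ancient_2", "inner", 0.0),
        ("modern", "inner", 200.0),
    ]
    return build_tree(lineage_frame(rows), [f"modern_{i}" for i in range(1, 5)])


@pytest.fixture
def small_traits():
    rng = np.random.default_rng(7)
    breeds = ["ancient_1", "ancient_2"] + [f"modern_{i}" for i in range(1, 5)]
    labels = ["ancient", "ancient"] + ["modern"] * 4
    weight = np.array([12.0, 30.0, 8.0, 20.0, 40.0, 60.0])
    return pd.DataFrame(
        {
            "breed": breeds,
            "label": labels,
            "weight_kg": weight,
            "lifespan_yr": 13.5 - 0.09 * weight + rng.normal(0, 0.3, 6)
            + np.array([1.3, 1.3, 0, 0, 0, 0]),
            "litter_size": 4.0 + 0.05 * weight + rng.normal(0, 0.2, 6),
            "cancer_deaths": [20, 30, 15, 40, 60, 80],
            "diagnosed_deaths": [100, 120, 100, 150, 180, 200],
        }
    )
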