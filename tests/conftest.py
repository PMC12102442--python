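import numpy as np
import pandas as pd
import pytest

from gyremet import synthetic
from gyremet.io import RANKS


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic survey at the default study conditions, shared read-only."""
    return synthetic.gen_dataset(synthetic.GeneratorConfig(seed=1))


@pytest.fixture
def tiny_table():
    counts = [
        [5, 0, 1, 10],
        [3, 2, 0, 8],
        [0, 4, 4, 6],
        [1, 1, 1, 1],
        [2, 3, 4, 5],
    ]
    return pd.DataFrame(
        counts,
        index=pd.Index([f"S{i}" for i in range(1, 6)], name="sample_id"),
        columns=pd.Index([f"ASV{j}" for j in range(1, 5)], name="asv_id"),
    )


def make_taxonomy(lineages: dict) -> pd.DataFrame:
    """Build a taxonomy frame from {asv_id: (domain,...,genus)} tuples."""
    rows = {asv: dict(zip(RANKS, lineage)) for asv, lineage in lineages.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(RANKS))
    df.index.name = "asv_id"
    return df.fillna("")


@pytest.fixture
def tiny_tax():
    return make_taxonomy(
        {
            "ASV1": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "SAR11_clade", "", ""),
            "ASV2": ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast", "", ""),
            "ASV3": ("Bacteria", "Bacteroidota", "Bacteroidia", "Flavobacteriales", "", ""),
            "ASV4": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "SAR86_clade", "", ""),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
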