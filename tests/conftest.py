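import numpy as np
import pandas as pd
import pytest

from perturbmeta.synthdata import SimulationConfig, generate_collection


@pytest.fixture(scope="session")
def null_config():
    """No planted effects: every gene is null in every study."""
    return SimulationConfig(
        n_studies=4,
        genes_per_study=2000,
        samples_per_group=10,
        deg_fraction=0.0,
        effect_size_log2fc=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def null_collection(null_config):
    return generate_collection(null_config)


@pytest.fixture
def toy_matrix():
    """4 genes x 6 samples with per-gene medians 1, 2, 3, 4."""
    data = np.array(
        [
            [1.0] * 6,
            [2.0] * 6,
            [3.0] * 6,
            [4.0] * 6,
        ]
    )
    return pd.DataFrame(
        data,
        index=["G1", "G2", "G3", "G4"],
        columns=[f"s{i}" for i in range(6)],
    )


def make_deg_table(genes, log2fc, p, ci_half=0.2, adj=None, status=None):
    """Assemble a per-study DEG table in the meta-analysis input layout."""
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    table = pd.DataFrame(
        {
            "gene": list(genes),
            "log2FC": log2fc,
            "CI.L": log2fc - ci_half,
            "CI.R": log2fc + ci_half,
            "P.Value": p,
        }
    )
    if adj is not None:
        table["adj.P.Val"] = adj
    if status is not None:
        table["status"] = status
    return table
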