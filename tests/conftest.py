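import numpy as np
import pandas as pd
import pytest

from typestate import CellDataset, SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset with both effect types present."""
    cfg = SimConfig(
        n_genes=600, n_cells_per_sample=80, t=0.8, s=0.8, seed=42
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """Simulation without any type or state effects."""
    cfg = SimConfig(
        n_genes=600, n_cells_per_sample=80, p_type=0.0, p_state=0.0, seed=7
    )
    return simulate(cfg)


def make_dataset(counts, sample_ids, group_ids, norm=None, clusters=None):
    """Assemble a CellDataset from raw arrays (test helper)."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "group_id": group_ids},
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"),
    )
    if clusters is not None:
        meta["true_cluster"] = clusters
    gene_meta = pd.DataFrame(
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    )
    ds = CellDataset(counts=counts, cell_meta=meta, gene_meta=gene_meta)
    if norm is not None:
        ds.norm = np.asarray(norm, dtype=float)
    return ds
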