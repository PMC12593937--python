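"""Standardized processing: QC, normalization, PCA, clustering, pseudobulk.

The fixed order of operations is QC filtering -> library-size normalization
-> (scoring) -> feature selection -> PCA on the selected features -> shared
nearest-neighbour Louvain clustering at a low and a high resolution ->
per-(sample, cluster) pseudobulk aggregation.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CellDataset


@dataclass
class Embedding:
    """PCA embedding: cells x components scores, per-component explained
    variance (non-increasing) and the ordered genes it was computed from."""

    pcs: np.ndarray
    explained_var: np.ndarray
    features_used: pd.Index

    @property
    def n_components(self) -> int:
        return self.pcs.shape[1]


@dataclass
class Pseudobulk:
    """Genes x (sample, cluster) summed counts with unit metadata."""

    sums: np.ndarray
    unit_meta: pd.DataFrame  # columns: sample_id, group_id, cluster
    gene_ids: pd.Index

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.sums.sum(axis=0)

    @property
    def n_units(self) -> int:
        return self.sums.shape[1]


def qc_filter(
    data: CellDataset,
    min_cells_per_gene: int = 20,
    min_genes_per_cell: int = 1,
) -> CellDataset:
    """Drop genes detected in too few cells, then cells with too few genes."""
    detected = data.counts > 0
    keep_genes = detected.sum(axis=1) >= min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("qc_filter removed every gene")
    counts = data.counts[keep_genes]
    keep_cells = (counts > 0).sum(axis=0) >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError("qc_filter removed every cell")
    return CellDataset(
        counts=counts[:, keep_cells],
        cell_meta=data.cell_meta.loc[keep_cells].copy(),
        gene_meta=data.gene_meta.loc[keep_genes].copy(),
        norm=None,
    )


def normalize(data: CellDataset, pseudocount: float = 1.0) -> CellDataset:
    """Median-library-size normalization on the natural-log scale.

    norm = log(pseudocount + counts * median(lib) / lib), per cell.
    """
    lib = data.counts.sum(axis=0).astype(float)
    zero = lib == 0
    if zero.any():
        bad = data.cell_meta.index[zero][:5].tolist()
        raise ValueError(f"cells with zero library size: {bad}")
    med = float(np.median(lib))
    norm = np.log(pseudocount + data.counts * (med / lib)[None, :])
    out = data.copy()
    out.norm = norm
    return out


def run_pca(
    data: CellDataset,
    features: pd.Index | list,
    n_components: int = 30,
) -> Embedding:
    """Exact SVD PCA on centered, unit-variance scaled log-expression of the
    given features; component signs fixed by the largest-magnitude loading."""
    if data.norm is None:
        raise ValueError("normalize() must run before run_pca")
    features = pd.Index(features)
    missing = features.difference(data.gene_ids)
    if len(missing):
        raise ValueError(f"features not in dataset: {list(missing[:5])}")
    idx = data.gene_ids.get_indexer(features)
    X = data.norm[idx].T.astype(float)  # cells x features
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"excluding {int(const.sum())} constant feature(s) from PCA")
        X = X[:, ~const]
        features = features[~const]
        sd = sd[~const]
    if X.shape[1] == 0:
        raise ValueError("no non-constant features left for PCA")
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_cells, n_features)={min(X.shape)}"
        )
    Xs = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(n_components), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    pcs = U * S[None, :] * flip[None, :]
    explained = S**2 / (X.shape[0] - 1)
    return Embedding(pcs=pcs, explained_var=explained, features_used=features)


def _snn_graph(pcs: np.ndarray, k_neighbors: int):
    """Exact kNN graph with shared-neighbour Jaccard edge weights.

    Neighbourhoods include the cell itself; edges are the union of directed
    kNN links.
    """
    from sklearn.neighbors import NearestNeighbors

    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)  # includes self in column 0
    import scipy.sparse as sp

    rows = np.repeat(np.arange(n), k_neighbors + 1)
    A = sp.csr_matrix(
        (np.ones(idx.size), (rows, idx.ravel())), shape=(n, n)
    )
    A.data[:] = 1.0
    inter = (A @ A.T).tocoo()  # |N(i) & N(j)|
    mask = inter.row < inter.col
    r, c, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    # keep only pairs that are kNN-linked in at least one direction
    linked = np.asarray(A[r, c]).ravel() + np.asarray(A[c, r]).ravel() > 0
    r, c, shared = r[linked], c[linked], shared[linked]
    union = 2.0 * (k_neighbors + 1) - shared
    w = shared / union
    keep = w > 0
    return list(zip(r[keep].tolist(), c[keep].tolist())), w[keep]


def cluster_graph(
    emb: Embedding,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Louvain community detection on the SNN graph of the embedding.

    Deterministic given the seed; labels are contiguous integers from 0 in
    order of first appearance.
    """
    import igraph as ig

    n = emb.pcs.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    edges, weights = _snn_graph(emb.pcs, k_neighbors)
    g = ig.Graph(n=n, edges=edges)
    _pyrandom.seed(seed)  # python-igraph draws from Python's random module
    part = g.community_multilevel(weights=list(weights), resolution=resolution)
    labels = np.asarray(part.membership)
    _, labels = np.unique(labels, return_inverse=True)
    # relabel by first appearance for stability
    order = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def make_pseudobulk(data: CellDataset, cluster_labels) -> Pseudobulk:
    """Sum counts over cells within each (sample, cluster) unit."""
    labels = np.asarray(cluster_labels)
    if labels.size != data.n_cells:
        raise ValueError("cluster_labels length does not match cells")
    sample = data.cell_meta["sample_id"].to_numpy()
    group = data.cell_meta["group_id"].to_numpy()
    keys = pd.MultiIndex.from_arrays([sample, labels])
    codes, uniques = pd.factorize(keys, sort=True)
    U = len(uniques)
    ind = np.zeros((data.n_cells, U))
    ind[np.arange(data.n_cells), codes] = 1.0
    sums = (data.counts @ ind).astype(np.int64)
    samp_u = uniques.get_level_values(0)
    clust_u = uniques.get_level_values(1)
    s2g = dict(zip(sample, group))
    unit_meta = pd.DataFrame(
        {
            "sample_id": samp_u,
            "group_id": [s2g[s] for s in samp_u],
            "cluster": clust_u,
        }
    )
    return Pseudobulk(sums=sums, unit_meta=unit_meta, gene_ids=data.gene_ids)


def normalize_pseudobulk(pb: Pseudobulk, pseudocount: float = 1.0) -> np.ndarray:
    """Median-library-size log-normalization of pseudobulk sums."""
    lib = pb.sums.sum(axis=0).astype(float)
    lib = np.maximum(lib, 1.0)
    med = float(np.median(lib))
    return np.log(pseudocount + pb.sums * (med / lib)[None, :])
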