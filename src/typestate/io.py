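"""Plain-text I/O: MatrixMarket counts, TSV metadata, truth and score tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .prep import Pseudobulk
from .simulate import CellDataset, SimTruth


def write_dataset(data: CellDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.csr_matrix(data.counts))
    data.cell_meta.to_csv(outdir / "cells.tsv", sep="\t")
    data.gene_meta.to_csv(outdir / "genes.tsv", sep="\t")


def read_dataset(indir: str | Path) -> CellDataset:
    indir = Path(indir)
    counts = np.asarray(scipy.io.mmread(indir / "matrix.mtx").todense()).astype(np.int64)
    cell_meta = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    gene_meta = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    return CellDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    nG, K = truth.cluster_fc.shape
    G = truth.state_fc.shape[2]
    cols = {}
    for k in range(K):
        cols[f"log_cluster_fc_k{k}"] = np.log(truth.cluster_fc[:, k])
    for k in range(K):
        for g in range(1, G):
            cols[f"log_state_fc_k{k}_g{g}"] = np.log(truth.state_fc[:, k, g])
    df = pd.DataFrame(cols, index=truth.gene_ids)
    if truth.categories is not None:
        for c in truth.CATEGORY_NAMES:
            df[c] = truth.categories[c].astype(int).to_numpy()
    if truth.true_typeness is not None:
        df["true_typeness"] = truth.true_typeness
        df["true_stateness"] = truth.true_stateness
    df.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> SimTruth:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kcols = sorted(c for c in df.columns if c.startswith("log_cluster_fc_k"))
    scols = sorted(c for c in df.columns if c.startswith("log_state_fc_k"))
    K = len(kcols)
    G = len(scols) // K + 1
    cluster_fc = np.exp(df[kcols].to_numpy())
    state = np.ones((len(df), K, G))
    for c in scols:
        tag = c.removeprefix("log_state_fc_")
        k, g = (int(x[1:]) for x in tag.split("_"))
        state[:, k, g] = np.exp(df[c].to_numpy())
    truth = SimTruth(
        gene_ids=df.index, cluster_fc=cluster_fc, state_fc=state
    )
    if set(SimTruth.CATEGORY_NAMES) <= set(df.columns):
        truth.categories = df[list(SimTruth.CATEGORY_NAMES)].astype(bool)
    if "true_typeness" in df.columns:
        truth.true_typeness = df["true_typeness"].to_numpy()
        truth.true_stateness = df["true_stateness"].to_numpy()
    return truth


def write_pseudobulk(pb: Pseudobulk, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "pseudobulk.mtx", sp.csr_matrix(pb.sums))
    pb.unit_meta.to_csv(outdir / "unit_meta.tsv", sep="\t", index=False)
    pd.Series(pb.gene_ids, name="gene_id").to_csv(
        outdir / "pb_genes.tsv", sep="\t", index=False
    )


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_pstar(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, p_star), e.g. from an external DSA tool."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="p_star")
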