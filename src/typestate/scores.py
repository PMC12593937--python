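"""Per-gene type and state feature scores.

* ``hvg`` — biological variance component above a fitted mean-variance trend
  of log-normalized expression (highly variable genes).
* ``tF`` — empirical-Bayes moderated F-statistic for between-cluster
  variation of pseudobulk expression, adjusting for sample effects
  (high-resolution clusters).
* ``tPVE`` / ``sPVE`` — percent variance of single-cell expression explained
  by cluster / condition in a random-intercept model
  Y ~ (1|sample) + (1|group) + (1|cluster).
* ``sPBDS`` — -log(p*) from per-cluster pseudobulk differential-state tests
  across conditions (low-resolution clusters), p* = smallest BH-adjusted
  p-value across clusters.
* ``random`` — i.i.d. uniform reference score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import _stats
from .prep import Pseudobulk, normalize_pseudobulk
from .simulate import CellDataset

log = logging.getLogger(__name__)


def score_hvg(data: CellDataset, frac: float = 0.3) -> pd.Series:
    """Variance of log-expression above a local-quadratic mean-variance trend."""
    if data.norm is None:
        raise ValueError("normalize() must run before score_hvg")
    m = data.norm.mean(axis=1)
    v = data.norm.var(axis=1, ddof=1)
    trend = _stats.loess_fit(m, v, frac=frac, degree=2)
    return pd.Series(v - trend, index=data.gene_ids, name="hvg")


def _design(unit_meta: pd.DataFrame, columns) -> np.ndarray:
    """Intercept plus drop-first dummy blocks for the given metadata columns."""
    blocks = [np.ones((len(unit_meta), 1))]
    for col in columns:
        d = pd.get_dummies(unit_meta[col], drop_first=True).to_numpy(dtype=float)
        blocks.append(d)
    return np.hstack(blocks)


def score_tf(pb: Pseudobulk, d0: float | None = None) -> pd.Series:
    """Moderated F-statistics for cluster effects on log pseudobulk expression.

    The linear model is intercept + sample + cluster on pseudobulk units from
    high-resolution clusters; residual variances are EB-squeezed before
    forming F = (between-cluster mean square) / posterior variance. Passing
    ``d0=0`` reproduces the classical (unmoderated) F.
    """
    clusters = pb.unit_meta["cluster"]
    if clusters.nunique() < 2:
        raise ValueError("type score undefined: need at least 2 clusters")
    Y = normalize_pseudobulk(pb)
    X_full = _design(pb.unit_meta, ["sample_id", "cluster"])
    X_null = _design(pb.unit_meta, ["sample_id"])
    r_full = np.linalg.matrix_rank(X_full)
    r_null = np.linalg.matrix_rank(X_null)
    df_clu = r_full - r_null
    df_resid = pb.n_units - r_full
    if df_resid < 1:
        raise ValueError(
            "zero residual degrees of freedom; more replicate samples needed"
        )

    def rss(X):
        Q, _ = np.linalg.qr(X)
        fitted = (Y @ Q) @ Q.T
        return ((Y - fitted) ** 2).sum(axis=1)

    rss_full = rss(X_full)
    rss_null = rss(X_null)
    s2 = rss_full / df_resid
    num = np.maximum(rss_null - rss_full, 0.0) / df_clu
    post, _, _ = _stats.squeeze_var(np.maximum(s2, 1e-300), df_resid, d0=d0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where((num <= 0) & (post <= 1e-12), 0.0, num / np.maximum(post, 1e-12))
    return pd.Series(F, index=pb.gene_ids, name="tF")


def score_pve(
    data: CellDataset,
    high_res_labels,
    method: str = "reml",
) -> tuple[pd.Series, pd.Series]:
    """Percent variance explained by cluster (tPVE) and condition (sPVE).

    Random-intercept variance components for sample, group and cluster are
    estimated per gene; PVE is the component's share of the total including
    the residual. Constant genes get 0 by convention.
    """
    if data.norm is None:
        raise ValueError("normalize() must run before score_pve")
    meta = data.cell_meta
    labels = np.asarray(high_res_labels)
    for name, vals in (
        ("samples", meta["sample_id"].unique()),
        ("groups", meta["group_id"].unique()),
        ("clusters", np.unique(labels)),
    ):
        if len(vals) < 2:
            raise ValueError(f"score_pve needs at least 2 {name}")
    vc = _stats.variance_components(
        data.norm,
        [meta["sample_id"].to_numpy(), meta["group_id"].to_numpy(), labels],
        factor_names=["sample", "group", "cluster"],
        method=method,
    )
    total = vc[["sample", "group", "cluster", "residual"]].sum(axis=1).to_numpy()
    safe = np.where(total > 0, total, 1.0)
    tpve = np.where(total > 0, vc["cluster"].to_numpy() / safe, 0.0)
    spve = np.where(total > 0, vc["group"].to_numpy() / safe, 0.0)
    return (
        pd.Series(tpve, index=data.gene_ids, name="tPVE"),
        pd.Series(spve, index=data.gene_ids, name="sPVE"),
    )


def _group_test_one(counts: np.ndarray, sub: pd.DataFrame, gene_ids, label) -> pd.DataFrame:
    lib = np.maximum(counts.sum(axis=0), 1.0)
    offset = np.log(lib)
    X_full = _design(sub, ["group_id"])
    X_null = np.ones((len(sub), 1))
    res = _stats.ql_group_test(counts, X_full, X_null, offset)
    p = res["p"]
    adj = _stats.bh_adjust(p)
    logfc = res["beta"][:, 1] / np.log(2.0)
    logfc[~res["tested"]] = 0.0
    return pd.DataFrame(
        {"gene_id": gene_ids, "cluster": label, "logFC": logfc, "p": p, "adj_p": adj}
    )


def pbds_test(
    pb: Pseudobulk,
    min_samples_per_group: int = 2,
    fallback_global: bool = True,
) -> pd.DataFrame:
    """Per-cluster pseudobulk cross-group NB quasi-likelihood tests.

    Returns a long DataFrame (gene_id, cluster, logFC, p, adj_p); BH
    adjustment is within cluster, across genes. Clusters missing a group (or
    with fewer than ``min_samples_per_group`` samples in either group) are
    skipped with a warning. Genes with all-zero pseudobulk counts in a
    cluster get p = 1 there.

    When every cluster is condition-pure — which happens when the upstream
    embedding separates cells by condition — no within-cluster comparison
    exists; with ``fallback_global`` the test is then run once on
    whole-dataset sample-level pseudobulks (the coarsest clustering),
    labelled ``"all"``. Without the fallback this situation raises.
    """
    meta = pb.unit_meta
    frames = []
    for clu in pd.unique(meta["cluster"]):
        sel = (meta["cluster"] == clu).to_numpy()
        sub = meta.loc[sel]
        sizes = sub.groupby("group_id", observed=True).size()
        if len(sizes) < 2 or (sizes < min_samples_per_group).any():
            log.warning("skipping cluster %r: insufficient samples per group", clu)
            continue
        frames.append(
            _group_test_one(pb.sums[:, sel].astype(float), sub, pb.gene_ids, clu)
        )
    if not frames:
        if not fallback_global:
            raise ValueError("no cluster had both groups; differential test impossible")
        log.warning(
            "no cluster contains both groups; falling back to whole-dataset pseudobulks"
        )
        codes, samples = pd.factorize(meta["sample_id"], sort=True)
        agg = np.zeros((pb.sums.shape[0], len(samples)))
        for j, c in enumerate(codes):
            agg[:, c] += pb.sums[:, j]
        s2g = dict(zip(meta["sample_id"], meta["group_id"]))
        sub = pd.DataFrame(
            {"sample_id": samples, "group_id": [s2g[s] for s in samples]}
        )
        sizes = sub.groupby("group_id", observed=True).size()
        if len(sizes) < 2 or (sizes < min_samples_per_group).any():
            raise ValueError("cross-group comparison impossible even globally")
        frames.append(_group_test_one(agg, sub, pb.gene_ids, "all"))
    return pd.concat(frames, ignore_index=True)


def score_spbds(pb: Pseudobulk) -> pd.Series:
    """-log(p*) with p* the smallest BH-adjusted cross-group p across
    (low-resolution) clusters; natural log."""
    table = pbds_test(pb)
    p_star = (
        table.groupby("gene_id", observed=True)["adj_p"].min().reindex(pb.gene_ids)
    )
    score = -np.log(np.clip(p_star.to_numpy(), 1e-300, 1.0))
    return pd.Series(score, index=pb.gene_ids, name="sPBDS")


def score_random(data: CellDataset, seed: int = 0) -> pd.Series:
    """I.i.d. uniform reference scores, reproducible by seed."""
    rng = np.random.default_rng(seed)
    return pd.Series(rng.random(data.n_genes), index=data.gene_ids, name="random")


def compute_scores(
    data: CellDataset,
    pb_high: Pseudobulk,
    pb_low: Pseudobulk,
    high_res_labels,
    seed: int = 0,
    method: str = "reml",
) -> pd.DataFrame:
    """All scores as one gene x score table (hvg, tF, tPVE, sPVE, sPBDS, random)."""
    hvg = score_hvg(data)
    tf = score_tf(pb_high)
    tpve, spve = score_pve(data, high_res_labels, method=method)
    spbds = score_spbds(pb_low)
    rnd = score_random(data, seed=seed)
    return pd.concat([hvg, tf, tpve, spve, spbds, rnd], axis=1)
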