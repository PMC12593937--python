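"""Evaluation statistics for selections and embeddings.

ARI against the simulated clusters, F1 of selected gene sets against truth
categories, local inverse Simpson's index (LISI) with its (L-1)/(n-1)
scaling, percent variance explained by group/cluster (PVE_g/PVE_k) on
expression, principal-component regression (PCR_g/PCR_k) on embeddings, and
Spearman correlations of feature scores against true typeness/stateness.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _stats
from .prep import Embedding
from .simulate import CellDataset, SimTruth

log = logging.getLogger(__name__)


def ari(true_labels, pred_labels) -> float:
    """Adjusted Rand index (permutation-model); negative values are kept."""
    from sklearn.metrics import adjusted_rand_score

    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(true_labels, pred_labels))


def f1_selection(selected, truth_set) -> float:
    """F1 = TP / (TP + (FP + FN)/2); 1.0 when both sets are empty."""
    sel = set(selected)
    tru = set(truth_set)
    if not sel and not tru:
        return 1.0
    tp = len(sel & tru)
    fp = len(sel - tru)
    fn = len(tru - sel)
    denom = tp + 0.5 * (fp + fn)
    return tp / denom if denom > 0 else 0.0


def lisi(emb: Embedding | np.ndarray, labels, perplexity: float = 30.0):
    """Per-cell local inverse Simpson's index and its scaled summary.

    Neighbour weights use a Gaussian kernel with per-cell bandwidth tuned by
    binary search to the target perplexity; L = 1 / sum(p_c^2) over category
    probabilities in the weighted neighbourhood. The summary is the mean L
    scaled to [0, 1] via (L - 1) / (n_categories - 1).
    """
    from sklearn.neighbors import NearestNeighbors

    pcs = emb.pcs if isinstance(emb, Embedding) else np.asarray(emb, float)
    codes, cats = pd.factorize(pd.Series(np.asarray(labels)))
    n_cat = len(cats)
    if n_cat < 2:
        raise ValueError("lisi needs at least 2 categories with cells")
    n = pcs.shape[0]
    if n <= 3 * perplexity:
        raise ValueError("lisi needs more than 3 * perplexity cells")
    k = min(n - 1, int(np.ceil(3 * perplexity)))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    d2 = dist[:, 1:] ** 2
    nb = idx[:, 1:]
    logU = np.log(perplexity)
    L = np.empty(n)
    for i in range(n):
        di = d2[i]
        lo, hi = -np.inf, np.inf
        beta = 1.0 / (np.mean(di) + 1e-12)
        P = None
        for _ in range(64):
            w = np.exp(-beta * di)
            sw = w.sum()
            if sw <= 1e-300:
                H = 0.0
                P = np.zeros_like(w)
                P[np.argmin(di)] = 1.0
            else:
                P = w / sw
                H = -(P * np.log(np.maximum(P, 1e-300))).sum()
            diff = H - logU
            if abs(diff) < 1e-5:
                break
            if diff > 0:
                lo = beta
                beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = beta / 2 if not np.isfinite(lo) else (beta + lo) / 2
        mass = np.bincount(codes[nb[i]], weights=P, minlength=n_cat)
        # debiased weighted Simpson concentration: without the correction a
        # finite effective neighbourhood biases L below the true effective
        # number of categories (a perfectly mixed binary labelling would read
        # ~1.9 rather than 2)
        ess_inv = float((P**2).sum())
        simpson = ((mass**2).sum() - ess_inv) / max(1.0 - ess_inv, 1e-12)
        # the floor allows sampling noise to overshoot n_cat symmetrically so
        # the mean is not pulled down by one-sided clipping
        L[i] = 1.0 / np.maximum(simpson, 1.0 / (2.0 * n_cat))
    scaled = float(np.clip((L.mean() - 1.0) / (n_cat - 1.0), 0.0, 1.0))
    return L, scaled


def pve_eval(
    data: CellDataset,
    labels_k,
    labels_g,
    genes=None,
    method: str = "reml",
) -> tuple[float, float]:
    """Mean per-gene PVE by cluster and by group, residual disregarded.

    Components for Y ~ (1|g) + (1|k) are re-scaled to sum to one; genes with
    both components zero are skipped (their count is logged).
    """
    if data.norm is None:
        raise ValueError("normalize() must run before pve_eval")
    idx = (
        slice(None)
        if genes is None
        else data.gene_ids.get_indexer(pd.Index(genes))
    )
    Y = data.norm[idx]
    vc = _stats.variance_components(
        Y,
        [np.asarray(labels_g), np.asarray(labels_k)],
        factor_names=["group", "cluster"],
        method=method,
    )
    tot = (vc["group"] + vc["cluster"]).to_numpy()
    keep = tot > 0
    if (~keep).any():
        log.info("pve_eval: skipping %d degenerate gene(s)", int((~keep).sum()))
    if not keep.any():
        return 0.0, 0.0
    pve_k = float((vc["cluster"].to_numpy()[keep] / tot[keep]).mean())
    pve_g = float((vc["group"].to_numpy()[keep] / tot[keep]).mean())
    return pve_k, pve_g


def pcr(emb: Embedding, labels) -> float:
    """Explained-variance-weighted mean ANOVA R^2 of PCs on a categorical."""
    codes, cats = pd.factorize(pd.Series(np.asarray(labels)))
    if len(cats) < 2:
        log.warning("pcr: single category; returning 0 by convention")
        return 0.0
    pcs = emb.pcs
    r2 = np.empty(pcs.shape[1])
    for i in range(pcs.shape[1]):
        x = pcs[:, i]
        grand = x.mean()
        sst = ((x - grand) ** 2).sum()
        if sst <= 0:
            r2[i] = 0.0
            continue
        ssb = 0.0
        for c in range(len(cats)):
            xc = x[codes == c]
            ssb += xc.size * (xc.mean() - grand) ** 2
        r2[i] = ssb / sst
    w = emb.explained_var
    return float((w * r2).sum() / w.sum())


def score_truth_correlation(scores: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    """Spearman correlation of every score column against true typeness and
    stateness; constant columns are recorded as 0 with a warning."""
    if truth.true_typeness is None:
        raise ValueError("truth scores not populated; run true_scores")
    t = pd.Series(truth.true_typeness, index=truth.gene_ids)
    s = pd.Series(truth.true_stateness, index=truth.gene_ids)
    t = t.reindex(scores.index)
    s = s.reindex(scores.index)
    if t.isna().any():
        raise ValueError("scores and truth are on different gene sets")
    out = {}
    for col in scores.columns:
        x = scores[col].to_numpy()
        if np.all(x == x[0]):
            log.warning("score %r is constant; correlation set to 0", col)
            out[col] = (0.0, 0.0)
        else:
            out[col] = (
                float(sps.spearmanr(x, t.to_numpy()).statistic),
                float(sps.spearmanr(x, s.to_numpy()).statistic),
            )
    return pd.DataFrame(
        out, index=["true_typeness", "true_stateness"]
    ).T
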