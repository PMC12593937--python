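"""Cluster-based pseudobulk differential-state analysis.

Per low-resolution cluster, sample-level pseudobulks are tested across
conditions with a negative-binomial quasi-likelihood model; the per-gene
minimum BH-adjusted p-value across clusters (p*) defines "hits" at a given
alpha. Concordance between runs is the Spearman correlation of p* vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .metrics import f1_selection
from .prep import Pseudobulk
from .scores import pbds_test
from .simulate import SimTruth

log = logging.getLogger(__name__)


@dataclass
class DSAResult:
    table: pd.DataFrame  # long: gene_id, cluster, logFC, p, adj_p
    p_star: pd.Series  # per gene, min adj_p across clusters
    hits: pd.Index
    alpha: float
    n_instances: int


def run_dsa(pb: Pseudobulk, alpha: float = 0.05) -> DSAResult:
    """Full per-cluster test table plus p* and hit set."""
    table = pbds_test(pb)
    p_star = (
        table.groupby("gene_id", observed=True)["adj_p"]
        .min()
        .reindex(pb.gene_ids)
        .fillna(1.0)
    )
    hits = p_star.index[p_star.to_numpy() < alpha]
    return DSAResult(
        table=table,
        p_star=p_star,
        hits=hits,
        alpha=alpha,
        n_instances=int(table["cluster"].nunique()),
    )


def concordance(p_star_a: pd.Series, p_star_b: pd.Series, min_genes: int = 50) -> float:
    """Spearman correlation of two p* vectors on their common gene set."""
    common = p_star_a.index.intersection(p_star_b.index)
    if len(common) < min_genes:
        raise ValueError(
            f"only {len(common)} genes shared; need at least {min_genes}"
        )
    return float(
        sps.spearmanr(
            p_star_a.loc[common].to_numpy(), p_star_b.loc[common].to_numpy()
        ).statistic
    )


def ds_f1(result: DSAResult, truth: SimTruth) -> float | None:
    """F1 of DSA hits against the true DS gene set; None (logged) when both
    the DS set and the hit set are empty."""
    if truth.categories is None:
        raise ValueError("truth categories not populated")
    ds_genes = truth.category_genes("DS")
    if len(ds_genes) == 0 and len(result.hits) == 0:
        log.info("ds_f1 undefined: no DS genes and no hits; reporting missing")
        return None
    return f1_selection(result.hits, ds_genes)
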