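"""Gamma-Poisson simulator for multi-sample, multi-condition scRNA-seq counts.

Cells belong to one of K clusters (cell types) and one of G experimental
groups (conditions), with R replicate samples per group. Two location
parameters control the strength of the competing effects:

* ``t`` ("typeness"): per-gene, per-cluster fold-changes, FC ~ LogNormal(t,
  fc_scale) with a random up/down sign on the log scale, assigned to a gene
  with probability ``p_type``;
* ``s`` ("stateness"): condition fold-changes drawn the same way with
  location ``s``, assigned to a gene with probability ``p_state``; an
  affected gene draws an independent fold-change per cluster for every
  group beyond the reference.

Counts are Gamma-Poisson: gene baseline means are Gamma across genes
(droplet-like sparsity, ~0.3 counts/gene/cell by default), scaled by a
log-normal per-cell library factor and the applicable fold-changes, with a
per-observation Gamma layer adding biological overdispersion (``bcv``, the
biological coefficient of variation). The full ground truth (fold-change
matrices, gene categories, true typeness/stateness) is returned alongside
the counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class SimConfig:
    """Simulation parameters; defaults follow the study design of three
    clusters and three replicate samples in each of two conditions."""

    n_genes: int = 2000
    n_cells_per_sample: int = 200
    n_clusters: int = 3
    n_groups: int = 2
    n_replicates: int = 3
    t: float = 0.5
    s: float = 0.5
    fc_scale: float = 0.4
    p_type: float = 0.3
    p_state: float = 0.3
    mean_shape: float = 0.6
    mean_rate: float = 2.0
    lib_sigma: float = 0.2
    bcv: float = 0.3
    sample_sigma: float = 0.3
    cluster_props: Optional[Sequence[float]] = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_cells_per_sample", "n_clusters", "n_groups",
                     "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"configuration error: {name} must be positive")
        if self.t < 0 or self.s < 0:
            raise ValueError("configuration error: t and s must be non-negative")
        if not (0 <= self.p_type <= 1 and 0 <= self.p_state <= 1):
            raise ValueError("configuration error: p_type/p_state must be in [0, 1]")
        if self.fc_scale <= 0:
            raise ValueError("configuration error: fc_scale must be positive")
        if self.bcv < 0:
            raise ValueError("configuration error: bcv must be non-negative")
        if self.cluster_props is not None:
            props = np.asarray(self.cluster_props, dtype=float)
            if props.size != self.n_clusters or np.any(props <= 0):
                raise ValueError("configuration error: invalid cluster_props")


@dataclass
class SimTruth:
    """Ground truth: per-gene fold-change matrices, gene categories and
    derived true typeness/stateness scores.

    ``cluster_fc`` is genes x clusters, ``state_fc`` genes x clusters x
    groups (group 0 is the reference, all ones). Fold-changes are stored on
    the natural scale; categorization and scoring work on natural logs.
    """

    gene_ids: pd.Index
    cluster_fc: np.ndarray
    state_fc: np.ndarray
    categories: Optional[pd.DataFrame] = None
    true_typeness: Optional[np.ndarray] = None
    true_stateness: Optional[np.ndarray] = None

    CATEGORY_NAMES = ("DE", "DS", "DEgtDS", "DSgtDE", "DEnotDS", "DSnotDE")

    def category_genes(self, name: str) -> pd.Index:
        if self.categories is None:
            raise ValueError("categories not populated; run categorize_genes")
        if name not in self.CATEGORY_NAMES:
            raise ValueError(f"unknown category {name!r}")
        return self.gene_ids[self.categories[name].to_numpy()]

    def subset(self, genes: pd.Index) -> "SimTruth":
        """Truth restricted to the given genes (e.g. after QC filtering)."""
        keep = self.gene_ids.get_indexer(genes)
        if (keep < 0).any():
            raise ValueError("genes not present in truth")
        return dataclasses.replace(
            self,
            gene_ids=pd.Index(genes),
            cluster_fc=self.cluster_fc[keep],
            state_fc=self.state_fc[keep],
            categories=None if self.categories is None else self.categories.iloc[keep],
            true_typeness=(
                None if self.true_typeness is None else self.true_typeness[keep]
            ),
            true_stateness=(
                None if self.true_stateness is None else self.true_stateness[keep]
            ),
        )


@dataclass
class CellDataset:
    """Genes x cells counts with cell and gene annotations.

    ``cell_meta`` always carries ``sample_id`` and ``group_id``; simulated
    data adds ``true_cluster`` and derived labels are attached as
    ``cluster_lo`` / ``cluster_hi``. ``norm`` holds log-normalized expression
    once :func:`typestate.prep.normalize` has run.
    """

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    norm: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.counts.shape != (len(self.gene_meta), len(self.cell_meta)):
            raise ValueError("counts shape does not match gene/cell metadata")
        samples = self.cell_meta.groupby("sample_id", observed=True)["group_id"].nunique()
        if (samples > 1).any():
            raise ValueError("a sample_id maps to more than one group_id")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index

    def copy(self) -> "CellDataset":
        return CellDataset(
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            norm=None if self.norm is None else self.norm.copy(),
        )


def _log_abs_cluster(truth: SimTruth) -> np.ndarray:
    return np.abs(np.log(truth.cluster_fc))

def _log_abs_state(truth: SimTruth) -> np.ndarray:
    """|log state FC| over the non-reference (cluster, group) slots."""
    return np.abs(np.log(truth.state_fc[:, :, 1:]))


def simulate(config: SimConfig) -> tuple[CellDataset, SimTruth]:
    """Draw a dataset and its ground truth; bit-reproducible given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nG, K, G, R = config.n_genes, config.n_clusters, config.n_groups, config.n_replicates

    lam = rng.gamma(shape=config.mean_shape, scale=1.0 / config.mean_rate, size=nG)

    # cluster (type) fold-changes: FC ~ LogNormal(t, fc_scale), random sign
    has_type = rng.random(nG) < config.p_type
    mag_t = rng.normal(config.t, config.fc_scale, size=(nG, K))
    sign_t = rng.choice([-1.0, 1.0], size=(nG, K))
    log_cfc = np.where(has_type[:, None], sign_t * mag_t, 0.0)
    cluster_fc = np.exp(log_cfc)

    # condition (state) fold-changes: affected genes draw an independent FC
    # per cluster for each group beyond the reference
    has_state = rng.random(nG) < config.p_state
    mag_s = rng.normal(config.s, config.fc_scale, size=(nG, K, G - 1))
    sign_s = rng.choice([-1.0, 1.0], size=(nG, K, G - 1))
    log_sfc = np.where(has_state[:, None, None], sign_s * mag_s, 0.0)
    state_fc = np.concatenate(
        [np.ones((nG, K, 1)), np.exp(log_sfc)], axis=2
    )

    # cells
    n_cells = config.n_cells_per_sample * R * G
    sample_ids, group_ids = [], []
    for g in range(G):
        for r in range(R):
            sid = f"g{g}_r{r}"
            sample_ids += [sid] * config.n_cells_per_sample
            group_ids += [f"g{g}"] * config.n_cells_per_sample
    props = (
        np.full(K, 1.0 / K)
        if config.cluster_props is None
        else np.asarray(config.cluster_props, float) / np.sum(config.cluster_props)
    )
    clusters = rng.choice(K, size=n_cells, p=props)
    lib = rng.lognormal(mean=0.0, sigma=config.lib_sigma, size=n_cells)

    gvec = np.array([int(s[1:]) for s in group_ids])
    # per-(gene, sample) log-normal factors: sample-to-sample variability
    n_samples = G * R
    samp_fc = (
        rng.lognormal(mean=0.0, sigma=config.sample_sigma, size=(nG, n_samples))
        if config.sample_sigma > 0
        else np.ones((nG, n_samples))
    )
    svec = np.repeat(np.arange(n_samples), config.n_cells_per_sample)
    mean = (
        lam[:, None]
        * lib[None, :]
        * samp_fc[:, svec]
        * cluster_fc[:, clusters]
        * state_fc[:, clusters, gvec]
    )
    if config.bcv > 0:
        # biological overdispersion: Gamma-mixed Poisson (NB with CV = bcv)
        shape = 1.0 / config.bcv**2
        mean = rng.gamma(shape=shape, scale=mean / shape)
    counts = rng.poisson(mean)

    gene_ids = pd.Index([f"gene{i:04d}" for i in range(nG)], name="gene_id")
    cell_ids = pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell_id")
    cell_meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group_id": group_ids,
            "true_cluster": clusters,
        },
        index=cell_ids,
    )
    gene_meta = pd.DataFrame({"base_mean": lam}, index=gene_ids)
    data = CellDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)
    truth = SimTruth(gene_ids=gene_ids, cluster_fc=cluster_fc, state_fc=state_fc)
    truth = categorize_genes(truth)
    truth = true_scores(truth)
    return data, truth


def categorize_genes(truth: SimTruth, log_fc_threshold: float = 0.0) -> SimTruth:
    """Fill the DE/DS/DEgtDS/DSgtDE/DEnotDS/DSnotDE membership flags.

    DE: any |log cluster FC| above the threshold; DS: any |log condition FC|
    above it. "Greater than" compares the mean |log FC| across clusters with
    the mean across the non-reference (cluster, group) slots.
    """
    if log_fc_threshold < 0:
        raise ValueError("log_fc_threshold must be non-negative")
    la_c = _log_abs_cluster(truth)
    la_s = _log_abs_state(truth)
    de = (la_c > log_fc_threshold).any(axis=1)
    ds = (la_s > log_fc_threshold).any(axis=(1, 2))
    mean_c = la_c.mean(axis=1)
    mean_s = la_s.mean(axis=(1, 2))
    cats = pd.DataFrame(
        {
            "DE": de,
            "DS": ds,
            "DEgtDS": de & (mean_c > mean_s),
            "DSgtDE": ds & (mean_s > mean_c),
            "DEnotDS": de & ~ds,
            "DSnotDE": ds & ~de,
        },
        index=truth.gene_ids,
    )
    return dataclasses.replace(truth, categories=cats)


def true_scores(truth: SimTruth) -> SimTruth:
    """Fill true typeness/stateness: mean |log FC| over clusters, and over
    the non-reference (cluster, group) slots, respectively."""
    typeness = _log_abs_cluster(truth).mean(axis=1)
    stateness = _log_abs_state(truth).mean(axis=(1, 2))
    return dataclasses.replace(
        truth, true_typeness=typeness, true_stateness=stateness
    )
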