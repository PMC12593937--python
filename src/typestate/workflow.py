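"""Orchestration of the simulation-grid study.

For every (t, s, seed) grid cell: simulate -> QC -> normalize -> initial
feature selection and clustering -> score -> for each selection strategy:
select, re-embed on the selected features, re-cluster, evaluate, and run
pseudobulk differential-state analysis. Results are aggregated into long
tables with full provenance; completed cells are skipped on rerun via a
JSON manifest.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as tsio
from . import metrics as tsmetrics
from .dsa import ds_f1, run_dsa
from .prep import cluster_graph, make_pseudobulk, normalize, qc_filter, run_pca
from .scores import compute_scores
from .select import SelectionSpec, apply_strategy
from .simulate import CellDataset, SimConfig, SimTruth, simulate

log = logging.getLogger(__name__)


@dataclass
class PrepParams:
    min_cells_per_gene: int = 20
    min_genes_per_cell: int = 1
    n_components: int = 30
    k_neighbors: int = 20
    resolution_low: float = 0.5
    resolution_high: float = 2.0
    n_hvg_initial: int = 1000


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    t_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    s_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    strategies: Sequence[str] = ("random", "hvg", "tF", "tF-sPVE", "oracle:DEnotDS")
    seeds: Sequence[int] = (0, 1)
    prep: PrepParams = field(default_factory=PrepParams)
    outdir: str = "results"
    compute_lisi: bool = True
    run_dsa: bool = True

    def validate(self) -> None:
        if not len(self.t_grid) or not len(self.s_grid) or not len(self.strategies):
            raise ValueError("grid and strategies must be non-empty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")


def derive_seed(master: int, *tags) -> int:
    """Deterministic per-stage seed below 2^31."""
    key = "|".join([str(master)] + [str(t) for t in tags])
    return int(zlib.crc32(key.encode()) % (2**31 - 1))


def prepare(data: CellDataset, params: PrepParams, seed: int):
    """QC, normalize, initial HVG-based embedding, low/high-res clustering."""
    from .scores import score_hvg

    data = qc_filter(data, params.min_cells_per_gene, params.min_genes_per_cell)
    data = normalize(data)
    hvg = score_hvg(data)
    n_init = min(params.n_hvg_initial, data.n_genes)
    feats = hvg.sort_values(ascending=False).index[:n_init]
    n_comp = min(params.n_components, len(feats) - 1, data.n_cells - 1)
    emb = run_pca(data, feats, n_components=n_comp)
    lo = cluster_graph(emb, params.k_neighbors, params.resolution_low,
                       seed=derive_seed(seed, "lo"))
    hi = cluster_graph(emb, params.k_neighbors, params.resolution_high,
                       seed=derive_seed(seed, "hi"))
    data.cell_meta["cluster_lo"] = lo
    data.cell_meta["cluster_hi"] = hi
    return data, emb


def reprocess_and_evaluate(
    data: CellDataset,
    truth: Optional[SimTruth],
    selected: pd.Index,
    params: PrepParams,
    seed: int,
    compute_lisi: bool = True,
    with_dsa: bool = True,
):
    """Re-embed on a selection, re-cluster, and compute the metric panel.

    Returns (metrics dict, DSAResult or None). ARI is against the simulated
    clusters when truth labels are present.
    """
    n_comp = min(params.n_components, len(selected) - 1, data.n_cells - 1)
    if n_comp < 2:
        raise ValueError("selection too small to embed")
    emb = run_pca(data, selected, n_components=n_comp)
    labels = cluster_graph(emb, params.k_neighbors, params.resolution_low,
                           seed=derive_seed(seed, "relo"))
    meta = data.cell_meta
    out: dict[str, float] = {"n_selected": float(len(selected))}
    if "true_cluster" in meta.columns:
        out["ARI"] = tsmetrics.ari(meta["true_cluster"].to_numpy(), labels)
    k_ref = (
        meta["true_cluster"].to_numpy()
        if "true_cluster" in meta.columns
        else labels
    )
    pve_k, pve_g = tsmetrics.pve_eval(
        data, k_ref, meta["group_id"].to_numpy(), genes=selected
    )
    out["PVE_k"], out["PVE_g"] = pve_k, pve_g
    out["PCR_k"] = tsmetrics.pcr(emb, k_ref)
    out["PCR_g"] = tsmetrics.pcr(emb, meta["group_id"].to_numpy())
    if compute_lisi:
        _, out["LISI_k"] = tsmetrics.lisi(emb, k_ref)
        _, out["LISI_g"] = tsmetrics.lisi(emb, meta["group_id"].to_numpy())
    if truth is not None and truth.categories is not None:
        for cat in ("DEnotDS", "DSnotDE"):
            out[f"F1_{cat}"] = tsmetrics.f1_selection(
                selected, truth.category_genes(cat)
            )
    dsa_res = None
    if with_dsa:
        pb = make_pseudobulk(data, labels)
        dsa_res = run_dsa(pb)
        out["n_hits"] = float(len(dsa_res.hits))
        if truth is not None:
            f1 = ds_f1(dsa_res, truth)
            if f1 is not None:
                out["F1_DS_hits"] = f1
    return out, dsa_res


def run_cell(t: float, s: float, seed: int, config: RunConfig, celldir: Path):
    """One grid cell: simulate, prep, score, iterate strategies; write outputs."""
    import dataclasses

    celldir.mkdir(parents=True, exist_ok=True)
    manifest_path = celldir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("complete"):
            log.info("skipping completed cell %s", celldir.name)
            return manifest
    sim_cfg = dataclasses.replace(
        config.sim, t=t, s=s, seed=derive_seed(seed, t, s, "sim")
    )
    data, truth = simulate(sim_cfg)
    data, _ = prepare(data, config.prep, derive_seed(seed, t, s, "prep"))
    truth_kept = _subset_truth(truth, data.gene_ids)
    tsio.write_truth(truth_kept, celldir / "truth.tsv")
    pb_hi = make_pseudobulk(data, data.cell_meta["cluster_hi"].to_numpy())
    pb_lo = make_pseudobulk(data, data.cell_meta["cluster_lo"].to_numpy())
    scores = compute_scores(
        data, pb_hi, pb_lo, data.cell_meta["cluster_hi"].to_numpy(),
        seed=derive_seed(seed, t, s, "score"),
    )
    tsio.write_scores(scores, celldir / "scores.tsv")
    corr = tsmetrics.score_truth_correlation(scores, truth_kept)
    eval_rows, corr_rows, failures = [], [], []
    for sc in corr.index:
        for tr in corr.columns:
            corr_rows.append(
                {"t": t, "s": s, "seed": seed, "score": sc,
                 "truth_measure": tr, "spearman": corr.loc[sc, tr]}
            )
    for strat in config.strategies:
        try:
            spec = SelectionSpec(strategy=strat,
                                 seed=derive_seed(seed, t, s, strat, "sel"))
            selected = apply_strategy(scores, spec, truth=truth_kept)
            vals, dsa_res = reprocess_and_evaluate(
                data, truth_kept, selected, config.prep,
                derive_seed(seed, t, s, strat),
                compute_lisi=config.compute_lisi, with_dsa=config.run_dsa,
            )
            for metric, value in vals.items():
                eval_rows.append(
                    {"t": t, "s": s, "seed": seed, "strategy": strat,
                     "metric": metric, "value": value}
                )
            if dsa_res is not None:
                pstar = dsa_res.p_star.rename("p_star").to_frame()
                pstar["hit"] = (dsa_res.p_star < dsa_res.alpha).astype(int)
                pstar.to_csv(celldir / f"pstar_{strat.replace(':', '_')}.tsv", sep="\t")
        except Exception as exc:  # isolate per-strategy failures
            log.warning("strategy %s failed in %s: %s", strat, celldir.name, exc)
            failures.append({"strategy": strat, "error": str(exc)})
    pd.DataFrame(eval_rows).to_csv(celldir / "eval.tsv", sep="\t", index=False)
    pd.DataFrame(corr_rows).to_csv(celldir / "corr.tsv", sep="\t", index=False)
    manifest = {
        "t": t, "s": s, "seed": seed, "complete": True,
        "strategies": list(config.strategies), "failures": failures,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _subset_truth(truth: SimTruth, genes: pd.Index) -> SimTruth:
    return truth.subset(genes)


def run_grid(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Loop the full grid; aggregate eval.tsv and corr.tsv; resume-safe."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_eval, all_corr, failed_cells = [], [], []
    for t in config.t_grid:
        for s in config.s_grid:
            for seed in config.seeds:
                name = f"t{t}_s{s}_seed{seed}"
                celldir = outdir / name
                try:
                    run_cell(float(t), float(s), int(seed), config, celldir)
                except Exception as exc:
                    log.error("grid cell %s failed: %s", name, exc)
                    failed_cells.append({"cell": name, "error": str(exc)})
                    continue
                ev = celldir / "eval.tsv"
                co = celldir / "corr.tsv"
                if ev.exists() and ev.stat().st_size > 1:
                    df = pd.read_csv(ev, sep="\t")
                    if len(df):
                        all_eval.append(df)
                if co.exists() and co.stat().st_size > 1:
                    df = pd.read_csv(co, sep="\t")
                    if len(df):
                        all_corr.append(df)
    eval_df = pd.concat(all_eval, ignore_index=True) if all_eval else pd.DataFrame()
    corr_df = pd.concat(all_corr, ignore_index=True) if all_corr else pd.DataFrame()
    eval_df.to_csv(outdir / "eval.tsv", sep="\t", index=False)
    corr_df.to_csv(outdir / "corr.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps({"failed_cells": failed_cells}, indent=1)
    )
    return {"eval": eval_df, "corr": corr_df}


def load_external(counts_mtx: str | Path, cell_meta_tsv: str | Path,
                  gene_meta_tsv: str | Path | None = None) -> CellDataset:
    """Load a real dataset (MTX + TSV), applying annotation-based exclusions.

    ``cell_meta`` must have ``sample_id`` and ``group_id``; optional columns:
    ``multiplet`` (truthy / "doublet" / "multiplet" rows dropped) and
    ``cell_type`` ("unassigned"/empty rows dropped). Exclusions run before
    any gene filtering.
    """
    import scipy.io

    counts = np.asarray(scipy.io.mmread(counts_mtx).todense()).astype(np.int64)
    cell_meta = pd.read_csv(cell_meta_tsv, sep="\t", index_col=0)
    missing = [c for c in ("sample_id", "group_id") if c not in cell_meta.columns]
    if missing:
        raise ValueError(f"cell metadata missing required columns: {missing}")
    if gene_meta_tsv is not None:
        gene_meta = pd.read_csv(gene_meta_tsv, sep="\t", index_col=0)
    else:
        gene_meta = pd.DataFrame(
            index=pd.Index([f"gene{i}" for i in range(counts.shape[0])],
                           name="gene_id")
        )
    keep = np.ones(len(cell_meta), dtype=bool)
    if "multiplet" in cell_meta.columns:
        vals = cell_meta["multiplet"].astype(str).str.lower()
        keep &= ~vals.isin({"true", "1", "doublet", "multiplet"})
    if "cell_type" in cell_meta.columns:
        vals = cell_meta["cell_type"].astype(str).str.lower()
        keep &= ~vals.isin({"unassigned", "na", "nan", ""})
    return CellDataset(
        counts=counts[:, keep],
        cell_meta=cell_meta.loc[keep].copy(),
        gene_meta=gene_meta,
    )
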