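"""Rank-based feature selection, including type-not-state rank differences.

Single-score strategies rank genes by decreasing score. Combined strategies
(e.g. ``tF-sPVE``) rank by the difference rank(type) - rank(state), with
ranks assigned in increasing score order so that genes with a high type
score and a low state score float to the top. Oracle strategies return a
ground-truth gene category from the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import SimTruth

STRATEGIES = (
    "random",
    "hvg",
    "tF",
    "tPVE",
    "tF-sPBDS",
    "tF-sPVE",
    "tPVE-sPVE",
)


@dataclass
class SelectionSpec:
    strategy: str
    n: Optional[int] = None  # None: bind to |DEnotDS| from truth
    seed: int = 0

    def validate(self) -> None:
        if self.strategy.startswith("oracle:"):
            cat = self.strategy.split(":", 1)[1]
            if cat not in SimTruth.CATEGORY_NAMES:
                raise ValueError(f"unknown oracle category {cat!r}")
        elif self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be positive")


def rank_single(score: pd.Series) -> pd.Series:
    """Fractional ranks, rank 1 = largest score."""
    bad = score.index[score.isna()]
    if len(bad):
        raise ValueError(f"NaN scores for genes: {list(bad[:5])}")
    return score.rank(ascending=False, method="average")


def _strict_order(key: pd.Series, descending: bool = True) -> pd.Index:
    """Total ordering by key, ties broken by gene identifier."""
    df = pd.DataFrame({"key": key.to_numpy(), "gene": key.index})
    df = df.sort_values(["key", "gene"], ascending=[not descending, True],
                        kind="mergesort")
    return pd.Index(df["gene"])


def rank_combined(type_score: pd.Series, state_score: pd.Series) -> pd.Series:
    """Combined key rank(type) - rank(state), ranks in increasing score order."""
    if not type_score.index.equals(state_score.index):
        raise ValueError("type and state scores are on different gene sets")
    for s in (type_score, state_score):
        if s.isna().any():
            raise ValueError("NaN scores in combined ranking")
    r_t = type_score.rank(ascending=True, method="average")
    r_s = state_score.rank(ascending=True, method="average")
    return r_t - r_s


def select_top_n(order: pd.Index, n: int) -> pd.Index:
    if n > len(order):
        raise ValueError(f"n={n} exceeds the {len(order)} ranked genes")
    return order[:n]


def apply_strategy(
    scores: pd.DataFrame,
    spec: SelectionSpec,
    truth: Optional[SimTruth] = None,
) -> pd.Index:
    """Resolve a selection strategy to an ordered set of selected genes.

    ``n`` unset binds to the number of DEnotDS genes in the provided truth
    (oracle strategies always return their full category).
    """
    spec.validate()
    genes = scores.index
    if spec.strategy.startswith("oracle:"):
        if truth is None:
            raise ValueError("oracle strategies require simulation truth")
        cat = spec.strategy.split(":", 1)[1]
        return truth.category_genes(cat).intersection(genes, sort=False)
    if spec.n is None:
        if truth is None:
            raise ValueError("n unset: simulation truth needed to bind n = |DEnotDS|")
        n = int(truth.categories["DEnotDS"].sum())
    else:
        n = spec.n
    if spec.strategy == "random":
        rng = np.random.default_rng(spec.seed)
        order = pd.Index(genes[rng.permutation(len(genes))])
    elif "-" in spec.strategy:
        t_name, s_name = spec.strategy.split("-")
        key = rank_combined(scores[t_name], scores[s_name])
        order = _strict_order(key)
    else:
        order = _strict_order(scores[spec.strategy])
    return select_top_n(order, n)
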