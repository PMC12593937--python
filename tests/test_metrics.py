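import itertools

import numpy as np
import pandas as pd
import pytest

from typestate import (
    Embedding,
    SimTruth,
    ari,
    f1_selection,
    lisi,
    pcr,
    pve_eval,
    score_truth_correlation,
)
from conftest import make_dataset


def _ari_pair_counting(a, b):
    """Brute-force ARI over all cell pairs (independent oracle)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    exp = (ss + sd) * (ss + ds) / total
    mx = 0.5 * ((ss + sd) + (ss + ds))
    if mx == exp:
        return 1.0
    return (ss - exp) / (mx - exp)


class TestAri:
    def test_identical_labelings(self):
        assert ari([0, 1, 1, 2], [5, 3, 3, 9]) == 1.0

    def test_hand_computed_negative_case(self):
        assert ari([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 3, 30)
            assert ari(a, b) == pytest.approx(_ari_pair_counting(a, b), abs=1e-12)
        singles = np.arange(30)  # all-singleton labelling
        b = rng.integers(0, 3, 30)
        assert ari(singles, b) == pytest.approx(
            _ari_pair_counting(singles, b), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ari([1, 2], [1, 2, 3])


class TestF1:
    def test_perfect_selection(self):
        assert f1_selection({"a", "b"}, {"a", "b"}) == 1.0

    def test_balanced_errors(self):
        sel = set(range(10))  # TP=5 FP=5
        tru = set(range(5)) | set(range(100, 105))  # FN=5
        assert f1_selection(sel, tru) == pytest.approx(0.5)

    def test_disjoint_sets(self):
        assert f1_selection({"a"}, {"b"}) == 0.0

    def test_both_empty_convention(self):
        assert f1_selection(set(), set()) == 1.0


class TestLisi:
    def test_fully_mixed_binary_labels(self):
        rng = np.random.default_rng(0)
        pcs = rng.normal(size=(1000, 5))
        labels = rng.integers(0, 2, 1000)
        per_cell, scaled = lisi(pcs, labels, perplexity=30)
        assert per_cell.mean() == pytest.approx(2.0, abs=0.1)
        assert scaled == pytest.approx(1.0, abs=0.05)

    def test_separated_blobs(self):
        rng = np.random.default_rng(1)
        pcs = np.vstack([rng.normal(size=(300, 4)),
                         rng.normal(size=(300, 4)) + 50.0])
        labels = np.array([0] * 300 + [1] * 300)
        per_cell, scaled = lisi(pcs, labels, perplexity=30)
        assert per_cell.mean() == pytest.approx(1.0, abs=0.05)
        assert scaled == pytest.approx(0.0, abs=0.05)

    def test_permuted_labels_scale_to_one(self):
        rng = np.random.default_rng(2)
        pcs = np.vstack([rng.normal(size=(500, 3)),
                         rng.normal(size=(500, 3)) + 8.0])
        labels = rng.permutation([0] * 500 + [1] * 500)
        _, scaled = lisi(pcs, labels, perplexity=30)
        assert scaled == pytest.approx(1.0, abs=0.05)

    def test_preconditions(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            lisi(rng.normal(size=(50, 2)), np.zeros(50))  # one category
        with pytest.raises(ValueError):
            lisi(rng.normal(size=(50, 2)), rng.integers(0, 2, 50),
                 perplexity=30)  # too few cells


class TestPveEval:
    def _dataset(self, y, groups, clusters):
        samples = [f"{g}_r0" for g in groups]  # one sample per group level
        ds = make_dataset(np.zeros_like(y, dtype=int), samples, list(groups))
        ds.norm = np.asarray(y, float)
        return ds

    def test_cluster_driven_expression(self):
        rng = np.random.default_rng(0)
        n = 600
        clusters = np.repeat([0, 1, 2], n // 3)
        groups = np.tile(["g0", "g1"], n // 2)
        y = 3.0 * clusters[None, :] + rng.normal(scale=0.5, size=(5, n))
        ds = self._dataset(y, groups, clusters)
        pve_k, pve_g = pve_eval(ds, clusters, groups)
        assert pve_k == pytest.approx(1.0, abs=0.05)
        assert pve_g == pytest.approx(0.0, abs=0.05)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        n = 300
        clusters = np.repeat([0, 1, 2], n // 3)
        groups = np.tile(["g0", "g1"], n // 2)
        y = (2.0 * clusters + (groups == "g1") * 1.5
             + rng.normal(size=(8, n)))
        ds = self._dataset(y, groups, clusters)
        pk, pg = pve_eval(ds, clusters, groups)
        pk2, pg2 = pve_eval(ds, groups, clusters)  # swapped roles
        assert pk == pytest.approx(pg2, abs=1e-9)
        assert pg == pytest.approx(pk2, abs=1e-9)

    def test_per_gene_shares_sum_to_one(self):
        rng = np.random.default_rng(2)
        n = 240
        clusters = np.repeat([0, 1], n // 2)
        groups = np.tile(["g0", "g1"], n // 2)
        y = clusters[None, :] * rng.normal(1, 0.2, size=(6, 1)) + rng.normal(
            size=(6, n)
        )
        ds = self._dataset(y, groups, clusters)
        pk, pg = pve_eval(ds, clusters, groups)
        assert pk + pg == pytest.approx(1.0, abs=1e-9)


class TestPcr:
    def _emb(self, pcs, ev):
        return Embedding(pcs=np.asarray(pcs, float),
                         explained_var=np.asarray(ev, float),
                         features_used=pd.Index(["f"]))

    def test_label_determined_component(self):
        labels = np.repeat([0, 1], 50)
        pc1 = labels * 2.0 - 1.0
        emb = self._emb(np.column_stack([pc1, np.zeros(100)]), [5.0, 0.0])
        assert pcr(emb, labels) == pytest.approx(1.0)

    def test_independent_labels_near_null_value(self):
        rng = np.random.default_rng(0)
        n, C = 2000, 2
        pcs = rng.normal(size=(n, 5))
        labels = rng.integers(0, C, n)
        val = pcr(self._emb(pcs, np.ones(5)), labels)
        assert val == pytest.approx((C - 1) / (n - 1), abs=0.005)

    def test_matches_regression_oracle(self):
        from sklearn.linear_model import LinearRegression

        rng = np.random.default_rng(1)
        n = 100
        labels = rng.integers(0, 3, n)
        pcs = rng.normal(size=(n, 4)) + labels[:, None] * rng.normal(size=4)
        ev = np.array([4.0, 3.0, 2.0, 1.0])
        onehot = pd.get_dummies(labels).to_numpy(dtype=float)
        r2 = np.array([
            LinearRegression().fit(onehot, pcs[:, j]).score(onehot, pcs[:, j])
            for j in range(4)
        ])
        oracle = float((ev * r2).sum() / ev.sum())
        assert pcr(self._emb(pcs, ev), labels) == pytest.approx(oracle, abs=1e-10)

    def test_single_category_convention(self):
        rng = np.random.default_rng(2)
        emb = self._emb(rng.normal(size=(50, 3)), np.ones(3))
        assert pcr(emb, np.zeros(50)) == 0.0


class TestScoreTruthCorrelation:
    def _truth(self, typeness, stateness):
        genes = pd.Index([f"g{i}" for i in range(len(typeness))], name="gene_id")
        return SimTruth(
            gene_ids=genes,
            cluster_fc=np.ones((len(typeness), 3)),
            state_fc=np.ones((len(typeness), 3, 2)),
            true_typeness=np.asarray(typeness, float),
            true_stateness=np.asarray(stateness, float),
        )

    def test_perfect_and_null_scores(self):
        rng = np.random.default_rng(0)
        ty = rng.random(2000)
        st = rng.random(2000)
        truth = self._truth(ty, st)
        scores = pd.DataFrame(
            {"perfect": ty, "noise": rng.random(2000)}, index=truth.gene_ids
        )
        corr = score_truth_correlation(scores, truth)
        assert corr.shape == (2, 2)
        assert corr.loc["perfect", "true_typeness"] == pytest.approx(1.0)
        assert abs(corr.loc["noise", "true_typeness"]) < 0.1
        assert abs(corr.loc["noise", "true_stateness"]) < 0.1

    def test_constant_score_recorded_as_zero(self):
        truth = self._truth(np.arange(10.0), np.arange(10.0))
        scores = pd.DataFrame({"flat": np.ones(10)}, index=truth.gene_ids)
        corr = score_truth_correlation(scores, truth)
        assert corr.loc["flat", "true_typeness"] == 0.0
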