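"""DEG filtering, preferential-expression calls, k-means clustering, Venn."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chromtrans import (
    call_deg,
    cluster_by_marks,
    integrate_marks_expression,
    preferential_expression,
    quantile_normalize,
)
from chromtrans.marks import DifferentialMarkResult


class TestCallDeg:
    def test_fold_change_above_threshold(self):
        a = pd.Series({"g": 10.0})
        b = pd.Series({"g": 4.0})
        da, db = call_deg(a, b, fold=2.0, pseudocount=0.0)
        assert da == {"g"} and db == set()

    def test_exactly_twofold_excluded_by_strict_inequality(self):
        a = pd.Series({"g": 8.0})
        b = pd.Series({"g": 4.0})
        da, db = call_deg(a, b, fold=2.0, pseudocount=0.0)
        assert da == set() and db == set()

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.lognormal(2, 1, 100), index=[f"g{i}" for i in range(100)])
        b = pd.Series(rng.lognormal(2, 1, 100), index=a.index)
        da, db = call_deg(a, b)
        db2, da2 = call_deg(b, a)
        assert da == da2 and db == db2

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            call_deg(pd.Series({"g": -1.0}), pd.Series({"g": 1.0}))

    def test_planted_fourfold_recovered_exactly(self, sim_noiseless, pipeline_noiseless):
        _, truth = sim_noiseless
        *_, results = pipeline_noiseless
        da, db = results["deg"]
        ta, tb = truth.deg_sets()
        assert da == ta and db == tb


class TestPreferential:
    def _panel(self, values, target_val, n_target=1):
        """One gene; non-target samples take ``values``."""
        cols = [f"t{i}" for i in range(len(values))] + [f"c{i}" for i in range(n_target)]
        data = list(values) + [target_val] * n_target
        m = pd.DataFrame([data], index=["g"], columns=cols)
        tissues = pd.Series(
            ["other"] * len(values) + ["callus"] * n_target, index=cols
        )
        return m, tissues

    def test_z_score_arithmetic(self):
        # others {1,2,3}: mean 2, sd 1 (ddof=1); target 5 -> Z = 3
        m, t = self._panel([1.0, 2.0, 3.0], 5.0)
        calls = preferential_expression(m, t, "callus", normalize=False)
        assert calls.loc["g", "z"] == pytest.approx(3.0)

    def test_target_at_mean_not_preferential(self):
        m, t = self._panel([1.0, 2.0, 3.0], 2.0)
        calls = preferential_expression(m, t, "callus", normalize=False)
        assert calls.loc["g", "z"] == pytest.approx(0.0)
        assert not calls.loc["g", "preferential"]

    def test_constant_others_degenerate_handling(self):
        m, t = self._panel([2.0, 2.0, 2.0], 7.0)
        calls = preferential_expression(m, t, "callus", normalize=False)
        assert calls.loc["g", "degenerate"]
        assert calls.loc["g", "preferential"]
        m2, t2 = self._panel([2.0, 2.0, 2.0], 2.0)
        calls2 = preferential_expression(m2, t2, "callus", normalize=False)
        assert not calls2.loc["g", "preferential"]

    def test_fewer_than_three_others_rejected(self):
        m, t = self._panel([1.0, 2.0], 5.0)
        with pytest.raises(ValueError, match="3 non-target"):
            preferential_expression(m, t, "callus")

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(8)
        cols = [f"s{i}" for i in range(10)]
        m = pd.DataFrame(rng.lognormal(1, 0.5, (20, 10)),
                         index=[f"g{i}" for i in range(20)], columns=cols)
        t = pd.Series(["callus"] * 2 + ["other"] * 8, index=cols)
        perm = list(rng.permutation(cols))
        a = preferential_expression(m, t, "callus")
        b = preferential_expression(m[perm], t[perm], "callus")
        pd.testing.assert_frame_equal(a, b)

    def test_constant_shift_invariance_normalization_off(self):
        rng = np.random.default_rng(12)
        cols = [f"s{i}" for i in range(8)]
        m = pd.DataFrame(rng.lognormal(1, 0.5, (15, 8)),
                         index=[f"g{i}" for i in range(15)], columns=cols)
        t = pd.Series(["callus"] * 2 + ["other"] * 6, index=cols)
        a = preferential_expression(m, t, "callus", normalize=False)
        b = preferential_expression(m + 10.0, t, "callus", normalize=False)
        pd.testing.assert_series_equal(a["z"], b["z"])

    def test_planted_panel_recovery(self, sim_noisy, pipeline_noisy):
        """150 planted +4 sd callus genes: recall and precision >= 0.95."""
        _, truth = sim_noisy
        *_, results = pipeline_noisy
        calls = results["preferential"]
        pred = set(calls.index[calls["preferential"]])
        planted = truth.preferential_set()
        recall = len(pred & planted) / len(planted)
        precision = len(pred & planted) / len(pred)
        assert recall >= 0.95 and precision >= 0.95

    def test_quantile_normalize_equalizes_distributions(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.lognormal(0, 1, (50, 4)), columns=list("abcd"))
        qn = quantile_normalize(m)
        ref = np.sort(qn["a"].values)
        for c in "bcd":
            assert np.allclose(np.sort(qn[c].values), ref)


class TestClustering:
    def _matrix(self, labels, rng):
        """Rows drawn from two planted archetypes: flat zero vs. block signal."""
        rows = []
        for lab in labels:
            base = np.zeros(30)
            if lab == 1:
                base[5:20] = 50.0
            rows.append(base + rng.normal(0, 0.5, 30).clip(min=0))
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(labels))])

    def test_two_archetypes_perfectly_separated(self):
        rng = np.random.default_rng(21)
        labels = [i % 2 for i in range(80)]
        m = self._matrix(labels, rng)
        res = cluster_by_marks([m], k=2, seed=5)
        assert adjusted_rand_score(labels, res.labels.values) == 1.0

    def test_k_one_single_cluster(self):
        rng = np.random.default_rng(21)
        m = self._matrix([0, 1, 0, 1], rng)
        res = cluster_by_marks([m], k=1, seed=5)
        assert set(res.labels) == {1}

    def test_duplicated_rows_double_cluster_sizes(self):
        rng = np.random.default_rng(21)
        labels = [i % 2 for i in range(40)]
        m = self._matrix(labels, rng)
        dup = pd.concat([m, m.set_axis([f"d{i}" for i in range(len(m))])])
        r1 = cluster_by_marks([m], k=2, seed=5)
        r2 = cluster_by_marks([dup], k=2, seed=5)
        s1 = sorted(r1.labels.value_counts().values)
        s2 = sorted(r2.labels.value_counts().values)
        assert [2 * x for x in s1] == list(s2)

    def test_k_exceeding_genes_rejected(self):
        rng = np.random.default_rng(21)
        m = self._matrix([0, 1], rng)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_by_marks([m], k=3, seed=5)

    def test_mismatched_gene_sets_rejected(self):
        rng = np.random.default_rng(21)
        m1 = self._matrix([0, 1, 0], rng)
        m2 = m1.set_axis(["x", "y", "z"])
        with pytest.raises(ValueError, match="share"):
            cluster_by_marks([m1, m2], k=2, seed=5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(21)
        m = self._matrix([i % 2 for i in range(30)], rng)
        a = cluster_by_marks([m], k=2, seed=9)
        b = cluster_by_marks([m], k=2, seed=9)
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestVenn:
    def _res(self, a, b):
        return DifferentialMarkResult(
            "H3K27me3", "callus", "seedling", set(a), set(b)
        )

    def test_disjoint_inputs_all_zero(self):
        counts, _ = integrate_marks_expression(
            self._res({"a"}, {"b"}), {"c"}, {"d"}
        )
        assert (counts.values == 0).all()

    def test_containment_fills_one_cell(self):
        deg_a = {"x", "y"}
        counts, lists = integrate_marks_expression(
            self._res({"m"}, deg_a | {"z"}), deg_a, set()
        )
        assert counts.loc["seedling", "callus"] == 2
        assert lists["mark_seedling__expr_callus"] == deg_a

    def test_cells_partition_each_direction(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(200)]
        mark_a = set(rng.choice(genes, 60, replace=False))
        mark_b = set(rng.choice(sorted(set(genes) - mark_a), 50, replace=False))
        deg_a = set(rng.choice(genes, 70, replace=False))
        deg_b = set(rng.choice(sorted(set(genes) - deg_a), 40, replace=False))
        counts, lists = integrate_marks_expression(self._res(mark_a, mark_b), deg_a, deg_b)
        assert counts.loc["callus"].sum() == len(mark_a & (deg_a | deg_b))
        assert counts.loc["seedling"].sum() == len(mark_b & (deg_a | deg_b))
        assert sum(len(v) for v in lists.values()) == counts.values.sum()

    def test_planted_anticorrelation_dominates_cross_cells(self, pipeline_noiseless):
        """H3K27me3 is repressive: genes losing it in callus are enriched for
        callus-higher expression, so cross cells beat same-direction cells."""
        *_, results = pipeline_noiseless
        venn = results["venn"]
        assert venn.loc["seedling", "callus"] > venn.loc["seedling", "seedling"]
        assert venn.loc["callus", "seedling"] > venn.loc["callus", "callus"]
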