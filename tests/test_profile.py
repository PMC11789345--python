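"""Clustering, sigup discovery, naming grammar and proportion tables."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import fiberfa as ff


def planted_blobs(n_per=100, p=20, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per, p))
    b = rng.normal(0.0, 1.0, (n_per, p))
    b[:, :5] += sep
    X = np.vstack([a, b])
    truth = np.repeat([0, 1], n_per)
    return X, truth


class TestClustering:
    def test_two_blobs_recovered_exactly(self):
        X, truth = planted_blobs()
        labels = ff.cluster_subpopulation(X, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_given_seed(self):
        X, _ = planted_blobs(seed=3)
        l1 = ff.cluster_subpopulation(X, seed=5)
        l2 = ff.cluster_subpopulation(X, seed=5)
        assert np.array_equal(l1, l2)

    def test_neighbors_clamped_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (5, 4))
        with caplog.at_level("WARNING"):
            labels = ff.cluster_subpopulation(X, n_neighbors=15, seed=0)
        assert "clamped" in caplog.text
        assert len(labels) == 5

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            ff.cluster_subpopulation(np.zeros((2, 3)))


class TestSigups:
    def test_planted_gene_flagged_in_its_cluster(self):
        rng = np.random.default_rng(1)
        n = 200
        X = rng.normal(5.0, 1.0, (2 * n, 30))
        X[:n, 0] += 2.0  # 4-fold on the log2 scale
        expr = pd.DataFrame(X, columns=[f"g{j}" for j in range(30)])
        labels = np.repeat([0, 1], n)
        sig = ff.find_sigups(expr, labels, alpha=0.05, min_lfc=1.0)
        hits = sig[(sig.cluster == 0) & (sig.gene == "g0")]
        assert len(hits) == 1
        assert hits["lfc"].iloc[0] == pytest.approx(2.0, abs=0.3)
        assert not ((sig.cluster == 1) & (sig.gene == "g0")).any()

    def test_infinite_lfc_floor_empties_sigups(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(0, 1, (100, 10)))
        labels = np.repeat([0, 1], 50)
        sig = ff.find_sigups(expr, labels, min_lfc=np.inf)
        assert sig.empty

    def test_single_cluster_rejected(self):
        expr = pd.DataFrame(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            ff.find_sigups(expr, np.zeros(10, dtype=int))

    def test_permutation_null_calibrated(self):
        # mean flagged fraction under label permutation stays below alpha
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(0, 1, (120, 40)))
        alpha = 0.05
        fracs = []
        for _ in range(200):
            labels = rng.permutation(np.repeat([0, 1], 60))
            sig = ff.find_sigups(expr, labels, alpha=alpha, min_lfc=0.0)
            fracs.append(len(sig) / (2 * 40))
        assert np.mean(fracs) <= alpha + 0.01


class TestNaming:
    def sig(self, rows):
        return pd.DataFrame(rows, columns=["cluster", "gene", "lfc", "p_adj"])

    def names(self, annotations):
        return {a.cluster: a.name for a in annotations}

    def test_unique_sigup_plain_name(self):
        ann = ff.name_clusters(self.sig([(0, "Myh4", 2.0, 1e-5)]),
                               sizes={0: 50, 1: 10})
        assert self.names(ann) == {0: "Myh4+", 1: "Unknown"}

    def test_shared_sigups_indexed_by_descending_size(self):
        rows = [(0, "Ckm", 2.0, 1e-4), (1, "Ckm", 1.5, 1e-3)]
        ann = ff.name_clusters(self.sig(rows), sizes={0: 10, 1: 90})
        assert self.names(ann) == {1: "Ckm+(1)", 0: "Ckm+(2)"}

    def test_multiple_unknowns_indexed(self):
        ann = ff.name_clusters(self.sig([]), sizes={0: 5, 1: 20, 2: 10})
        assert self.names(ann) == {1: "Unknown(1)", 2: "Unknown(2)",
                                   0: "Unknown(3)"}

    def test_largest_fold_change_gene_names_the_cluster(self):
        rows = [(0, "Pygm", 1.2, 1e-3), (0, "Ttn", 3.0, 1e-6)]
        ann = ff.name_clusters(self.sig(rows), sizes={0: 30, 1: 10})
        assert self.names(ann)[0] == "Ttn+"

    def test_pure_function_deterministic(self):
        rows = [(0, "Ckm", 2.0, 1e-4), (1, "Ckm", 2.0, 1e-4)]
        a1 = ff.name_clusters(self.sig(rows), sizes={0: 10, 1: 10})
        a2 = ff.name_clusters(self.sig(rows), sizes={0: 10, 1: 10})
        assert a1 == a2


class TestProportions:
    def test_toy_arithmetic(self):
        labels = ["x", "x", "y", "y", "y", "y"]
        conds = ["A", "A", "A", "B", "B", "B"]
        tab = ff.condition_proportions(labels, conds)
        assert tab.fractions.loc["A", "x"] == pytest.approx(2 / 3)
        assert tab.fractions.loc["A", "y"] == pytest.approx(1 / 3)
        assert tab.fractions.loc["B", "x"] == 0.0
        assert tab.fractions.loc["B", "y"] == 1.0
        assert tab.counts.loc["A"].sum() == 3

    def test_rows_sum_to_one(self, default_run):
        fr = default_run.class_proportions.fractions
        np.testing.assert_allclose(fr.sum(axis=1), 1.0, atol=1e-12)

    def test_single_cluster_rows_are_unity(self):
        tab = ff.condition_proportions(["k"] * 4, ["A", "A", "B", "B"])
        assert (tab.fractions == 1.0).all().all()

    def test_combine_all_names_gives_one(self, default_run):
        tab = default_run.class_proportions
        combined = ff.combine_clusters(tab, list(tab.fractions.columns))
        np.testing.assert_allclose(combined, 1.0, atol=1e-12)

    def test_combine_empty_set_gives_zero(self, default_run):
        combined = ff.combine_clusters(default_run.class_proportions, [])
        assert (combined == 0.0).all()

    def test_combine_additive_over_disjoint_sets(self, default_run):
        tab = default_run.class_proportions
        names = list(tab.fractions.columns)
        left = ff.combine_clusters(tab, names[:2])
        right = ff.combine_clusters(tab, names[2:])
        np.testing.assert_allclose(left + right, 1.0, atol=1e-12)

    def test_unknown_name_rejected(self, default_run):
        with pytest.raises(KeyError):
            ff.combine_clusters(default_run.class_proportions, ["nope"])


class TestMarkerComparison:
    def test_null_markers_not_significant_on_default_run(self, default_run):
        cmp = default_run.marker_comparison
        assert set(cmp["gene"]) == {"Fbxo32", "Trim63"}
        # no condition effect is planted on the atrophy markers
        assert not cmp["significant"].any()

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(0)
        n = 200
        expr = pd.DataFrame({
            "Fbxo32": np.concatenate([rng.normal(4, 1, n),
                                      rng.normal(5, 1, n)]),
            "other": rng.normal(4, 1, 2 * n),
        })
        conds = ["Ctrl"] * n + ["P"] * n
        cmp = ff.compare_marker_expression(expr, ["Fbxo32"], conds)
        assert cmp["significant"].all()

    def test_absent_gene_named(self, default_run):
        expr = default_run.expr.to_frame()
        with pytest.raises(KeyError, match="Nope1"):
            ff.compare_marker_expression(expr, ["Nope1"],
                                         default_run.expr.condition)


class TestEndToEnd:
    def test_depletion_direction_recovered(self, default_run):
        combined = default_run.combined
        assert combined["P_PG"] < combined["Ctrl"]

    def test_cluster_tables_consistent(self, default_run):
        for sub, d in default_run.subpop.items():
            sizes = {a.cluster: a.size for a in d["annotations"]}
            assert sum(sizes.values()) == len(d["cells"])
            names = [a.name for a in d["annotations"]]
            assert len(set(names)) == len(names)
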