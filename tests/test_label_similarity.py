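"""Selection frequencies, similarity matrices, residualization, WPGMA."""

import numpy as np
import pandas as pd
import pytest

from autoannot.label_similarity import (
    cluster_labels,
    cut_clusters,
    dice_matrix,
    residualize,
    selection_frequency,
    selection_table,
    spearman_matrix,
    to_newick,
    wordcloud_export,
)
from oracles import dice_oracle, ols_residual_oracle, spearman_oracle, wpgma_oracle


class TestSelectionFrequency:
    def test_always_selected(self):
        sel = {("L", it, f): ["a", "b"] for it in range(5) for f in range(2)}
        freq = selection_frequency(sel, "L")
        assert freq["a"] == 1.0 and freq["b"] == 1.0

    def test_half_selected(self):
        sel = {("L", it, 0): (["a"] if it < 5 else ["b"]) for it in range(10)}
        freq = selection_frequency(sel, "L")
        assert freq["a"] == 0.5 and freq["b"] == 0.5

    def test_hand_fixture(self):
        sel = {
            ("L", 0, 0): ["x", "y"],
            ("L", 0, 1): ["x"],
            ("L", 1, 0): ["y", "z"],
        }
        freq = selection_frequency(sel, "L")
        assert freq["x"] == pytest.approx(2 / 3)
        assert freq["y"] == pytest.approx(2 / 3)
        assert freq["z"] == pytest.approx(1 / 3)

    def test_alignment_fills_zeros(self):
        sel = {("A", 0, 0): ["x"], ("B", 0, 0): ["y"]}
        table = selection_table(sel)
        assert table.loc["A", "y"] == 0.0
        assert table.loc["B", "x"] == 0.0


class TestSpearman:
    def test_identical_distributions(self):
        d = pd.DataFrame([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9]], index=["A", "B"])
        rho = spearman_matrix(d)
        assert rho.loc["A", "B"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        d = pd.DataFrame([[0.1, 0.5, 0.9], [0.9, 0.5, 0.1]], index=["A", "B"])
        assert spearman_matrix(d).loc["A", "B"] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            k, f = int(rng.integers(2, 6)), int(rng.integers(3, 12))
            X = np.round(rng.random((k, f)), 1)  # rounding induces ties
            d = pd.DataFrame(X, index=[f"L{i}" for i in range(k)])
            rho = spearman_matrix(d)
            for i in range(k):
                for j in range(i + 1, k):
                    expected = spearman_oracle(X[i], X[j])
                    assert rho.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame(rng.random((4, 9)), index=list("ABCD"))
        rho = spearman_matrix(d)
        np.testing.assert_allclose(rho.values, rho.values.T)
        np.testing.assert_allclose(np.diag(rho.values), 1.0)


class TestDice:
    def test_hand_half(self):
        m = pd.DataFrame(
            {"D:X": [1, 1, 0], "D:Y": [0, 1, 1]}, index=["1", "2", "3"]
        )
        assert dice_matrix(m).loc["D:X", "D:Y"] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        m = pd.DataFrame(
            {"D:A": [1, 1, 0], "D:B": [1, 1, 0], "D:C": [0, 0, 1]},
            index=["1", "2", "3"],
        )
        d = dice_matrix(m)
        assert d.loc["D:A", "D:B"] == pytest.approx(1.0)
        assert d.loc["D:A", "D:C"] == pytest.approx(0.0)

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(15, 5)),
            columns=[f"D:L{j}" for j in range(5)],
            index=[f"d{i}" for i in range(15)],
        )
        d = dice_matrix(m)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = dice_oracle(m.iloc[:, i], m.iloc[:, j])
                assert d.iloc[i, j] == pytest.approx(expected)


class TestResidualize:
    def _frames(self, rho, dice, labels):
        return (pd.DataFrame(rho, index=labels, columns=labels),
                pd.DataFrame(dice, index=labels, columns=labels))

    def test_constant_dice_centers_rho(self):
        labels = list("ABC")
        rho = np.array([[1, 0.2, 0.4], [0.2, 1, 0.6], [0.4, 0.6, 1]])
        dice = np.full((3, 3), 0.5)
        r, d = self._frames(rho, dice, labels)
        resid = residualize(r, d)
        off = np.array([0.2, 0.4, 0.6])
        expected = off - off.mean()
        assert resid.loc["A", "B"] == pytest.approx(expected[0])
        assert resid.loc["B", "C"] == pytest.approx(expected[2])

    def test_perfect_linear_fit_zero_residuals(self):
        labels = list("ABCD")
        rng = np.random.default_rng(4)
        dice = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        dvals = rng.random(len(iu[0]))
        dice[iu] = dvals
        dice = dice + dice.T
        rho = 0.3 + 0.5 * dice
        np.fill_diagonal(rho, 1.0)
        np.fill_diagonal(dice, 1.0)
        r, d = self._frames(rho, dice, labels)
        resid = residualize(r, d)
        off = resid.values[iu]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        labels = list("ABCD")
        rng = np.random.default_rng(5)
        k = 4
        iu = np.triu_indices(k, 1)
        rho = np.eye(k)
        dice = np.eye(k)
        rho_vals = rng.random(len(iu[0]))
        dice_vals = rng.random(len(iu[0]))
        rho[iu] = rho_vals
        dice[iu] = dice_vals
        rho, dice = rho + rho.T - np.eye(k), dice + dice.T - np.eye(k)
        r, d = self._frames(rho, dice, labels)
        resid = residualize(r, d)
        expected = ols_residual_oracle(list(dice_vals), list(rho_vals))
        np.testing.assert_allclose(resid.values[iu], expected, atol=1e-10)

    def test_residuals_uncorrelated_with_dice(self):
        rng = np.random.default_rng(6)
        k = 6
        labels = [f"L{i}" for i in range(k)]
        iu = np.triu_indices(k, 1)
        rho = np.eye(k); dice = np.eye(k)
        rho[iu] = rng.random(len(iu[0])); dice[iu] = rng.random(len(iu[0]))
        rho, dice = rho + rho.T - np.eye(k), dice + dice.T - np.eye(k)
        resid = residualize(*self._frames(rho, dice, labels))
        corr = np.corrcoef(resid.values[iu], dice[iu])[0, 1]
        assert abs(corr) < 1e-10

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        k = 5
        labels = [f"L{i}" for i in range(k)]
        iu = np.triu_indices(k, 1)
        rho = np.eye(k); dice = np.eye(k)
        rho[iu] = rng.random(len(iu[0])); dice[iu] = rng.random(len(iu[0]))
        rho, dice = rho + rho.T - np.eye(k), dice + dice.T - np.eye(k)
        resid = residualize(*self._frames(rho, dice, labels))
        np.testing.assert_allclose(resid.values, resid.values.T)


class TestClustering:
    def test_identical_labels_merge_first_at_zero(self):
        labels = ["A", "B", "C"]
        sim = pd.DataFrame(
            [[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]],
            index=labels, columns=labels,
        )
        tree = cluster_labels(sim)
        first = tree.linkage[0]
        assert first[2] == pytest.approx(0.0)
        merged = {tree.labels[int(first[0])], tree.labels[int(first[1])]}
        assert merged == {"A", "B"}

    def test_three_point_hand_trace(self):
        labels = ["A", "B", "C"]
        # distances: AB = 0.1, AC = 0.8, BC = 0.6
        sim = pd.DataFrame(
            [[1.0, 0.9, 0.2], [0.9, 1.0, 0.4], [0.2, 0.4, 1.0]],
            index=labels, columns=labels,
        )
        tree = cluster_labels(sim)
        # first merge A,B at 0.1; then C joins at mean(0.8, 0.6) = 0.7
        assert tree.linkage[0][2] == pytest.approx(0.1)
        assert tree.linkage[1][2] == pytest.approx(0.7)

    def test_matches_wpgma_oracle_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k = int(rng.integers(3, 8))
            labels = [f"L{i}" for i in range(k)]
            d = np.zeros((k, k))
            iu = np.triu_indices(k, 1)
            d[iu] = np.round(rng.random(len(iu[0])), 6)  # distinct w.h.p.
            d = d + d.T
            sim = pd.DataFrame(1.0 - d, index=labels, columns=labels)
            np.fill_diagonal(sim.values, 1.0)
            tree = cluster_labels(sim)
            merges = wpgma_oracle(d, labels)
            heights = sorted(h for _, _, h in merges)
            np.testing.assert_allclose(sorted(tree.linkage[:, 2]), heights,
                                       atol=1e-10)

    def test_single_label_tree(self):
        sim = pd.DataFrame([[1.0]], index=["A"], columns=["A"])
        tree = cluster_labels(sim)
        assert tree.labels == ["A"]
        assert to_newick(tree) == "A;"

    def test_planted_two_groups_recovered(self):
        labels = [f"G1_{i}" for i in range(3)] + [f"G2_{i}" for i in range(3)]
        k = len(labels)
        sim = np.full((k, k), 0.1)
        for i in range(k):
            for j in range(k):
                if (i < 3) == (j < 3):
                    sim[i, j] = 0.9
        np.fill_diagonal(sim, 1.0)
        tree = cluster_labels(pd.DataFrame(sim, index=labels, columns=labels))
        clusters = cut_clusters(tree, 2)
        g1 = {clusters[l] for l in labels[:3]}
        g2 = {clusters[l] for l in labels[3:]}
        assert len(g1) == 1 and len(g2) == 1 and g1 != g2

    def test_newick_parses_with_dendropy(self):
        import dendropy

        labels = list("ABCD")
        rng = np.random.default_rng(9)
        d = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        d[iu] = rng.random(6)
        d = d + d.T
        tree = cluster_labels(pd.DataFrame(1 - d, index=labels, columns=labels))
        t = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == set(labels)


class TestWordcloud:
    def test_ten_features_exports_one(self):
        sel = {("L", 0, 0): [f"f{i}" for i in range(10)]}
        cloud = wordcloud_export(["L"], sel)
        assert len(cloud) == 1

    def test_uniform_weights_lexicographic(self):
        sel = {("L", 0, 0): [f"f{i:02d}" for i in range(20)]}
        cloud = wordcloud_export(["L"], sel)
        assert list(cloud.index) == ["f00", "f01"]

    def test_hand_means_across_labels(self):
        feats_a = [f"f{i:02d}" for i in range(20)]
        sel = {
            ("A", 0, 0): feats_a,
            ("A", 1, 0): feats_a[:10],
            ("B", 0, 0): feats_a[:5],
        }
        cloud = wordcloud_export(["A", "B"], sel)
        # f00..f04: mean(1.0, 1.0) = 1.0 across labels A (1.0) and B (1.0)
        assert cloud.iloc[0] == pytest.approx(1.0)
        assert len(cloud) == 2  # ceil(0.1 * 20)
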