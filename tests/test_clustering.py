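"""Group construction and naming, sqrt-Jaccard distances, leaf ordering, export."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phresp.clustering import (
    EnrichmentGroup,
    build_groups,
    export_heatmap,
    group_label,
    jaccard_sqrt_distance,
    order_groups,
)


def _group(label_parts, members):
    strain, contrast, direction = label_parts
    return EnrichmentGroup(strain=strain, contrast=contrast, direction=direction,
                           members=frozenset(members))


class TestNaming:
    def test_published_label_scheme(self):
        assert group_label("NPAL-12", ("7.0", "8.2"), "En") == "NPAL-12_7En8"
        assert group_label("NPAL-12", ("4.7", "8.2"), "Dp") == "NPAL-12_4Dp8"
        assert group_label("EUNS-26", ("4.7", "7.0"), "En") == "EUNS-26_4En7"

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            group_label("X", ("4.7", "7.0"), "Up")


class TestBuildGroups:
    def _composite(self, rows):
        return pd.DataFrame(rows, columns=["set_id", "enriched", "depleted"])

    def test_split_by_direction_and_both(self):
        comp = self._composite([
            ("A", True, False), ("B", False, True), ("C", True, True), ("D", False, False),
        ])
        en, dp = build_groups(comp, "NPAL-12", ("7.0", "8.2"))
        assert en.label == "NPAL-12_7En8"
        assert en.members == {"A", "C"}
        assert dp.members == {"B", "C"}

    def test_empty_groups_retained(self):
        comp = self._composite([("A", False, False)])
        en, dp = build_groups(comp, "S01", ("4.7", "8.2"))
        assert en.members == frozenset() and dp.members == frozenset()


class TestJaccardSqrt:
    def test_identical_disjoint_and_partial(self):
        groups = {
            "g1": {"x", "y"}, "g2": {"x", "y"}, "g3": {"a", "b"}, "g4": {"y", "z"},
        }
        d = jaccard_sqrt_distance(groups)
        assert d.loc["g1", "g2"] == 0.0
        assert d.loc["g1", "g3"] == 1.0
        assert d.loc["g1", "g4"] == pytest.approx(math.sqrt(1 - 1 / 3))
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_empty_group_conventions(self):
        d = jaccard_sqrt_distance({"e1": set(), "e2": set(), "full": {"a"}})
        assert d.loc["e1", "e2"] == 0.0
        assert d.loc["e1", "full"] == 1.0

    def test_matches_formula_on_exhaustive_small_pairs(self):
        universe = ["a", "b", "c", "d"]
        subsets = [frozenset(c) for r in range(5) for c in itertools.combinations(universe, r)]
        groups = {f"s{i}": s for i, s in enumerate(subsets)}
        d = jaccard_sqrt_distance(groups)
        for i, a_set in enumerate(subsets):
            for j, b_set in enumerate(subsets):
                if i == j:
                    continue
                a = len(a_set & b_set)
                b = len(a_set - b_set)
                c = len(b_set - a_set)
                expected = 0.0 if a + b + c == 0 else math.sqrt(1 - a / (a + b + c))
                assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(14)
        universe = np.arange(20)
        for _ in range(500):
            sets = {
                f"t{i}": frozenset(rng.choice(universe, size=rng.integers(1, 10),
                                              replace=False))
                for i in range(3)
            }
            d = jaccard_sqrt_distance(sets).to_numpy()
            for i, j, k in itertools.permutations(range(3), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_distance_ignores_absent_set_ids(self):
        base = {"g1": {"a", "b"}, "g2": {"b", "c"}}
        d1 = jaccard_sqrt_distance(base)
        d2 = jaccard_sqrt_distance({k: v | set() for k, v in base.items()})
        assert np.allclose(d1.values, d2.values)


class TestOrdering:
    def test_identical_pair_are_adjacent_leaves(self):
        groups = {"a1": {"x", "y"}, "a2": {"x", "y"}, "far": {"q", "r"}}
        matrix = jaccard_sqrt_distance(groups)
        order, _ = order_groups(matrix)
        i, j = order.index("a1"), order.index("a2")
        assert abs(i - j) == 1

    def test_three_group_merge_matches_minimum_distance_scan(self):
        groups = {"a": {"x", "y", "z"}, "b": {"x", "y", "w"}, "c": {"p", "q"}}
        matrix = jaccard_sqrt_distance(groups)
        _, link = order_groups(matrix)
        # brute force: the closest pair merges first
        labels = sorted(groups)
        best = min(
            ((i, j) for i in range(3) for j in range(i + 1, 3)),
            key=lambda ij: matrix.loc[labels[ij[0]], labels[ij[1]]],
        )
        assert set(link[0, :2].astype(int)) == set(best)

    def test_leaf_order_invariant_to_input_permutation(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": frozenset(rng.choice(30, size=8, replace=False).tolist())
                  for i in range(6)}
        matrix = jaccard_sqrt_distance(groups)
        shuffled = matrix.iloc[::-1, ::-1]
        o1, _ = order_groups(matrix)
        o2, _ = order_groups(shuffled)
        assert o1 == o2

    def test_asymmetric_matrix_rejected(self):
        bad = pd.DataFrame([[0.0, 0.5], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            order_groups(bad)


class TestExport:
    def test_tsv_round_trip_and_symmetry(self, tmp_path):
        groups = {"a": {"x"}, "b": {"x", "y"}, "c": {"z"}}
        matrix = jaccard_sqrt_distance(groups)
        order, _ = order_groups(matrix)
        out = export_heatmap(matrix, order, tmp_path / "heat", render_png=False)
        back = pd.read_csv(out["tsv"], sep="\t", index_col="group")
        assert list(back.index) == order
        assert np.allclose(back.values, back.values.T)
        assert np.allclose(back.values, matrix.loc[order, order].values)

    def test_png_written_when_requested(self, tmp_path):
        matrix = jaccard_sqrt_distance({"a": {"x"}, "b": {"y"}})
        out = export_heatmap(matrix, ["a", "b"], tmp_path / "heat", render_png=True)
        assert out["png"].exists() and out["png"].stat().st_size > 0

    def test_block_structure_visible_in_exported_matrix(self, tmp_path):
        """Two planted clusters of groups show smaller within- than between-block distances."""
        rng = np.random.default_rng(9)
        core1 = set(range(10))
        core2 = set(range(20, 30))
        groups = {}
        for i in range(3):
            groups[f"A{i}"] = frozenset(core1 | {int(rng.integers(40, 50))})
            groups[f"B{i}"] = frozenset(core2 | {int(rng.integers(50, 60))})
        matrix = jaccard_sqrt_distance(groups)
        order, _ = order_groups(matrix)
        out = export_heatmap(matrix, order, tmp_path / "blocks", render_png=False)
        back = pd.read_csv(out["tsv"], sep="\t", index_col="group")
        within = [back.loc[a, b] for a in groups for b in groups
                  if a != b and a[0] == b[0]]
        between = [back.loc[a, b] for a in groups for b in groups if a[0] != b[0]]
        assert max(within) < min(between)


def test_planted_similar_strains_cluster_together():
    """Strains sharing most affected sets end up adjacent in the leaf order."""
    rng = np.random.default_rng(4)
    shared = frozenset(f"SET{i}" for i in range(12))
    groups = {
        "S01_4En8": shared | {"SET90"},
        "S02_4En8": shared | {"SET91"},
        "S03_4En8": frozenset(f"SET{i}" for i in rng.choice(range(30, 80), 12, replace=False)),
        "S04_4En8": frozenset(f"SET{i}" for i in rng.choice(range(100, 150), 12, replace=False)),
    }
    matrix = jaccard_sqrt_distance(groups)
    order, _ = order_groups(matrix)
    assert abs(order.index("S01_4En8") - order.index("S02_4En8")) == 1
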