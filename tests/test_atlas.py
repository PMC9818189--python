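"""Pre-processing: depth normalisation, ID mapping, duplicate and tree collapsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmedeconv import (
    Atlas,
    ConfigurationError,
    DataError,
    GeneMatrix,
    TypeTree,
    collapse_duplicates,
    collapse_tree,
    map_genes,
    normalize_counts,
)


def mini_atlas(expr, labels, gene_ids=None):
    expr = np.asarray(expr, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(expr.shape[0])]
    cells = [f"c{i}" for i in range(expr.shape[1])]
    return Atlas(expr, gene_ids, cells, np.array(labels, dtype=object),
                 TypeTree.flat(sorted(set(labels))))


class TestNormalizeCounts:
    def test_hand_computed_column(self):
        at = mini_atlas([[2.0], [3.0]], ["a"])
        out = normalize_counts(at)
        np.testing.assert_allclose(out.expr[:, 0], [4000.0, 6000.0])

    def test_already_normalised_unchanged(self):
        at = mini_atlas([[4000.0], [6000.0]], ["a"])
        out = normalize_counts(at)
        np.testing.assert_allclose(out.expr, at.expr)

    def test_idempotent(self, small_atlas):
        once = normalize_counts(small_atlas)
        twice = normalize_counts(once)
        np.testing.assert_allclose(once.expr, twice.expr, rtol=1e-12)

    def test_zero_column_names_cell(self):
        at = mini_atlas([[1.0, 0.0], [1.0, 0.0]], ["a", "b"])
        with pytest.raises(DataError, match="c1"):
            normalize_counts(at)

    @given(st.integers(2, 40))
    @settings(max_examples=20, deadline=None)
    def test_column_sums_hit_target(self, n):
        rng = np.random.default_rng(n)
        at = mini_atlas(rng.random((5, n)) + 0.01, ["a"] * n)
        out = normalize_counts(at, target=10_000)
        np.testing.assert_allclose(out.expr.sum(axis=0), 10_000, rtol=1e-12)


class TestMapGenes:
    def test_rename_drop_and_count(self):
        gm = GeneMatrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                        ["ENSG1", "ENSG2", "ENSG3"], ["s1", "s2"])
        out, rep = map_genes(gm, {"ENSG1": "TP53", "ENSG3": "MYC"})
        assert out.gene_ids == ["TP53", "MYC"]
        assert (rep.n_mapped, rep.n_dropped, rep.dropped_ids) == (2, 1, ["ENSG2"])

    def test_many_to_one_defers_collapse(self):
        gm = GeneMatrix([[1.0, 5.0], [2.0, 8.0]], ["p1", "p2"], ["s1", "s2"])
        out, _ = map_genes(gm, {"p1": "A", "p2": "A"})
        assert out.gene_ids == ["A", "A"]
        collapsed = collapse_duplicates(out, "maxmean")
        assert collapsed.gene_ids == ["A"]
        np.testing.assert_array_equal(collapsed.expr, [[2.0, 8.0]])

    def test_empty_intersection_errors(self):
        gm = GeneMatrix([[1.0]], ["x"], ["s"])
        with pytest.raises(DataError, match="no overlap"):
            map_genes(gm, {"y": "Z"})


class TestCollapseDuplicates:
    def test_maxmean_keeps_largest_mean_row(self):
        gm = GeneMatrix([[1.0, 5.0], [2.0, 8.0]], ["A", "A"], ["s1", "s2"])
        out = collapse_duplicates(gm, "maxmean")
        np.testing.assert_array_equal(out.expr, [[2.0, 8.0]])  # means 3 vs 5

    def test_sum_adds_elementwise(self):
        gm = GeneMatrix([[1.0, 5.0], [2.0, 8.0]], ["A", "A"], ["s1", "s2"])
        out = collapse_duplicates(gm, "sum")
        np.testing.assert_array_equal(out.expr, [[3.0, 13.0]])

    @pytest.mark.parametrize("strategy", ["maxmean", "sum"])
    def test_no_duplicates_identity(self, strategy):
        gm = GeneMatrix([[1.0], [2.0]], ["A", "B"], ["s"])
        out = collapse_duplicates(gm, strategy)
        np.testing.assert_array_equal(out.expr, gm.expr)
        assert out.gene_ids == gm.gene_ids

    def test_unknown_strategy_lists_valid(self):
        gm = GeneMatrix([[1.0]], ["A"], ["s"])
        with pytest.raises(ConfigurationError, match="maxmean.*sum"):
            collapse_duplicates(gm, "median")

    def test_maxmean_tie_first_row_wins(self):
        gm = GeneMatrix([[1.0, 3.0], [3.0, 1.0]], ["A", "A"], ["s1", "s2"])
        out = collapse_duplicates(gm, "maxmean")
        np.testing.assert_array_equal(out.expr, [[1.0, 3.0]])

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_sum_conserves_mass_and_maxmean_rows_exist(self, seed):
        rng = np.random.default_rng(seed)
        ids = [rng.choice(["A", "B", "C"]) for _ in range(6)]
        gm = GeneMatrix(rng.random((6, 3)), ids, ["s1", "s2", "s3"])
        summed = collapse_duplicates(gm, "sum")
        assert summed.expr.sum() == pytest.approx(gm.expr.sum())
        kept = collapse_duplicates(gm, "maxmean")
        for row in kept.expr:
            assert any(np.array_equal(row, orig) for orig in gm.expr)


class TestCollapseTree:
    def make_macrophage_atlas(self):
        labels = ["inflammatory macrophage"] * 40 + ["non-inflammatory macrophage"] * 60
        tree = TypeTree({
            "root": ["macrophage", "T cell"],
            "macrophage": ["inflammatory macrophage", "non-inflammatory macrophage"],
        })
        expr = np.ones((4, 100))
        labels += []
        return Atlas(expr[:, :100], [f"g{i}" for i in range(4)],
                     [f"c{i}" for i in range(100)], np.array(labels, dtype=object), tree)

    def test_macrophage_merge(self):
        at = self.make_macrophage_atlas()
        merged = collapse_tree(at, {
            "inflammatory macrophage": "macrophage",
            "non-inflammatory macrophage": "macrophage",
        })
        assert int(np.sum(merged.labels == "macrophage")) == 100
        assert "macrophage" in merged.tree.leaves()
        np.testing.assert_array_equal(merged.expr, at.expr)  # expression untouched

    def test_identity_map_unchanged(self, small_atlas):
        out = collapse_tree(small_atlas, {})
        assert list(out.labels) == list(small_atlas.labels)
        assert out.tree == small_atlas.tree

    def test_eight_subtypes_to_four_types(self):
        """Merging eight subtypes pairwise leaves exactly four leaf labels."""
        from tmedeconv import AtlasSpec, make_atlas

        spec = AtlasSpec(
            n_types=4,
            subtype_map={f"type_{i}": [f"type_{i}a", f"type_{i}b"] for i in range(4)},
            n_cells_per_type=25,
            n_genes=400,
            n_markers_per_type=8,
            seed=5,
        )
        at = make_atlas(spec)
        assert len(set(at.labels)) == 8
        merge = {f"type_{i}{s}": f"type_{i}" for i in range(4) for s in "ab"}
        merged = collapse_tree(at, merge)
        assert sorted(set(merged.labels)) == [f"type_{i}" for i in range(4)]
        assert sorted(merged.tree.leaves()) == [f"type_{i}" for i in range(4)]
        assert merged.expr.sum() == pytest.approx(at.expr.sum())  # mass conserved

    def test_unknown_key_named(self, small_atlas):
        with pytest.raises(DataError, match="ghost"):
            collapse_tree(small_atlas, {"ghost": "macrophage"})
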