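import numpy as np
import pytest

from omicsview.data_io import AnnotationCatalog, Rect, default_cell_layout
from omicsview.errors import ValidationError
from omicsview.treemap import (TreeNode, build_pathway_tree, internal, layout,
                               place_leaf_icons, slice_and_dice, squarify,
                               worst_aspect)
from omicsview.values import ValueVector

from ._squarified_reference import squarified_reference


def _overlap_area(a: Rect, b: Rect) -> float:
    w = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
    h = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
    return max(w, 0.0) * max(h, 0.0)


def _check_tiling(nodes, tol=1e-9):
    """Child rects tile each parent's interior with weight-proportional areas."""
    for ln in nodes:
        if not ln.node.children:
            continue
        interior = ln.rect.shrink(4.0)
        kids = [c for c in nodes
                if any(c.node is child for child in ln.node.children)]
        total = sum(k.rect.area for k in kids)
        assert abs(total - interior.area) <= tol * max(interior.area, 1.0)
        for k in kids:
            expect = interior.area * k.node.weight / ln.node.weight
            assert abs(k.rect.area - expect) <= tol * max(expect, 1.0)
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                assert _overlap_area(kids[i].rect, kids[j].rect) <= 1e-9


class TestSquarify:
    def test_two_equal_children_split_unit_square(self):
        # two congruent 0.5 x 1 halves (orientation fixed by the row rule)
        root = internal("r", [TreeNode("a", 1.0), TreeNode("b", 1.0)])
        nodes = layout(root, Rect(0, 0, 1, 1), inner_pad=0.0)
        kids = sorted([ln.rect for ln in nodes[1:]], key=lambda r: (r.x, r.y))
        assert all(k.area == 0.5 for k in kids)
        assert all({k.w, k.h} == {0.5, 1.0} for k in kids)
        assert kids[0].w == kids[1].w and kids[0].h == kids[1].h

    def test_single_child_fills_interior(self):
        root = internal("r", [TreeNode("a", 3.0)])
        nodes = layout(root, Rect(0, 0, 100, 50), inner_pad=4.0)
        assert nodes[1].rect == Rect(4, 4, 92, 42)

    def test_classic_weights_match_reference(self):
        # the canonical squarified demonstration instance
        weights = [6.0, 6.0, 4.0, 3.0, 2.0, 2.0, 1.0]
        rect = Rect(0, 0, 600, 400)
        scale = rect.area / sum(weights)
        areas = [w * scale for w in weights]
        got = squarify(areas, rect)
        expect = squarified_reference(areas, rect)
        assert len(got) == len(expect)
        for g, e in zip(got, expect):
            np.testing.assert_allclose(g, e, rtol=1e-9, atol=1e-9)

    def test_flat_random_instances_match_reference(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            weights = rng.uniform(0.5, 20.0, size=n)
            weights = np.sort(weights)[::-1]  # layout contract: descending
            rect = Rect(0, 0, float(rng.integers(100, 800)),
                        float(rng.integers(100, 800)))
            areas = (weights / weights.sum() * rect.area).tolist()
            got = squarify(areas, rect)
            expect = squarified_reference(areas, rect)
            for g, e in zip(got, expect):
                np.testing.assert_allclose(g, e, rtol=1e-9, atol=1e-9)

    def test_usually_beats_slice_and_dice(self):
        rng = np.random.default_rng(13)
        wins = 0
        trials = 200
        for _ in range(trials):
            n = int(rng.integers(3, 40))
            weights = np.sort(rng.lognormal(0, 1, size=n))[::-1]
            rect = Rect(0, 0, 600, 400)
            areas = (weights / weights.sum() * rect.area).tolist()
            sq = worst_aspect(squarify(areas, rect))
            sd = worst_aspect(slice_and_dice(areas, rect))
            if sq <= sd:
                wins += 1
        assert wins >= 0.95 * trials


def _random_tree(rng, max_depth=3, max_children=5) -> TreeNode:
    def build(depth, name):
        if depth == 0 or rng.random() < 0.35:
            return TreeNode(name, float(rng.integers(1, 20)))
        n = int(rng.integers(1, max_children + 1))
        kids = [build(depth - 1, f"{name}.{i}") for i in range(n)]
        return internal(name, kids)
    return build(max_depth, "root")


class TestLayoutInvariants:
    def test_random_trees_tile_proportionally(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            root = _random_tree(rng)
            nodes = layout(root, Rect(0, 0, 1000, 700), inner_pad=4.0)
            assert sum(1 for ln in nodes if not ln.node.children) <= 5 ** 3
            _check_tiling(nodes)

    def test_zero_weight_root_rejected(self):
        with pytest.raises(ValidationError):
            layout(TreeNode("r", 0.0), Rect(0, 0, 10, 10))

    def test_pad_too_large_suggests_smaller(self):
        root = internal("r", [TreeNode("a", 1.0)])
        with pytest.raises(ValidationError, match="inner-pad"):
            layout(root, Rect(0, 0, 6, 6), inner_pad=4.0)

    def test_adding_an_entity_grows_the_leaf_fraction(self):
        a, b = TreeNode("a", 5.0), TreeNode("b", 10.0)
        before = layout(internal("r", [a, b]), Rect(0, 0, 100, 100), 0.0)
        after = layout(internal("r", [TreeNode("a", 6.0), b]),
                       Rect(0, 0, 100, 100), 0.0)
        frac = lambda nodes, name: next(
            ln.rect.area for ln in nodes if ln.node.name == name) / 100 ** 2
        assert frac(after, "a") > frac(before, "a")


class TestPathwayTree:
    def _catalog(self):
        return AnnotationCatalog(
            entity_compartments={"g1": frozenset({"cytosol"})},
            entity_pathways={"g1": frozenset({"p1", "p2"})},
            pathway_compartments={"p1": frozenset({"cytosol"}),
                                  "p2": frozenset({"nucleus"})},
            universe=frozenset({"g1", "g2"}),
        )

    def test_entity_in_two_pathways_duplicates(self):
        v = ValueVector(["g1"], [1.0])
        tree = build_pathway_tree(self._catalog(), v)
        leaves = [c for comp in tree.children for c in comp.children]
        assert sum(leaf.weight for leaf in leaves) == 2.0

    def test_no_pathway_annotation_gives_empty_root(self):
        v = ValueVector(["g2"], [1.0])
        tree = build_pathway_tree(self._catalog(), v)
        assert tree.children == [] and tree.weight == 0.0

    def test_leaf_weights_match_triple_loop_oracle(self, tables):
        cat = tables.catalog
        ds = tables.dataset
        ids = ds.entity_ids
        v = ValueVector(ids, np.nan_to_num(ds.values[:, 0], nan=1.0))
        tree = build_pathway_tree(cat, v, default_cell_layout())
        got = {}
        for comp in tree.children:
            for leaf in comp.children:
                got[(comp.name, leaf.name)] = leaf.weight
        displayed = set(ids)
        expect = {}
        for pw, comps in cat.pathway_compartments.items():
            n = sum(1 for e, pws in cat.entity_pathways.items()
                    if pw in pws and e in displayed)
            if n == 0:
                continue
            for c in comps:
                expect[(c, pw)] = float(n)
        assert got == expect

    def test_compartment_fills_reuse_cell_palette(self, tables):
        lay = default_cell_layout()
        ds = tables.dataset
        v = ValueVector(ds.entity_ids, np.nan_to_num(ds.values[:, 0], nan=1.0))
        tree = build_pathway_tree(tables.catalog, v, lay)
        for comp in tree.children:
            assert comp.fill == lay.fill(comp.name)


class TestLeafIcons:
    def test_three_discs_in_ample_leaf(self):
        leaf = TreeNode("p", 3.0, entities=("a", "b", "c"))
        nodes = layout(internal("r", [leaf]), Rect(0, 0, 300, 300), 4.0)
        leaves = [ln for ln in nodes if not ln.node.children]
        v = ValueVector(["a", "b", "c"], [3.0, 1.0, 2.0])
        groups, plan = place_leaf_icons(leaves, v, 8.0, 2.0)
        assert plan.g == 1
        assert [g.shape for g in groups[0]] == ["disc"] * 3
        assert [g.member_entities[0] for g in groups[0]] == ["b", "c", "a"]

    def test_tiny_leaf_forces_rectangles(self):
        leaf = TreeNode("p", 8.0, entities=tuple(f"e{i}" for i in range(8)))
        nodes = layout(internal("r", [leaf]), Rect(0, 0, 30, 30), 2.0)
        leaves = [ln for ln in nodes if not ln.node.children]
        v = ValueVector([f"e{i}" for i in range(8)], list(range(8)))
        groups, plan = place_leaf_icons(leaves, v, 8.0, 2.0)
        assert plan.g > 1
        assert any(g.shape == "rectangle" for g in groups[0])

    def test_entity_conservation_across_leaves(self, tables):
        cat = tables.catalog
        ds = tables.dataset
        v = ValueVector(ds.entity_ids, np.nan_to_num(ds.values[:, 0], nan=1.0))
        tree = build_pathway_tree(cat, v, default_cell_layout())
        nodes = layout(tree, Rect(0, 0, 1000, 700), 4.0)
        leaves = [ln for ln in nodes if not ln.node.children]
        groups, _plan = place_leaf_icons(leaves, v, 8.0, 2.0)
        for i, ln in enumerate(leaves):
            flat = sorted(e for g in groups[i] for e in g.member_entities)
            assert flat == sorted(ln.node.entities)
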