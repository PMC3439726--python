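import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsview import fixtures
from omicsview.errors import InputFormatError, ValidationError
from omicsview.go_view import (GoGraph, build_go_tree, collapse,
                               entities_at_term, expand, expand_to_depth,
                               initial_state, read_annotations_gaf, read_obo)

TOY_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: mid process
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: leaf process
namespace: biological_process
is_a: GO:0000002 ! mid process

[Term]
id: GO:0000004
name: gone process
namespace: biological_process
is_obsolete: true

[Term]
id: GO:0000005
name: root function
namespace: molecular_function
"""


@pytest.fixture
def toy_graph(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return read_obo(p)


class TestReadObo:
    def test_chain_edges(self, toy_graph):
        assert toy_graph.parents["GO:0000002"] == {"GO:0000001"}
        assert toy_graph.parents["GO:0000003"] == {"GO:0000002"}

    def test_obsolete_term_absent(self, toy_graph):
        assert "GO:0000004" not in toy_graph.terms

    def test_namespace_roots(self, toy_graph):
        assert toy_graph.namespace_root("biological_process") == "GO:0000001"
        assert toy_graph.namespace_root("molecular_function") == "GO:0000005"

    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="cycle"):
            GoGraph(terms={"a": ("a", "biological_process"),
                           "b": ("b", "biological_process")},
                    parents={"a": frozenset({"b"}), "b": frozenset({"a"})})

    def test_fixture_dag_round_trips(self, tables, tmp_path):
        p = tmp_path / "fx.obo"
        fixtures.write_obo(tables.go_terms, tables.go_parents, p)
        g = read_obo(p)
        assert set(g.terms) == set(tables.go_terms)
        assert {t: g.parents.get(t, frozenset()) for t in g.terms
                if g.parents.get(t)} == tables.go_parents


class TestReadGaf:
    def test_not_qualifier_skipped(self, toy_graph, tmp_path):
        p = tmp_path / "a.gaf"
        row = ["DB", "g1", "g1", "NOT|involved_in", "GO:0000002", "R", "IEA",
               "", "P", "", "", "protein", "taxon:1", "20240101", "DB", "", ""]
        p.write_text("!gaf-version: 2.2\n" + "\t".join(row) + "\n")
        g = read_annotations_gaf(p, toy_graph)
        assert "g1" not in g.annotations

    def test_two_column_fallback(self, toy_graph, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("g1\tGO:0000003\n")
        g = read_annotations_gaf(p, toy_graph)
        assert g.annotations["g1"] == {"GO:0000003"}

    def test_unknown_term_skipped_with_count(self, toy_graph, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("g1\tGO:0000003\ng2\tGO:9999999\n")
        g = read_annotations_gaf(p, toy_graph)
        assert "g2" not in g.annotations and g.n_unknown_term_rows == 1

    def test_malformed_column_count_cites_line(self, toy_graph, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("g1\tGO:0000003\na\tb\tc\n")
        with pytest.raises(InputFormatError, match="a.tsv:2"):
            read_annotations_gaf(p, toy_graph)

    def test_fixture_gaf_round_trips(self, tables, go_graph, tmp_path):
        p = tmp_path / "fx.gaf"
        fixtures.write_gaf(tables.go_annotations, tables.go_terms, p)
        fresh = GoGraph(terms=dict(tables.go_terms),
                        parents=dict(tables.go_parents))
        read_annotations_gaf(p, fresh)
        assert fresh.annotations == tables.go_annotations


class TestPropagation:
    def test_root_collects_every_annotated_entity(self, toy_graph):
        toy_graph.annotations = {"g1": frozenset({"GO:0000003"}),
                                 "g2": frozenset({"GO:0000002"}),
                                 "g3": frozenset({"GO:0000005"})}
        displayed = {"g1", "g2", "g3"}
        assert entities_at_term(toy_graph, "GO:0000001", displayed) == {"g1", "g2"}

    def test_leaf_term_holds_direct_annotations_only(self, toy_graph):
        toy_graph.annotations = {"g1": frozenset({"GO:0000003"}),
                                 "g2": frozenset({"GO:0000002"})}
        assert entities_at_term(toy_graph, "GO:0000003", {"g1", "g2"}) == {"g1"}

    def test_matches_descendant_closure_oracle(self, go_graph, tables):
        displayed = set(tables.dataset.entity_ids)

        def closure(term):
            seen, stack = {term}, [term]
            while stack:
                t = stack.pop()
                for c, ps in tables.go_parents.items():
                    if t in ps and c not in seen:
                        seen.add(c)
                        stack.append(c)
            return seen

        for term in go_graph.terms:
            desc = closure(term)
            expect = {e for e, ts in tables.go_annotations.items()
                      if e in displayed and ts & desc}
            assert entities_at_term(go_graph, term, displayed) == expect

    def test_parent_counts_dominate_child_counts(self, go_graph, tables):
        displayed = set(tables.dataset.entity_ids)
        for child, parents in go_graph.parents.items():
            nc = len(entities_at_term(go_graph, child, displayed))
            for p in parents:
                assert len(entities_at_term(go_graph, p, displayed)) >= nc


class TestExpandCollapse:
    def test_expand_then_collapse_is_identity(self, toy_graph):
        s0 = initial_state(toy_graph, "biological_process")
        s1 = expand(s0, s0.root, toy_graph)
        assert s0.root in s1.expanded
        assert collapse(s1, s0.root, toy_graph) == s0

    def test_collapse_drops_expanded_descendants(self, toy_graph):
        s = initial_state(toy_graph, "biological_process")
        s = expand(s, "GO:0000001", toy_graph)
        s = expand(s, "GO:0000002", toy_graph)
        s = collapse(s, "GO:0000001", toy_graph)
        assert s.expanded == frozenset()

    def test_expand_hidden_term_rejected(self, toy_graph):
        s = initial_state(toy_graph, "biological_process")
        with pytest.raises(ValidationError, match="visible"):
            expand(s, "GO:0000003", toy_graph)

    def test_expand_leaf_is_noop(self, toy_graph):
        s = initial_state(toy_graph, "biological_process")
        s = expand(s, "GO:0000001", toy_graph)
        s = expand(s, "GO:0000002", toy_graph)
        assert expand(s, "GO:0000003", toy_graph) == s

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.booleans(), st.integers(0, 10 ** 6)),
                    max_size=25))
    def test_random_walks_keep_state_invariant(self, go_graph, steps):
        state = initial_state(go_graph, "biological_process")
        terms = sorted(go_graph.descendants(state.root))
        for do_expand, pick in steps:
            term = terms[pick % len(terms)]
            try:
                if do_expand:
                    state = expand(state, term, go_graph)
                else:
                    state = collapse(state, term, go_graph)
            except ValidationError:
                continue
            state.check(go_graph)


class TestBuildGoTree:
    def test_unexpanded_root_is_one_rectangle(self, go_graph, tables):
        displayed = set(tables.dataset.entity_ids)
        state = initial_state(go_graph, "biological_process")
        tree = build_go_tree(go_graph, state, displayed)
        assert tree.children == []
        root = state.root
        assert tree.weight == len(entities_at_term(go_graph, root, displayed))

    def test_weights_match_propagation_and_residual_covers(self, go_graph, tables):
        displayed = set(tables.dataset.entity_ids)
        rng = np.random.default_rng(31)
        for depth in (1, 2, 3):
            state = expand_to_depth(go_graph, "biological_process", depth,
                                    displayed)
            tree = build_go_tree(go_graph, state, displayed)

            def walk(node):
                if not node.children:
                    assert node.entities is not None
                    assert node.weight == len(node.entities)
                    return set(node.entities)
                covered = set()
                for c in node.children:
                    covered |= walk(c)
                return covered

            root_cov = walk(tree)
            expect = entities_at_term(go_graph, state.root, displayed)
            assert root_cov == expect

    def test_level_fills_differ_between_depths(self, go_graph, tables):
        displayed = set(tables.dataset.entity_ids)
        state = expand_to_depth(go_graph, "biological_process", 2, displayed)
        tree = build_go_tree(go_graph, state, displayed)
        if tree.children:
            assert tree.fill != tree.children[0].fill
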