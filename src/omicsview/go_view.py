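"""Gene Ontology DAG handling: OBO/GAF input, true-path propagation, and
the expand/collapse state behind the GO-hierarchy treemap.

Entities annotated to a term count toward every ancestor along ``is_a``
edges (the true-path rule), so the namespace root always shows every
annotated, displayed entity.  The rendered tree mirrors an expansion
frontier: an expanded term shows one child rectangle per populated child
plus a residual leaf for entities none of the shown children cover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import obonet

from .errors import InputFormatError, ValidationError
from .treemap import TreeNode, internal

log = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
# Views are offered for BP and MF; cellular_component is parsed but not rendered.
VIEW_NAMESPACES = ("biological_process", "molecular_function")

# depth-cycled rectangle fills, deliberately outside the YlOrRd icon ramp
GO_LEVEL_FILLS = ("#DCE9F5", "#C3D9EE", "#AAC9E7", "#91B9E0", "#78A9D9", "#5F99D2")


@dataclass
class GoGraph:
    """Term metadata, child->parents ``is_a`` edges, and entity annotations."""

    terms: dict[str, tuple[str, str]]  # id -> (name, namespace)
    parents: dict[str, frozenset[str]]  # child -> is_a parents
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        self._children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise ValidationError(f"edge points at unknown term {p!r}")
                self._children[p].add(child)
        g = nx.DiGraph((c, p) for c, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(
                "is_a relation contains a cycle: "
                + " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
            )
        for ents in self.annotations.values():
            for t in ents:
                if t not in self.terms:
                    raise ValidationError(f"annotation references unknown term {t!r}")

    def children(self, term: str) -> list[str]:
        self._require(term)
        return sorted(self._children[term])

    def namespace_root(self, namespace: str) -> str:
        if namespace not in NAMESPACES:
            raise ValidationError(f"unknown GO namespace {namespace!r}")
        roots = sorted(
            t for t, (_n, ns) in self.terms.items()
            if ns == namespace and not self.parents.get(t)
        )
        if not roots:
            raise ValidationError(f"no root term for namespace {namespace!r}")
        if len(roots) > 1:
            raise ValidationError(
                f"namespace {namespace!r} has multiple roots: {', '.join(roots)}"
            )
        return roots[0]

    def descendants(self, term: str) -> set[str]:
        """term plus everything reachable downward along is_a."""
        self._require(term)
        seen = {term}
        stack = [term]
        while stack:
            for c in self._children[stack.pop()]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return seen

    def _require(self, term: str):
        if term not in self.terms:
            raise ValidationError(f"unknown GO term {term!r}")


def read_obo(path) -> GoGraph:
    """Parse an OBO 1.2 file into terms + is_a edges (obsolete terms skipped)."""
    g = obonet.read_obo(path)  # skips is_obsolete stanzas
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, frozenset[str]] = {}
    for node, data in g.nodes(data=True):
        terms[node] = (data.get("name", node), data.get("namespace", ""))
    for node in g.nodes:
        ps = frozenset(
            parent for _c, parent, key in g.out_edges(node, keys=True) if key == "is_a"
        )
        if ps:
            parents[node] = ps
    return GoGraph(terms=terms, parents=parents)


def read_annotations_gaf(path, graph: GoGraph) -> GoGraph:
    """Fill entity->term annotations from GAF 2.x or a 2-column TSV.

    GAF rows with a NOT qualifier are skipped (standard GAF semantics);
    annotations to terms absent from the ontology are skipped with a
    logged count.
    """
    ann: dict[str, set[str]] = {}
    unknown = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                entity, term = fields[0].strip(), fields[1].strip()
            elif len(fields) == 17:
                qualifier = fields[3]
                if "NOT" in qualifier.split("|"):
                    continue
                entity, term = fields[1].strip(), fields[4].strip()
            else:
                raise InputFormatError(
                    path, lineno,
                    f"expected 2 (TSV) or 17 (GAF) columns, got {len(fields)}",
                )
            if term not in graph.terms:
                unknown += 1
                continue
            ann.setdefault(entity, set()).add(term)
    if unknown:
        log.info("annotations: skipped %d rows with unknown terms", unknown)
    graph.annotations = {e: frozenset(ts) for e, ts in ann.items()}
    graph.n_unknown_term_rows = unknown
    return graph


def entities_at_term(graph: GoGraph, term: str, displayed: set) -> set[str]:
    """Displayed entities annotated to the term or any descendant of it."""
    desc = graph.descendants(term)
    return {
        e for e in displayed
        if not graph.annotations.get(e, frozenset()).isdisjoint(desc)
    }


# ---------------------------------------------------------------------------
# expansion state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoViewState:
    """Which terms of one namespace are currently opened into sub-rectangles."""

    namespace: str
    root: str
    expanded: frozenset[str] = frozenset()

    def check(self, graph: GoGraph) -> None:
        for t in self.expanded:
            if t == self.root:
                continue
            # reachable from the root through expanded ancestors on some path
            frontier = {self.root} if self.root in self.expanded else set()
            seen = set(frontier)
            ok = False
            while frontier:
                nxt = set()
                for u in frontier:
                    for c in graph._children[u]:
                        if c == t:
                            ok = True
                        if c in self.expanded and c not in seen:
                            seen.add(c)
                            nxt.add(c)
                frontier = nxt
                if ok:
                    break
            if not ok:
                raise ValidationError(
                    f"expanded term {t} is not reachable through expanded ancestors"
                )


def initial_state(graph: GoGraph, namespace: str) -> GoViewState:
    return GoViewState(namespace=namespace, root=graph.namespace_root(namespace))


def _visible(state: GoViewState, graph: GoGraph, term: str) -> bool:
    if term == state.root:
        return True
    return any(p in state.expanded for p in graph.parents.get(term, frozenset()))


def expand(state: GoViewState, term: str, graph: GoGraph) -> GoViewState:
    """Open a visible term into its child rectangles; no-op on leaves."""
    graph._require(term)
    if not _visible(state, graph, term):
        raise ValidationError(f"cannot expand {term}: it is not currently visible")
    if not graph._children[term]:
        log.info("term %s has no children; expand is a no-op", term)
        return state
    return replace(state, expanded=state.expanded | {term})


def collapse(state: GoViewState, term: str, graph: GoGraph) -> GoViewState:
    """Close a term, dragging every orphaned expanded descendant shut too."""
    if term not in state.expanded:
        raise ValidationError(f"cannot collapse {term}: it is not expanded")
    keep = set(state.expanded) - {term}
    # iteratively drop expanded terms no longer reachable through an
    # expanded parent (descendants of the closed rectangle)
    changed = True
    while changed:
        changed = False
        for t in sorted(keep):
            if t != state.root and not any(
                p in keep for p in graph.parents.get(t, frozenset())
            ):
                keep.discard(t)
                changed = True
    return replace(state, expanded=frozenset(keep))


def expand_to_depth(graph: GoGraph, namespace: str, depth: int,
                    displayed: set | None = None) -> GoViewState:
    """Expand every term whose shortest-path depth from the root is < depth.

    The batch analog of clicking the level-down button ``depth`` times;
    with ``displayed`` given, terms with no displayed entities stay closed.
    """
    state = initial_state(graph, namespace)
    if depth <= 0:
        return state
    expanded: set[str] = set()
    seen = {state.root}
    queue = [(state.root, 0)]
    while queue:
        term, d = queue.pop(0)
        if d >= depth:
            continue
        if displayed is not None and not entities_at_term(graph, term, displayed):
            continue
        if graph._children[term]:
            expanded.add(term)
        for c in graph.children(term):
            if c not in seen:
                seen.add(c)
                queue.append((c, d + 1))
    return replace(state, expanded=frozenset(expanded))


# ---------------------------------------------------------------------------
# tree construction for the treemap engine
# ---------------------------------------------------------------------------

def build_go_tree(graph: GoGraph, state: GoViewState, displayed: set) -> TreeNode:
    """Weighted tree mirroring the expansion frontier.

    Every node's entity count honors the true-path rule; inside an expanded
    rectangle, entities whose specific annotations fall under no shown child
    gather in a residual leaf so nothing silently disappears.  Rectangle
    fills cycle through a depth-keyed palette distinct from the icon ramp.
    """
    def term_label(t: str) -> str:
        return graph.terms[t][0]

    def node_for(term: str, depth: int) -> TreeNode | None:
        ents = entities_at_term(graph, term, displayed)
        if not ents:
            return None
        fill = GO_LEVEL_FILLS[depth % len(GO_LEVEL_FILLS)]
        if term not in state.expanded or not graph._children[term]:
            return TreeNode(term_label(term), float(len(ents)),
                            fill=fill, entities=tuple(sorted(ents)))
        children = []
        covered: set[str] = set()
        for c in graph.children(term):
            child = node_for(c, depth + 1)
            if child is not None:
                children.append(child)
                covered |= entities_at_term(graph, c, displayed)
        residual = sorted(ents - covered)
        if residual:
            children.append(TreeNode(
                f"{term_label(term)} (other)", float(len(residual)),
                fill=GO_LEVEL_FILLS[(depth + 1) % len(GO_LEVEL_FILLS)],
                entities=tuple(residual),
            ))
        if not children:
            return TreeNode(term_label(term), float(len(ents)),
                            fill=fill, entities=tuple(sorted(ents)))
        node = internal(term_label(term), children, fill=fill)
        return node

    root = node_for(state.root, 0)
    if root is None:
        return TreeNode(term_label(state.root), 0.0, entities=())
    return root
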