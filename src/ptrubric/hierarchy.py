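"""Unified PT hierarchy: a validated DAG with expansion and normalization.

The hierarchy arranges all PT terms and rubric categories under a single set
of roots. Nodes are either ``pt-term`` (MeSH-style indexing targets) or
``rubric-category`` (organizational groupings); edges point from parent to
child and multiple parents are allowed (MeSH itself is polyhierarchical).

Two operations make the hierarchy useful downstream:

* ``expand_query`` — PubMed-style query expansion: a term stands for itself
  plus every more specific term below it.
* ``normalize_tags`` — post-prediction normalization: every assigned tag
  drags in all its pt-term ancestors, so indexing is hierarchy-consistent
  (an article tagged Cohort Studies is also an Observational Study and a
  Clinical Study, whatever its raw scores said).

Rubric-category nodes are excluded from both results by default, since only
PT terms are indexing targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .vocab_io import PTVocabulary, default_hierarchy_path

__all__ = [
    "Hierarchy",
    "HierarchyError",
    "HierarchyReport",
    "load_hierarchy",
    "save_hierarchy",
    "load_default_hierarchy",
    "validate_hierarchy",
]

NODE_KINDS = ("pt-term", "rubric-category")


class HierarchyError(ValueError):
    """Structurally invalid hierarchy (cycle, dangling parent, bad kind)."""


@dataclass
class Hierarchy:
    """DAG of named nodes; edges run parent → child."""

    graph: nx.DiGraph
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, data in self.graph.nodes(data=True):
            if data.get("kind") not in NODE_KINDS:
                raise HierarchyError(f"node {name!r} has invalid kind {data.get('kind')!r}")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = [u for u, _ in nx.find_cycle(self.graph)]
            raise HierarchyError(f"hierarchy contains a cycle: {cycle}")
        if not self.roots():
            raise HierarchyError("hierarchy has no root")

    # -- structure -----------------------------------------------------------

    def __contains__(self, name: object) -> bool:
        return name in self.graph

    def kind(self, name: str) -> str:
        self._check(name)
        return self.graph.nodes[name]["kind"]

    def parents(self, name: str) -> set[str]:
        self._check(name)
        return set(self.graph.predecessors(name))

    def children(self, name: str) -> set[str]:
        self._check(name)
        return set(self.graph.successors(name))

    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    def pt_terms(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "pt-term"}

    def categories(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "rubric-category"}

    def level(self, name: str) -> int:
        """Depth as the longest parent chain above the node (roots are 0)."""
        self._check(name)
        depth = 0
        frontier = self.parents(name)
        while frontier:
            depth += 1
            frontier = {p for f in frontier for p in self.parents(f)}
        return depth

    def _check(self, name: str) -> None:
        if name not in self.graph:
            raise KeyError(f"unknown term {name!r}")

    # -- closures ------------------------------------------------------------

    def descendants(self, term: str) -> set[str]:
        """All nodes strictly below ``term`` (transitive closure)."""
        self._check(term)
        return set(nx.descendants(self.graph, term))

    def ancestors(self, term: str) -> set[str]:
        """All nodes strictly above ``term`` (transitive closure)."""
        self._check(term)
        return set(nx.ancestors(self.graph, term))

    def expand_query(self, term: str, include_categories: bool = False) -> set[str]:
        """The term plus everything below it, restricted to pt-terms by default."""
        out = {term} | self.descendants(term)
        if not include_categories:
            out &= self.pt_terms()
        return out

    def normalize_tags(self, tags: set[str], include_categories: bool = False) -> set[str]:
        """Tags plus all their (pt-term, by default) ancestors; never removes a tag."""
        missing = sorted(t for t in tags if t not in self.graph)
        if missing:
            raise KeyError(f"tags absent from hierarchy: {missing}")
        out = set(tags)
        for t in tags:
            anc = self.ancestors(t)
            if not include_categories:
                anc &= self.pt_terms()
            out |= anc
        return out


def _build(nodes: list[dict], meta: dict | None = None) -> Hierarchy:
    g = nx.DiGraph()
    names = [n["name"] for n in nodes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise HierarchyError(f"duplicate node names: {dupes}")
    for n in nodes:
        g.add_node(n["name"], kind=n.get("kind", "pt-term"))
    for n in nodes:
        for p in n.get("parents", []):
            if p not in g:
                raise HierarchyError(f"node {n['name']!r} names dangling parent {p!r}")
            g.add_edge(p, n["name"])
    return Hierarchy(g, meta or {})


def load_hierarchy(path: str | Path) -> Hierarchy:
    """Load and validate a hierarchy from its JSON serialization.

    Schema: ``{"nodes": [{"name": str, "kind": str, "parents": [str, ...]}]}``
    with an optional free-form ``meta`` object.
    """
    raw = json.loads(Path(path).read_text())
    if "nodes" not in raw:
        raise HierarchyError(f"{path}: no 'nodes' key")
    return _build(raw["nodes"], raw.get("meta"))


def save_hierarchy(h: Hierarchy, path: str | Path) -> None:
    """JSON serialization; ``load_hierarchy(save_hierarchy(h))`` is the identity."""
    nodes = [
        {
            "name": name,
            "kind": h.graph.nodes[name]["kind"],
            "parents": sorted(h.graph.predecessors(name)),
        }
        for name in h.graph.nodes
    ]
    doc = {"meta": h.meta, "nodes": nodes} if h.meta else {"nodes": nodes}
    Path(path).write_text(json.dumps(doc, indent=1, ensure_ascii=False))


def load_default_hierarchy() -> Hierarchy:
    """The shipped unified hierarchy (5 broad roots, 13 low-level categories, 72 PTs)."""
    return load_hierarchy(default_hierarchy_path())


@dataclass
class HierarchyReport:
    """Cross-check of a hierarchy against a vocabulary."""

    missing_from_hierarchy: list[str]
    missing_from_vocab: list[str]
    structural_issues: list[str]

    @property
    def ok(self) -> bool:
        return not (self.missing_from_hierarchy or self.missing_from_vocab or self.structural_issues)


def validate_hierarchy(h: Hierarchy, vocab: PTVocabulary) -> HierarchyReport:
    """Report vocabulary/hierarchy mismatches and structural oddities.

    Structural issues reported: rubric categories with no children (orphaned
    groupings) and pt-term roots (terms attached to nothing).
    """
    pts = h.pt_terms()
    issues = []
    for cat in sorted(h.categories()):
        if not h.children(cat):
            issues.append(f"orphaned category (no members): {cat!r}")
    for root in sorted(h.roots()):
        if h.kind(root) == "pt-term":
            issues.append(f"pt-term without any parent: {root!r}")
    return HierarchyReport(
        missing_from_hierarchy=sorted(set(vocab.terms) - pts),
        missing_from_vocab=sorted(pts - set(vocab.terms)),
        structural_issues=issues,
    )
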