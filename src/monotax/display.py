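"""Collapse/expand views over an assessed tree, reports and renderers.

A :class:`DisplayTree` is a truncation of the annotated tree: a frontier of
*collapsed* nodes (drawn as single labelled leaves) partitions the leaf set
under the current view root.  Labels follow the field notation:

* ``<P>Cyanobacteria{15}`` — a monophyletic taxon, n complete-lineage
  members, ``{n+m}`` with the ``+m`` elided when m = 0 and written
  ``{0+m}`` when n = 0;
* ``<D>Bacteria(2282/11156+143)`` — one fragment of a non-monophyletic
  taxon: 2282 complete members here out of 11156 tree-wide, plus 143
  incomplete or absorbed sequences in this fragment;
* a bare strain tag for a single-sequence leaf.

Styles mirror the classic colour scheme: ``mono`` (red), ``non_mono``
(blue), ``query_hit`` (green, wins over red/blue), ``plain`` for single
sequences and pseudo-taxa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

from .errors import ArgumentError, TaxonLookupError
from .formats import UNCLASSIFIED, write_newick
from .monophyly import (
    AnnotatedTree,
    assess_monophyly,
    collapsible_as,
    full_assessment,
)
from .taxonomy import KEY_RANKS, TaxonKey, TaxonTable, is_complete, key_str
from .tree import Node, PhyloTree


def format_counts(n: int, m: int) -> str:
    """The ``{n+m}`` label suffix with the standard elision rules."""
    if m == 0:
        return f"{{{n}}}"
    if n == 0:
        return f"{{0+{m}}}"
    return f"{{{n}+{m}}}"


def format_fraction(n_frag: int, n_total: int, m_frag: int) -> str:
    """Fragment label suffix ``(n_frag/n_total+m_frag)``."""
    return f"({n_frag}/{n_total}+{m_frag})"


@dataclass
class DisplayLeaf:
    """One displayed line: a collapsed node (or plain leaf) with its label."""

    node: Node
    label: str
    style: str  # mono | non_mono | query_hit | plain
    key: Optional[TaxonKey]
    n: int
    m: int

    @property
    def size(self) -> int:
        return max(self.n + self.m, 1)


_STYLE_TAGS = {"mono": "[M]", "non_mono": "[N]", "query_hit": "[Q]", "plain": ""}


class DisplayTree:
    """A collapse/expand state over an :class:`AnnotatedTree`.

    The state is the set of collapsed frontier nodes under ``view_root``;
    everything above the frontier is expanded.  All mutating operations
    keep the invariant that the frontier partitions the leaves under the
    view root.
    """

    def __init__(self, at: AnnotatedTree, view_root: Optional[Node] = None):
        self.at = at
        self.view_root = view_root or at.tree.root
        self.frontier: list[Node] = []
        # query hit nodes -> the queried taxon key (labels at that rank)
        self.query_keys: dict[int, TaxonKey] = {}
        self.warnings: list[str] = []

    # -- equality is on the visible state, not object identity ------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, DisplayTree):
            return NotImplemented
        return (
            self.at is other.at
            and self.view_root is other.view_root
            and [n._id for n in self.frontier] == [n._id for n in other.frontier]
            and self.query_keys == other.query_keys
        )

    # ------------------------------------------------------------------
    # frontier construction
    # ------------------------------------------------------------------
    def _max_collapse_from(self, node: Node) -> list[Node]:
        """Greedy top-down collapse: a node becomes a display leaf iff it
        is collapsible; otherwise recurse into its children."""
        out: list[Node] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur.is_leaf or self.at.deepest_key(cur) is not None:
                out.append(cur)
            else:
                for child in reversed(cur.children):
                    stack.append(child)
        return out

    def _sort_frontier(self) -> None:
        self.frontier.sort(key=lambda nd: nd._tin)

    # ------------------------------------------------------------------
    # operations
    # ------------------------------------------------------------------
    def expand(self, node: Node) -> "DisplayTree":
        if node not in self.frontier:
            raise ArgumentError("expand: node is not a collapsed display leaf")
        if self.at.leaf_count(node) <= 1:
            self.warnings.append(
                "entry represents a single sequence and cannot be further expanded"
            )
            return self
        self.frontier.remove(node)
        self.query_keys.pop(node._id, None)
        for child in node.children:
            self.frontier.extend(self._max_collapse_from(child))
        self._sort_frontier()
        return self

    def collapse(self, node: Node) -> "DisplayTree":
        if node in self.frontier:
            return self  # already collapsed: no-op
        if not self.at.tree.is_ancestor(self.view_root, node):
            raise ArgumentError("collapse: node is outside the current view")
        covered = [f for f in self.frontier if self.at.tree.is_ancestor(node, f)]
        if not covered:
            raise ArgumentError("collapse: node is below the displayed frontier")
        for f in covered:
            self.frontier.remove(f)
            self.query_keys.pop(f._id, None)
        self.frontier.extend(self._max_collapse_from(node))
        self._sort_frontier()
        return self

    # ------------------------------------------------------------------
    # labelling
    # ------------------------------------------------------------------
    def _leaf_info(self, node: Node) -> DisplayLeaf:
        at = self.at
        if node.is_leaf and at.deepest_key(node) is None:
            # cannot happen (a single leaf always yields a key) but keep safe
            return DisplayLeaf(node, node.label or "", "plain", None, 1, 0)
        key, n, m = collapsible_as(node, at)  # type: ignore[misc]
        qkey = self.query_keys.get(node._id)
        if qkey is not None:
            key = qkey  # a query hit is labelled at the queried taxon's rank
        style: str
        if qkey is None and node.is_leaf and at.leaf_count(node) == 1:
            label = node.label or ""
            style = "plain"
            info = DisplayLeaf(node, label, style, key, n, m)
        elif key[-1] == UNCLASSIFIED:
            # pseudo-taxon: counts but no monophyly verdict
            label = _key_label(key) + format_counts(n, m)
            info = DisplayLeaf(node, label, "plain", key, n, m)
        else:
            try:
                status = assess_monophyly(key, at)
            except TaxonLookupError:
                # named composite key without an exact-member leaf (all its
                # witnesses are partially Unclassified): counts only
                status = None
            if status is None:
                label = _key_label(key) + format_counts(n, m)
                style = "plain"
            elif status.is_monophyletic:
                label = _key_label(key) + format_counts(n, m)
                style = "mono"
            else:
                label = _key_label(key) + format_fraction(n, status.n_total, m)
                style = "non_mono"
            info = DisplayLeaf(node, label, style, key, n, m)
        if qkey is not None:
            info.style = "query_hit"
        return info

    def display_leaves(self) -> list[DisplayLeaf]:
        return [self._leaf_info(node) for node in self.frontier]


def _key_label(key: TaxonKey) -> str:
    return f"<{KEY_RANKS[len(key) - 1]}>{key[-1]}"


# ---------------------------------------------------------------------------
# constructors / top-level operations
# ---------------------------------------------------------------------------

def maximal_collapse(
    at: AnnotatedTree, view_root: Optional[Node] = None
) -> DisplayTree:
    """The fully collapsed view: the minimum number of display leaves."""
    d = DisplayTree(at, view_root)
    d.frontier = d._max_collapse_from(d.view_root)
    d._sort_frontier()
    return d


def expand_node(d: DisplayTree, node: Node) -> DisplayTree:
    return d.expand(node)


def collapse_node(d: DisplayTree, node: Node) -> DisplayTree:
    return d.collapse(node)


def set_top_node(d: DisplayTree, node: Node) -> DisplayTree:
    """Re-root the view at an internal node and maximally collapse it."""
    if node.is_leaf:
        raise ArgumentError("top node must be an internal node, not a leaf")
    return maximal_collapse(d.at, view_root=node)


def _resolve_query(at: AnnotatedTree, name: str) -> list[TaxonKey]:
    """Taxon keys whose terminal name matches ``name``.

    Matching is case-insensitive after space->underscore normalization.  A
    rank-qualified query like ``<P>Actinobacteria`` restricts the match to
    that rank.
    """
    rank: Optional[str] = None
    text = name.strip()
    if len(text) > 3 and text[0] == "<" and text[2] == ">":
        rank = text[1].upper()
        if rank not in KEY_RANKS:
            raise TaxonLookupError(f"unknown rank marker <{rank}> in query {name!r}")
        text = text[3:]
    needle = text.replace(" ", "_").lower()
    hits: list[TaxonKey] = []
    near: set[str] = set()
    for rec in at.taxon_table.named_records():
        terminal = rec.key[-1].lower()
        if rank is not None and KEY_RANKS[len(rec.key) - 1] != rank:
            continue
        if terminal == needle:
            hits.append(tuple(rec.key))
        elif terminal.startswith(needle):
            near.add(rec.key[-1])
    if not hits:
        raise TaxonLookupError(
            f"no taxon named {text!r}", candidates=sorted(near)[:10]
        )
    return hits


def search_query(
    at: AnnotatedTree, name: str, view_root: Optional[Node] = None
) -> DisplayTree:
    """Expand the neighborhood of every fragment of the queried taxon.

    Each fragment becomes a collapsed display leaf styled as a query hit;
    all ancestors of fragments are expanded and every branch off those
    ancestor paths is maximally collapsed.
    """
    d = DisplayTree(at, view_root)
    root = d.view_root
    tree = at.tree
    targets: dict[int, Node] = {}
    target_keys: dict[int, TaxonKey] = {}
    for key in _resolve_query(at, name):
        status = assess_monophyly(key, at)
        for frag in status.fragment_nodes:
            if tree.is_ancestor(root, frag):
                targets[frag._id] = frag
                target_keys[frag._id] = key
            elif tree.is_ancestor(frag, root):
                # fragment covers the whole view: the view root is the hit
                targets[root._id] = root
                target_keys[root._id] = key
    if not targets:
        raise TaxonLookupError(
            f"taxon {name!r} has no fragment inside the current view"
        )
    ancestors: set[int] = set()
    for frag in targets.values():
        cur = frag.parent
        while cur is not None:
            ancestors.add(cur._id)
            if cur is root:
                break
            cur = cur.parent
    frontier: list[Node] = []
    stack = [root]
    while stack:
        cur = stack.pop()
        if cur._id in targets:
            frontier.append(cur)
        elif cur._id in ancestors:
            for child in reversed(cur.children):
                stack.append(child)
        else:
            frontier.extend(d._max_collapse_from(cur))
    d.frontier = frontier
    d._sort_frontier()
    shown = {n._id for n in frontier}
    d.query_keys = {i: k for i, k in target_keys.items() if i in shown}
    return d


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class ReportEntry:
    """One line of the hierarchical monophyly report."""

    path: str
    rank: str
    verdict: str  # "Yes" | "No" | "" (pseudo-taxa / sequence entries)
    n: int
    m: int
    is_singleton: bool = False

    @property
    def counts(self) -> str:
        return format_counts(self.n, self.m)


REPORT_MODES = ("total", "monophyly", "none", "unclassified")


def monophyly_report(
    at: AnnotatedTree,
    mode: str = "total",
    hide_singletons: bool = False,
    table: Optional[TaxonTable] = None,
) -> list[ReportEntry]:
    """The four-mode hierarchical taxon summary.

    ``total`` lists every named taxon with a Yes/No verdict; ``monophyly``
    only the monophyletic ones (optionally hiding trivially monophyletic
    singletons); ``none`` the non-monophyletic ones; ``unclassified`` the
    individual sequence entries whose lineage is incomplete (the ``m``
    augend of the ``{n+m}`` notation).
    """
    if mode not in REPORT_MODES:
        raise ArgumentError(f"unknown report mode {mode!r}; expected one of {REPORT_MODES}")
    table = table or at.taxon_table
    if mode == "unclassified":
        out = []
        for rec in table:
            if len(rec.key) != 7 or not rec.is_named:
                continue
            for leaf in at.member_leaves.get(tuple(rec.key), []):
                lineage = at.leaf_lineages[leaf.label]
                if not is_complete(lineage):
                    out.append(ReportEntry(
                        path=key_str(lineage.path) + "/" + lineage.strain_tag,
                        rank="T", verdict="", n=0, m=1,
                    ))
        return out

    statuses = full_assessment(at, table)
    out = []
    for rec in table:
        key = tuple(rec.key)
        if not rec.is_named:
            if mode == "total":
                out.append(ReportEntry(path=key_str(key), rank=rec.rank,
                                       verdict="", n=rec.n, m=rec.m))
            continue
        status = statuses.get(key)
        if status is None:
            continue  # no member leaf in the tree
        verdict = "Yes" if status.is_monophyletic else "No"
        singleton = status.state == "singleton"
        entry = ReportEntry(path=key_str(key), rank=rec.rank, verdict=verdict,
                            n=status.n_total, m=status.m_total,
                            is_singleton=singleton)
        if mode == "total":
            out.append(entry)
        elif mode == "monophyly" and verdict == "Yes":
            if not (hide_singletons and singleton):
                out.append(entry)
        elif mode == "none" and verdict == "No":
            out.append(entry)
    return out


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

def render(d: DisplayTree, format: str = "text") -> str:
    """Render a display state as indented text, JSON, or decorated Newick."""
    if format == "text":
        return _render_text(d)
    if format == "json":
        return _render_json(d)
    if format == "newick":
        return _render_newick(d)
    raise ArgumentError(f"unknown render format {format!r}")


def _display_skeleton(d: DisplayTree):
    """Nested (node, display_leaf_or_None, children) structure of the view."""
    frontier_ids = {n._id for n in d.frontier}

    def build(node: Node):
        if node._id in frontier_ids:
            return (node, d._leaf_info(node), [])
        return (node, None, [build(c) for c in node.children])

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, d.at.tree.n_nodes + 100))
    try:
        return build(d.view_root)
    finally:
        sys.setrecursionlimit(old)


def _render_text(d: DisplayTree) -> str:
    lines: list[str] = []

    def walk(entry, depth):
        node, info, children = entry
        indent = "  " * depth
        if info is not None:
            tag = _STYLE_TAGS[info.style]
            lines.append(f"{indent}{info.label}" + (f" {tag}" if tag else ""))
        else:
            key = d.at.deepest_key(node)
            name = _key_label(key) if key else "(root)"
            lines.append(f"{indent}+ {name}")
            for child in children:
                walk(child, depth + 1)

    walk(_display_skeleton(d), 0)
    return "\n".join(lines) + "\n"


def _render_json(d: DisplayTree) -> str:
    def walk(entry):
        node, info, children = entry
        if info is not None:
            return {
                "label": info.label,
                "style": info.style,
                "n": info.n,
                "m": info.m,
                "taxon": key_str(info.key) if info.key else None,
                "sequences": d.at.leaf_count(node),
            }
        return {
            "label": None,
            "children": [walk(c) for c in children],
        }

    return json.dumps(walk(_display_skeleton(d)), indent=2, sort_keys=True) + "\n"


def _render_newick(d: DisplayTree) -> str:
    def walk(entry) -> Node:
        node, info, children = entry
        if info is not None:
            return Node(label=info.label, length=node.length)
        clone = Node(label=None, length=node.length)
        for child in children:
            clone.add_child(walk(child))
        return clone

    return write_newick(PhyloTree(walk(_display_skeleton(d)))) + "\n"
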