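"""Taxonomy-phylogeny concordance: collapsibility and monophyly.

The central notions, all purely topological on the rooted tree:

* A leaf is *absorbable* into a taxon key K if, at every rank of K's path,
  the leaf's lineage either matches K's name or reads ``Unclassified``.
  (A leaf whose order and family are unassigned can therefore be swallowed
  by any clade of its domain/phylum/class without being a member.)
* A node is *collapsible* to the deepest key K such that every leaf below
  it is a member of K or absorbable into K.  If at some rank all leaves
  below read ``Unclassified`` the key extends with an ``Unclassified``
  component (a pseudo-taxon).  The only non-collapsible nodes are those
  mixing two or more named domains.
* A *fragment* of taxon K is a maximal node all of whose leaves are
  members of or absorbable into K and which contains at least one member.
  A taxon is monophyletic iff it has exactly one fragment; a taxon with a
  single member is trivially monophyletic ("singleton").

Per-fragment statistics: ``n_frag`` counts the fragment's members with
complete lineage, ``m_frag`` the remaining leaves under the fragment
(incomplete members plus absorbed strangers) — this is the ``{n+m}`` /
``(n_frag/n_total+m_frag)`` bookkeeping of the display layer.

``full_assessment`` computes fragments for every named taxon in one pass
over the tree using per-node per-rank agreement summaries;
``brute_force_monophyly`` re-derives the same answer by direct enumeration
of every node and serves as the independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Optional

from .errors import ArgumentError, DataError, TaxonLookupError
from .formats import UNCLASSIFIED, LineageTable, RankedLineage
from .taxonomy import (
    TaxonKey,
    TaxonTable,
    build_taxon_table,
    is_complete,
    key_str,
    lineage_keys,
)
from .tree import Node, PhyloTree

#: sentinel agreement codes: 0 = all Unclassified, 1 = one named value,
#: 2 = two or more distinct named values.
_CONFLICT = 2


@dataclass
class MonophylyStatus:
    """Monophyly verdict and fragment statistics for one taxon."""

    taxon: TaxonKey
    state: str  # "monophyletic" | "non_monophyletic" | "singleton"
    fragment_nodes: list[Node]
    fragment_counts: list[tuple[int, int]]  # (n_frag, m_frag) per fragment
    n_total: int
    m_total: int

    @property
    def is_monophyletic(self) -> bool:
        """Singletons count as monophyletic for reporting."""
        return self.state in ("monophyletic", "singleton")

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_nodes)

    def to_dict(self) -> dict:
        return {
            "taxon": key_str(self.taxon),
            "state": self.state,
            "n": self.n_total,
            "m": self.m_total,
            "fragments": [
                {"n": n, "m": m, "size": n + m}
                for n, m in self.fragment_counts
            ],
        }


class AnnotatedTree:
    """A tree whose every leaf carries a :class:`RankedLineage`.

    Built by :func:`annotate`.  Aggregates used by collapsibility and
    monophyly queries are computed lazily and cached; the object treats the
    tree as immutable once constructed.
    """

    def __init__(
        self,
        tree: PhyloTree,
        leaf_lineages: dict[str, RankedLineage],
        unmatched_leaves: Optional[list[str]] = None,
    ):
        self.tree = tree
        self.leaf_lineages = leaf_lineages
        self.unmatched_leaves = unmatched_leaves or []
        if len(leaf_lineages) != tree.n_leaves:
            raise DataError("every leaf must have exactly one lineage")
        self._assess_cache: dict[TaxonKey, MonophylyStatus] = {}
        self._build_aggregates()

    # ------------------------------------------------------------------
    # per-node aggregates
    # ------------------------------------------------------------------
    def _build_aggregates(self) -> None:
        tree = self.tree
        n = tree.n_nodes
        # per node, per rank 0..5: agreement code and the single named value
        self._code = [[0] * 6 for _ in range(n)]
        self._value: list[list[Optional[str]]] = [[None] * 6 for _ in range(n)]
        self._sp_code = [0] * n
        self._sp_value: list[Optional[str]] = [None] * n
        self._leafcount = [0] * n
        self._complete = [0] * n
        order = tree._preorder_reversed_children()
        for node in reversed(order):  # postorder
            i = node._id
            if node.is_leaf:
                lineage = self.leaf_lineages[node.label]
                for r, name in enumerate(lineage.ranks):
                    if name != UNCLASSIFIED:
                        self._code[i][r] = 1
                        self._value[i][r] = name
                self._sp_code[i] = 1
                self._sp_value[i] = lineage.species
                self._leafcount[i] = 1
                self._complete[i] = 1 if is_complete(lineage) else 0
            else:
                code_i, value_i = self._code[i], self._value[i]
                for child in node.children:
                    j = child._id
                    self._leafcount[i] += self._leafcount[j]
                    self._complete[i] += self._complete[j]
                    code_j, value_j = self._code[j], self._value[j]
                    for r in range(6):
                        cj = code_j[r]
                        if cj == 0:
                            continue
                        ci = code_i[r]
                        if ci == 0:
                            code_i[r] = cj
                            value_i[r] = value_j[r]
                        elif ci == 1:
                            if cj == _CONFLICT or value_j[r] != value_i[r]:
                                code_i[r] = _CONFLICT
                                value_i[r] = None
                    cj = self._sp_code[child._id]
                    ci = self._sp_code[i]
                    if ci == 0:
                        self._sp_code[i] = cj
                        self._sp_value[i] = self._sp_value[child._id]
                    elif ci == 1 and (
                        cj == _CONFLICT or self._sp_value[child._id] != self._sp_value[i]
                    ):
                        self._sp_code[i] = _CONFLICT
                        self._sp_value[i] = None

    # ------------------------------------------------------------------
    # derived indexes
    # ------------------------------------------------------------------
    @cached_property
    def member_leaves(self) -> dict[TaxonKey, list[Node]]:
        """Taxon key -> member leaf nodes (exact path match), all depths."""
        index: dict[TaxonKey, list[Node]] = {}
        for leaf in self.tree.leaves():
            lineage = self.leaf_lineages[leaf.label]
            for key in lineage_keys(lineage):
                index.setdefault(key, []).append(leaf)
        return index

    @cached_property
    def taxon_table(self) -> TaxonTable:
        """Taxon table over the leaves actually present in the tree."""
        table = LineageTable(
            entries={leaf.label: self.leaf_lineages[leaf.label]
                     for leaf in self.tree.leaves()}
        )
        return build_taxon_table(table)

    def leaf_count(self, node: Node) -> int:
        return self._leafcount[node._id]

    def complete_count(self, node: Node) -> int:
        return self._complete[node._id]

    # ------------------------------------------------------------------
    # collapsibility
    # ------------------------------------------------------------------
    def deepest_key(self, node: Node) -> Optional[TaxonKey]:
        """Deepest taxon key the node is collapsible to, or None.

        None only for the degenerate case of a node mixing two or more
        named domains.
        """
        i = node._id
        code, value = self._code[i], self._value[i]
        if code[0] == _CONFLICT:
            return None
        key: list[str] = []
        for r in range(6):
            c = code[r]
            if c == _CONFLICT:
                break
            key.append(value[r] if c == 1 else UNCLASSIFIED)
        return tuple(key)

    def is_candidate(self, node: Node, key: TaxonKey) -> bool:
        """True iff every leaf under node matches or is absorbable into key."""
        i = node._id
        code, value = self._code[i], self._value[i]
        for r, comp in enumerate(key):
            if r == 6:  # species component: never absorbable
                return self._sp_code[i] == 1 and self._sp_value[i] == comp
            c = code[r]
            if comp == UNCLASSIFIED:
                if c != 0:
                    return False
            elif c == _CONFLICT or (c == 1 and value[r] != comp):
                return False
        return True


def annotate(
    tree: PhyloTree, table: LineageTable
) -> tuple[AnnotatedTree, list[str]]:
    """Bind lineage-table entries to tree leaves.

    Binding key: exact strain-tag equality first, then the accession (the
    substring after the final ``__``).  Leaves without a table entry get an
    all-``Unclassified`` supra-specific lineage derived from their label;
    table entries absent from the tree produce warnings.
    """
    warnings: list[str] = []
    by_accession: dict[str, RankedLineage] = {}
    for tag, lineage in table.entries.items():
        if "__" in tag:
            acc = tag.rsplit("__", 1)[-1]
            if acc in by_accession:
                by_accession[acc] = None  # type: ignore[assignment] # ambiguous
            else:
                by_accession[acc] = lineage

    leaf_lineages: dict[str, RankedLineage] = {}
    unmatched: list[str] = []
    bound_tags: set[str] = set()
    for leaf in tree.leaves():
        label = leaf.label
        lineage = table.entries.get(label)
        if lineage is None and "__" in label:
            acc = label.rsplit("__", 1)[-1]
            lineage = by_accession.get(acc)
        if lineage is not None:
            leaf_lineages[label] = lineage
            bound_tags.add(lineage.strain_tag)
        else:
            species = label.rsplit("__", 1)[0] if "__" in label else label
            leaf_lineages[label] = RankedLineage(
                ranks=(UNCLASSIFIED,) * 6, species=species, strain_tag=label
            )
            unmatched.append(label)
            warnings.append(
                f"leaf {label!r} has no lineage entry; treated as fully Unclassified"
            )
    if not bound_tags:
        raise DataError(
            "no tree leaf matched any lineage-table entry; "
            "tree and table appear to be unrelated inputs"
        )
    for tag in table.entries:
        if tag not in bound_tags:
            warnings.append(f"lineage entry {tag!r} not found in the tree; ignored")
    return AnnotatedTree(tree, leaf_lineages, unmatched), warnings


def collapsible_as(
    node: Node, at: AnnotatedTree
) -> Optional[tuple[TaxonKey, int, int]]:
    """Deepest taxon key node collapses to, with its {n+m} counts.

    ``n`` counts leaves under the node that are complete-lineage members of
    the key; ``m`` counts the rest (incomplete members plus absorbed
    leaves).  Returns None only when the node mixes several named domains.
    """
    key = at.deepest_key(node)
    if key is None:
        return None
    n = at.complete_count(node)
    m = at.leaf_count(node) - n
    return key, n, m


def _fragments(
    at: AnnotatedTree, key: TaxonKey, members: list[Node]
) -> dict[int, Node]:
    """Map fragment-root node id -> node, for the given member leaves.

    Each member's fragment root is its highest ancestor for which every
    leaf below matches or absorbs into ``key``; candidacy is contiguous
    along root-ward paths, so a memoized upward walk suffices.
    """
    memo: dict[int, Node] = {}
    roots: dict[int, Node] = {}
    for leaf in members:
        if leaf._id in memo:
            continue
        chain = [leaf]
        cur = leaf
        while True:
            parent = cur.parent
            if parent is None:
                break
            if parent._id in memo:
                cur = memo[parent._id]
                break
            if not at.is_candidate(parent, key):
                break
            chain.append(parent)
            cur = parent
        root = cur if cur._id not in memo else memo[cur._id]
        for node in chain:
            memo[node._id] = root
        roots[root._id] = root
    return roots


def _status_from_fragments(
    at: AnnotatedTree, key: TaxonKey, members: list[Node], roots: dict[int, Node]
) -> MonophylyStatus:
    frag_nodes = sorted(roots.values(), key=lambda nd: nd._tin)
    counts = []
    for node in frag_nodes:
        n = at.complete_count(node)
        m = at.leaf_count(node) - n
        counts.append((n, m))
    n_total = sum(c[0] for c in counts)
    m_total = sum(c[1] for c in counts)
    if len(members) == 1:
        state = "singleton"
    elif len(frag_nodes) == 1:
        state = "monophyletic"
    else:
        state = "non_monophyletic"
    return MonophylyStatus(
        taxon=tuple(key),
        state=state,
        fragment_nodes=frag_nodes,
        fragment_counts=counts,
        n_total=n_total,
        m_total=m_total,
    )


def assess_monophyly(taxon: TaxonKey, at: AnnotatedTree) -> MonophylyStatus:
    """Fragments, state and {n+m} statistics for one taxon."""
    key = tuple(taxon)
    cached = at._assess_cache.get(key)
    if cached is not None:
        return cached
    members = at.member_leaves.get(key)
    if not members:
        raise TaxonLookupError(f"taxon {key_str(key)!r} has no member leaf in the tree")
    roots = _fragments(at, key, members)
    status = _status_from_fragments(at, key, members, roots)
    at._assess_cache[key] = status
    return status


def full_assessment(
    at: AnnotatedTree, table: Optional[TaxonTable] = None
) -> dict[TaxonKey, MonophylyStatus]:
    """One :class:`MonophylyStatus` per named taxon with members in the tree.

    Pseudo-taxa (terminal ``Unclassified``) carry counts in the taxon table
    but receive no monophyly verdict, mirroring the report filters.
    """
    table = table or at.taxon_table
    out: dict[TaxonKey, MonophylyStatus] = {}
    for rec in table.named_records():
        key = tuple(rec.key)
        if key not in at.member_leaves:
            continue
        out[key] = assess_monophyly(key, at)
    return out


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def _leaf_absorbable(lineage: RankedLineage, key: TaxonKey) -> bool:
    path = lineage.path
    for r, comp in enumerate(key):
        if r == 6:
            if path[6] != comp:
                return False
        elif path[r] != comp and path[r] != UNCLASSIFIED:
            return False
    return True


def _leaf_member(lineage: RankedLineage, key: TaxonKey) -> bool:
    return lineage.path[: len(key)] == tuple(key)


def brute_force_monophyly(taxon: TaxonKey, at: AnnotatedTree) -> MonophylyStatus:
    """Oracle: same contract as :func:`assess_monophyly`, by enumeration.

    Every tree node's leaf set is tested directly against the definition;
    intended for test-scale trees (a few hundred leaves).
    """
    key = tuple(taxon)
    tree = at.tree
    leafsets: dict[int, list[Node]] = {}
    order = tree._preorder_reversed_children()
    for node in reversed(order):
        if node.is_leaf:
            leafsets[node._id] = [node]
        else:
            acc: list[Node] = []
            for child in node.children:
                acc.extend(leafsets[child._id])
            leafsets[node._id] = acc

    members = [
        leaf for leaf in tree.leaves()
        if _leaf_member(at.leaf_lineages[leaf.label], key)
    ]
    if not members:
        raise TaxonLookupError(f"taxon {key_str(key)!r} has no member leaf in the tree")

    candidate: dict[int, bool] = {}
    for node in tree.preorder():
        candidate[node._id] = all(
            _leaf_absorbable(at.leaf_lineages[leaf.label], key)
            for leaf in leafsets[node._id]
        )
    roots: dict[int, Node] = {}
    for node in tree.preorder():
        if not candidate[node._id]:
            continue
        parent = node.parent
        if parent is not None and candidate[parent._id]:
            continue  # not maximal
        if any(_leaf_member(at.leaf_lineages[leaf.label], key)
               for leaf in leafsets[node._id]):
            roots[node._id] = node
    return _status_from_fragments(at, key, members, roots)
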