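"""Collapse/expand state machine, search, reports and label rendering."""

import json
import random

import pytest

from monotax import (
    ArgumentError,
    TaxonLookupError,
    UNCLASSIFIED,
    annotate,
    format_counts,
    format_fraction,
    maximal_collapse,
    monophyly_report,
    read_newick,
    render,
    search_query,
    set_top_node,
)
from monotax.fixtures import FixtureSpec, generate

from conftest import lin, table_of


def _world(**kw):
    spec = FixtureSpec(**kw)
    table, tree, truth = generate(spec)
    at, _ = annotate(tree, table)
    return at, truth


class TestLabelGrammar:
    def test_counts_elision_rules(self):
        assert format_counts(15, 0) == "{15}"
        assert format_counts(0, 9) == "{0+9}"
        assert format_counts(422, 7) == "{422+7}"

    def test_fraction_notation(self):
        assert format_fraction(2282, 11156, 143) == "(2282/11156+143)"

    def test_mono_label_no_augend(self, two_domain_world):
        at, _, _ = two_domain_world
        d = maximal_collapse(at)
        labels = [l.label for l in d.display_leaves()]
        assert labels == ["<D>Archaea{4}", "<D>Bacteria{4}"]

    def test_pseudo_taxon_zero_n_label(self):
        u1 = lin(p=UNCLASSIFIED, c=UNCLASSIFIED, o=UNCLASSIFIED,
                 f=UNCLASSIFIED, g=UNCLASSIFIED, species="Mys_a", acc="U1")
        u2 = lin(p=UNCLASSIFIED, c=UNCLASSIFIED, o=UNCLASSIFIED,
                 f=UNCLASSIFIED, g=UNCLASSIFIED, species="Mys_b", acc="U2")
        out = lin(d="Archaea", acc="A1")
        table = table_of(u1, u2, out)
        tree = read_newick(
            f"(({u1.strain_tag},{u2.strain_tag}),{out.strain_tag});")
        at, _ = annotate(tree, table)
        d = maximal_collapse(at)
        labels = {l.label for l in d.display_leaves()}
        assert "<G>Unclassified{0+2}" in labels

    def test_fragment_fraction_label(self):
        """A split phylum's fragments carry (n_frag/n_total+m_frag)."""
        a1, a2, a3 = (lin(p="PhyA", c=f"Cla{i}", o=f"Ord{i}", f=f"Fam{i}",
                          g=f"Gen{i}", acc=f"A{i}") for i in "123")
        b1, b2 = (lin(d="Archaea", p="PhyB", c="CB", o="OB", f="FB",
                      g=f"Hen{i}", acc=f"B{i}") for i in "12")
        table = table_of(a1, a2, a3, b1, b2)
        tree = read_newick(
            f"(({a1.strain_tag},{a2.strain_tag}),"
            f"(({b1.strain_tag},{a3.strain_tag}),{b2.strain_tag}));")
        at, _ = annotate(tree, table)
        d = maximal_collapse(at)
        labels = [l.label for l in d.display_leaves()]
        assert "<P>PhyA(2/3+0)" in labels  # big fragment: 2 of 3 complete members
        assert "<G>Gen3(1/3+0)" not in labels  # the stray leaf labels at its own depth
        frag_styles = {l.label: l.style for l in d.display_leaves()}
        assert frag_styles["<P>PhyA(2/3+0)"] == "non_mono"


class TestMaximalCollapse:
    def test_two_domain_view(self, two_domain_world):
        at, _, _ = two_domain_world
        d = maximal_collapse(at)
        assert len(d.frontier) == 2
        assert all(l.style == "mono" for l in d.display_leaves())

    def test_single_leaf_tree_plain(self):
        table = table_of(lin(acc="A1"))
        tree = read_newick(f"{list(table.entries)[0]};")
        at, _ = annotate(tree, table)
        d = maximal_collapse(at)
        leaves = d.display_leaves()
        assert len(leaves) == 1 and leaves[0].style == "plain"

    def test_leaf_conservation(self, two_domain_world):
        at, _, tree = two_domain_world
        d = maximal_collapse(at)
        assert sum(at.leaf_count(n) for n in d.frontier) == tree.n_leaves

    @pytest.mark.parametrize("seed", range(4))
    def test_minimality_exhaustive(self, seed):
        """Greedy collapse attains the minimum display-leaf count over all
        valid collapses (exhaustive enumeration on tiny trees)."""
        at, _ = _world(seed=seed, fanout=(2, 1, 1, 1, 1, 2),
                       species_per_genus=2, planted_moves=seed % 2)

        def all_frontiers(node):
            options = []
            if node.is_leaf or at.deepest_key(node) is not None:
                options.append([node])
            if not node.is_leaf:
                child_sets = [all_frontiers(c) for c in node.children]
                combos = [[]]
                for cs in child_sets:
                    combos = [acc + pick for acc in combos for pick in cs]
                options.extend(combos)
            return options

        best = min(len(f) for f in all_frontiers(at.tree.root))
        d = maximal_collapse(at)
        assert len(d.frontier) == best


class TestExpandCollapse:
    def test_expand_reveals_children_only(self, two_domain_world):
        at, _, _ = two_domain_world
        d = maximal_collapse(at)
        archaea, bacteria = d.frontier
        d.expand(archaea)
        labels = [l.label for l in d.display_leaves()]
        assert "<D>Bacteria{4}" in labels
        assert "<P>ArcPhy1{2}" in labels and "<P>ArcPhy2{2}" in labels

    def test_expand_then_collapse_roundtrip(self, two_domain_world):
        at, _, _ = two_domain_world
        d = maximal_collapse(at)
        reference = maximal_collapse(at)
        node = d.frontier[0]
        d.expand(node)
        assert d != reference
        d.collapse(node)
        assert d == reference

    def test_expand_singleton_warns_noop(self):
        table = table_of(lin(acc="A1"), lin(d="Archaea", acc="A2"))
        tags = list(table.entries)
        tree = read_newick(f"({tags[0]},{tags[1]});")
        at, _ = annotate(tree, table)
        d = maximal_collapse(at)
        before = list(d.frontier)
        d.expand(d.frontier[0])
        assert d.frontier == before and d.warnings

    def test_collapse_already_collapsed_noop(self, two_domain_world):
        at, _, _ = two_domain_world
        d = maximal_collapse(at)
        snapshot = list(d.frontier)
        d.collapse(d.frontier[0])
        assert d.frontier == snapshot


class TestSearchQuery:
    def test_monophyletic_class_single_green_leaf(self, two_domain_world):
        at, _, _ = two_domain_world
        d = search_query(at, "ArcC1a")
        hits = [l for l in d.display_leaves() if l.style == "query_hit"]
        assert len(hits) == 1
        assert hits[0].label == "<C>ArcC1a{1}"

    def test_split_taxon_shows_all_fragments(self):
        at, truth = _world(seed=4, planted_moves=2)
        split = truth.non_monophyletic[0].split("/")
        name = split[-1]
        d = search_query(at, "/".join(split) and name)
        hits = [l for l in d.display_leaves() if l.style == "query_hit"]
        assert len(hits) >= 2

    def test_rank_qualified_query(self, two_domain_world):
        at, _, _ = two_domain_world
        d = search_query(at, "<P>ArcPhy1")
        hits = [l for l in d.display_leaves() if l.style == "query_hit"]
        assert hits and all(h.key is not None and len(h.key) == 2 for h in hits)

    def test_unknown_name_lookup_error(self, two_domain_world):
        at, _, _ = two_domain_world
        with pytest.raises(TaxonLookupError):
            search_query(at, "zzz")

    def test_near_misses_listed(self, two_domain_world):
        at, _, _ = two_domain_world
        with pytest.raises(TaxonLookupError) as exc:
            search_query(at, "ArcPhy")
        assert "ArcPhy1" in str(exc.value)


class TestTopNode:
    def test_root_equals_maximal_collapse(self, two_domain_world):
        at, _, tree = two_domain_world
        d = maximal_collapse(at)
        assert set_top_node(d, tree.root) == d

    def test_subtree_view_excludes_other_domain(self, two_domain_world):
        at, _, tree = two_domain_world
        d = maximal_collapse(at)
        archaea_node = tree.root.children[0]
        sub = set_top_node(d, archaea_node)
        assert all(l.key[0] == "Archaea" for l in sub.display_leaves())

    def test_leaf_top_node_rejected(self, two_domain_world):
        at, _, tree = two_domain_world
        d = maximal_collapse(at)
        with pytest.raises(ArgumentError):
            set_top_node(d, tree.leaves()[0])


class TestReport:
    def test_concordant_none_mode_empty(self):
        at, _ = _world(seed=1)
        assert monophyly_report(at, mode="none") == []

    def test_hide_singletons_arithmetic(self):
        at, _ = _world(seed=2, species_per_genus=1)
        full = monophyly_report(at, mode="monophyly")
        hidden = monophyly_report(at, mode="monophyly", hide_singletons=True)
        n_singletons = sum(1 for e in full if e.is_singleton)
        assert len(full) - len(hidden) == n_singletons
        assert n_singletons > 0

    def test_unclassified_mode_counts_incomplete_entries(self):
        at, _ = _world(seed=3, unclassified_rate=0.25)
        from monotax import is_complete
        u = sum(1 for l in at.leaf_lineages.values() if not is_complete(l))
        assert len(monophyly_report(at, mode="unclassified")) == u
        assert u > 0

    def test_total_mode_hierarchical_order(self, two_domain_world):
        at, _, _ = two_domain_world
        entries = monophyly_report(at, mode="total")
        pos = {e.path: i for i, e in enumerate(entries)}
        for e in entries:
            parent = "/".join(e.path.split("/")[:-1])
            if parent:
                assert pos[parent] < pos[e.path]
        assert all(e.verdict == "Yes" for e in entries)


class TestRender:
    def test_text_contains_style_tags(self, two_domain_world):
        at, _, _ = two_domain_world
        text = render(maximal_collapse(at), "text")
        assert "<D>Archaea{4} [M]" in text

    def test_json_stable(self, two_domain_world):
        at, _, _ = two_domain_world
        d = maximal_collapse(at)
        a = render(d, "json")
        b = render(d, "json")
        assert a == b and json.loads(a)["children"]

    def test_newick_labels_quoted(self, two_domain_world):
        at, _, _ = two_domain_world
        nk = render(maximal_collapse(at), "newick")
        assert "'<D>Archaea{4}'" in nk
        read_newick(nk)  # parses back

    def test_unknown_format_rejected(self, two_domain_world):
        at, _, _ = two_domain_world
        with pytest.raises(ArgumentError):
            render(maximal_collapse(at), "svg")


class TestStateMachineSoundness:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_operation_sequences_keep_partition(self, seed):
        """Any expand/collapse/query/top-node sequence keeps the frontier a
        partition of the leaves under the view root."""
        at, _ = _world(seed=seed, planted_moves=seed % 3,
                       unclassified_rate=0.1)
        rng = random.Random(seed)
        d = maximal_collapse(at)
        names = [r.key[-1] for r in at.taxon_table.named_records()]
        for _ in range(40):
            op = rng.choice(["expand", "collapse", "query", "top", "reset"])
            try:
                if op == "expand" and d.frontier:
                    d.expand(rng.choice(d.frontier))
                elif op == "collapse":
                    node = rng.choice(list(at.tree.preorder()))
                    d.collapse(node)
                elif op == "query":
                    d = search_query(at, rng.choice(names))
                elif op == "top":
                    internal = [n for n in at.tree.preorder() if not n.is_leaf]
                    d = set_top_node(d, rng.choice(internal))
                else:
                    d = maximal_collapse(at)
            except (ArgumentError, TaxonLookupError):
                continue
            total = sum(at.leaf_count(n) for n in d.frontier)
            assert total == at.leaf_count(d.view_root)
            # no display leaf is an ancestor of another
            for x in d.frontier:
                for y in d.frontier:
                    if x is not y:
                        assert not at.tree.is_ancestor(x, y)
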