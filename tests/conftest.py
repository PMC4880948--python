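"""Shared fixtures and tiny hand-built worlds for the test suite."""

from __future__ import annotations

import pytest

from monotax import (
    LineageTable,
    RankedLineage,
    UNCLASSIFIED,
    annotate,
    read_newick,
)

#: The canonical fully-classified example lineage string.
STREPTOMYCES_MARKUP = (
    "<D>Bacteria<P>Actinobacteria<C>Actinobacteria<O>Streptomycetales"
    "<F>Streptomycetaceae<G>Streptomyces<S>Streptomyces_longisporoflavus"
    "<T>Streptomyces_longisporoflavus__DQ442520"
)


def lin(d="Bacteria", p="PhyA", c="ClaA", o="OrdA", f="FamA", g="GenA",
        species=None, acc="X1"):
    """Build a RankedLineage with short defaults."""
    species = species or f"{g}_sp"
    return RankedLineage(
        ranks=(d, p, c, o, f, g),
        species=species,
        strain_tag=f"{species}__{acc}",
    )


def table_of(*lineages) -> LineageTable:
    return LineageTable(entries={ln.strain_tag: ln for ln in lineages})


@pytest.fixture
def two_domain_world():
    """Two domains, two phyla each, fully concordant tree of 8 leaves.

    Leaf labels are the strain tags; the topology nests every taxon as a
    clade.
    """
    rows = []
    for dom in ("Archaea", "Bacteria"):
        for phy in ("1", "2"):
            for i in ("a", "b"):
                g = f"{dom[:3]}P{phy}G{i}"
                rows.append(lin(d=dom, p=f"{dom[:3]}Phy{phy}",
                                c=f"{dom[:3]}C{phy}{i}", o=f"{dom[:3]}O{phy}{i}",
                                f=f"{dom[:3]}F{phy}{i}", g=g, acc=f"{g}X"))
    table = table_of(*rows)
    tags = [r.strain_tag for r in rows]
    newick = (
        f"((({tags[0]},{tags[1]}),({tags[2]},{tags[3]})),"
        f"(({tags[4]},{tags[5]}),({tags[6]},{tags[7]})));"
    )
    tree = read_newick(newick)
    at, warnings = annotate(tree, table)
    assert not warnings
    return at, table, tree


@pytest.fixture
def absorption_world():
    """One domain; 2 leaves of phylum Cyano + 1 phylum-Unclassified leaf
    inside their clade, + an outgroup phylum."""
    a = lin(d="Bacteria", p="Cyano", c="C1", o="O1", f="F1", g="G1", acc="A1")
    b = lin(d="Bacteria", p="Cyano", c="C1", o="O1", f="F1", g="G2", acc="A2")
    u = RankedLineage(ranks=("Bacteria",) + (UNCLASSIFIED,) * 5,
                      species="Mystery_sp", strain_tag="Mystery_sp__U1")
    out = lin(d="Bacteria", p="Other", c="C9", o="O9", f="F9", g="G9", acc="A9")
    table = table_of(a, b, u, out)
    newick = (f"((({a.strain_tag},{b.strain_tag}),{u.strain_tag}),"
              f"{out.strain_tag});")
    tree = read_newick(newick)
    at, warnings = annotate(tree, table)
    assert not warnings
    return at, table, tree
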