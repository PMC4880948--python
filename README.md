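# monotax

**Taxonomy–phylogeny concordance on rooted trees**: collapse a large rooted
phylogeny (e.g. a 16S rRNA tree of all prokaryotic type strains) against an
eight-rank reference taxonomy, assess the monophyly of every taxon, explore
the tree through collapse/expand/search views, and test trial *lineage
modifications* by re-collapsing — as a library and CLI rather than a web GUI.

## The problem

Curated reference trees such as the All-Species Living Tree (LTP) ship as a
Newick file of ~12,000 leaves plus a lineage table assigning every sequence a
name at each of the eight ranks — Domain, Phylum, Class, Order, Family,
Genus, Species, sTrain (`<D><P><C><O><F><G><S><T>`), with the specifier
`Unclassified` marking missing assignments. Taxonomists want to know, taxon
by taxon, whether the tree agrees with the taxonomy: is each named taxon a
single clade (*monophyletic*), and if not, which outlier sequences break it
and which re-classification would fix it?

## The model

All computations are purely topological on the rooted tree:

* A leaf is **absorbable** into taxon *T* if at every rank of *T*'s path its
  lineage either matches or reads `Unclassified`.
* A **fragment** of *T* is a maximal node whose leaves are all members of or
  absorbable into *T* (containing at least one member). *T* is
  **monophyletic** iff it has exactly one fragment; a single-sequence taxon
  is trivially monophyletic.
* A collapsed branch is labelled `taxon{n+m}` — *n* members with complete
  lineage, *m* incomplete plus absorbed sequences — written `{n}` when
  m = 0 and `{0+m}` when n = 0. A fragment of a non-monophyletic taxon is
  labelled `taxon(n_frag/n_total+m_frag)`, e.g. `<D>Bacteria(2282/11156+143)`.
* Monophyletic collapsed taxa are tagged `[M]` (the classic red),
  non-monophyletic `[N]` (blue), search-query hits `[Q]` (green).

A **lineage modification** is a rewrite rule `old_lineage new_lineage`
(one space-separated pair per line) that changes only the supra-specific
ranks of one species — species and strain names are always preserved — so
that a proposed re-classification can be evaluated by re-collapsing.

## Worked example

The package ships a deterministic fixture generator (a taxonomy, a tree
concordant with it, and *k* planted prune-regraft outliers with known
ground truth):

```sh
$ monotax simulate --seed 11 --planted-moves 1 --with-repair --out-dir demo
fixture with 288 leaves written to demo

$ monotax view --tree demo/fixture.tree.newick --lineages demo/fixture.lineages.tsv
+ (root)
  <D>Dom002(143/144+0) [N]
  + (root)
    <D>Dom001(96/144+0) [N]
    + (root)
      + (root)
        + (root)
          + (root)
            <F>Fam004(4/6+0) [N]
            + (root)
              Gen011_sp2__A00022
              + (root)
                Gen011_sp1__A00021
                Gen129_sp2__A00258
          <F>Fam003{6} [M]
        <O>Ord001{12} [M]
      <C>Cla002{24} [M]
```

One leaf (`Gen129_sp2__A00258`) was moved from domain 2 into a family of
domain 1: both domains are split (`[N]`, fraction labels — e.g. 143 of
Dom002's 144 complete-lineage members sit in its big fragment), and the
view stays maximally collapsed everywhere the tree and taxonomy agree
(`Fam003{6} [M]`: 6 members, all complete, one clade). Applying the
generated repair file re-classifies the outlier to its landing
neighborhood:

```sh
$ monotax modify --tree demo/fixture.tree.newick \
    --lineages demo/fixture.lineages.tsv \
    --modifications demo/fixture.repair.txt
{
  "rules": [ {"species": "Gen129_sp2", "matched": 1} ],
  "non_monophyletic_before": [ "Dom001", ..., "Dom002/.../Gen129" ],
  "non_monophyletic_after": []
}
```

Twelve taxa (the outlier's source path and the invaded path, at every rank)
were non-monophyletic before; none remain after the single rewrite — the
library's closed loop. Other subcommands: `monotax report` (hierarchical
Yes/No monophyly list, modes `total|monophyly|none|unclassified`) and
`monotax view --query NAME | --top-node NAME | --expand NAME` for scripted
exploration; `--format {text,json,newick}` selects the renderer.

The same functionality is available as a library: `read_newick`,
`read_lineage_table`, `annotate`, `full_assessment`, `maximal_collapse`,
`search_query`, `apply_modifications`, `monotax.fixtures.generate`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch at the given
seed: it generates a ~300-leaf world with 5 planted violations, verifies
the assessment against the generator's ground truth, applies the repairing
modification file and checks that universal monophyly is restored, then
writes the results JSON to `--out`.

See `docs/methods.md` for the precise definitions, parameter defaults,
numerical choices and known limitations.
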