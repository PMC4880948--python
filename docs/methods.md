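# Methods

## Scope and objects

The package compares a fixed rooted phylogeny with an eight-rank reference
taxonomy. The tree (`PhyloTree`) is read from Newick with child order and
branch lengths preserved; branch lengths are never used by any computation
— the method is purely topological. The taxonomy is a table mapping each
strain tag (`species__accession`) to a `RankedLineage`: six supra-specific
names (Domain, Phylum, Class, Order, Family, Genus), a species and a strain
name. `Unclassified` is a reserved specifier for a missing assignment and
never occurs at species or strain level. A lineage is *complete* iff none
of the six supra-specific ranks is `Unclassified`.

A *taxon* is identified by its full path from Domain down to some rank,
never by its terminal name alone — two `Unclassified` families under
different orders are distinct records. Records whose terminal name is
`Unclassified` are *pseudo-taxa*: they carry counts but receive no
monophyly verdict (they surface through the `unclassified` report mode).

## Leaf binding

Tree leaves are bound to table entries by exact strain-tag equality first,
then by the accession (the substring after the final `__`). Unbound leaves
are kept and assigned an all-`Unclassified` supra-specific lineage derived
from their label; table entries absent from the tree are warned about and
ignored. Binding zero leaves is an error (unrelated inputs).

## Absorption, collapsibility, fragments

- A leaf **matches** taxon key K when its lineage equals K's name at every
  rank of K's path; it is **absorbable** into K when, at every rank of K's
  path, it either matches or reads `Unclassified`. Absorption at the
  species rank is impossible (species names are always present).
- The **deepest collapsible key** of a node is built rank by rank over the
  leaves below: one distinct named value extends the key with it; no named
  value extends it with `Unclassified` (pseudo component); two or more
  distinct named values stop the key. Only a node mixing several named
  domains is not collapsible at all. Counts for a collapsed node are
  `n` = leaves below with complete lineage (these are exactly the complete
  members of the key) and `m` = all remaining leaves (incomplete members
  plus absorbed strangers).
- A **fragment** of taxon K is a maximal node all of whose leaves match or
  absorb into K and which contains at least one matching member. Because
  "all leaves absorbable" is closed under taking descendants, each member
  leaf has a unique highest admissible ancestor; fragments are computed by
  a memoised upward walk from every member using per-node per-rank
  agreement summaries built in one post-order pass (O(nodes × ranks)).
  `brute_force_monophyly` recomputes the same contract by enumerating every
  node and testing the definition directly; it is the independent oracle in
  the test suite and for fixture ground truth.
- A taxon is **monophyletic** iff it has exactly one fragment; a taxon with
  exactly one member is a **singleton** and counts as monophyletic in all
  reports. Monophyly is read on the rooted tree only (no unrooted
  complement reading): the displayed tree is rooted at the basal split.

Per-fragment statistics: `n_frag` = complete members in the fragment,
`m_frag` = remaining leaves under the fragment. Totals are the sums over
fragments; every complete member of K lies in some fragment, so
`n_total` equals the tree-wide complete-member count used as the
denominator of the fraction notation.

## Display semantics

`maximal_collapse` works greedily top-down: a node becomes a display leaf
iff it is collapsible, else its children are visited. On a two-domain tree
this yields exactly two display leaves regardless of splits deeper inside —
fragments of broken taxa surface in query and expanded views. Labels use
the deepest collapsible key; query hits are labelled at the *queried*
taxon's rank instead (matching the classic viewer's green
`<C>Name{n}` results). Label grammar: `{n+m}`, elided to `{n}` when m = 0
and written `{0+m}` when n = 0; fragments of non-monophyletic taxa read
`(n_frag/n_total+m_frag)` with the `+m_frag` part always present. Style
precedence: query hit (green) over monophyletic (red) / non-monophyletic
(blue); single sequences and pseudo-taxa are plain.

`search_query` expands every ancestor of every fragment of the matched
taxa, collapses each fragment into one green display leaf, and maximally
collapses all branches off those ancestor paths. Matching is
case-insensitive on the terminal name after space→underscore
normalization; `<P>Name` restricts to a rank. `set_top_node` re-roots the
view at an internal node and re-collapses. Expanding a single-sequence
leaf is a warned no-op; expanding then collapsing the same node restores
the identical display state.

## Lineage modifications

A rule rewrites the six supra-specific ranks of entries whose (Domain..
Genus, species) equals the rule's old lineage exactly; species and strain
names are never changed. Rules written without the leading `<D>` marker —
the customary shorthand — match any domain and leave the entry's domain
untouched. Rules apply in file order, each entry at most once (first match
wins); zero-match rules produce warnings, not errors, so a cleared or
re-submitted file behaves like an undo. `apply_modifications` is pure: it
returns a new table plus per-rule match counts.

## Synthetic fixtures

`fixtures.generate(FixtureSpec)` emits a taxonomy by recursive fan-out
(defaults: 2 domains × 3 phyla × 2 classes × 2 orders × 2 families ×
3 genera × 2 species × 1 strain = 288 leaves, a desk-scale stand-in for
the ~12,000-leaf real input), a tree concordant with it (taxa nested as
clades, random binary resolution inside each taxon, branch lengths uniform
0.01–0.2), and then:

- **Planted moves** (`planted_moves = k`): k leaves pruned and regrafted
  onto uniformly random admissible edges — never the root edge, never
  inside the source genus (which would not break monophyly), never into a
  subtree already holding a moved leaf; donors must leave ≥ 2 leaves in
  their genus. Each move records the rewrite that repairs it: the longest
  common supra-specific prefix of the landing subtree's true lineages,
  padded with `Unclassified`. Applying the generated repair file restores
  universal monophyly (the closed-loop property the test suite pins).
- **Unclassified blanking** (`unclassified_rate = u`): applied to the table
  after tree construction, so topology is untouched. The rate is a
  per-rank hazard for a *contiguous rank-downward* blank: scanning from
  Domain to Genus, the first rank that fires (probability u each) and all
  deeper supra-specific ranks become `Unclassified`. Independent per-slot
  blanking would create lineages classified below an unclassified rank;
  the path taxa of such lineages are scattered across the tree and
  genuinely non-monophyletic, which would destroy the guarantee that a
  concordant world assesses 100% monophyletic. Contiguous downward
  incompleteness is also the shape real unclassified lineages
  overwhelmingly take. What a green concordance test therefore does *not*
  establish: behavior on lineages with interior `Unclassified` ranks,
  which the assessment itself handles (they are exercised directly in unit
  tests) but the generator does not emit.

Ground truth for a fixture is assessed with the brute-force oracle up to
1500 leaves; above that the fast implementation is used (recorded in the
`oracle` field) since the quadratic oracle cannot fit the performance
envelope at 12,000 leaves.

All randomness flows from one `random.Random(seed)`; identical specs yield
byte-identical Newick, table and ground-truth outputs.

What the generator does not emulate: sequence evolution, branch-length
realism, rate variation, label noise beyond unbound leaves, and real
nomenclature (names are `Dom001`, `Phy003`, `Gen129_sp2`, …).

## Numerical and degenerate-input choices

- Name normalization: whitespace runs become `_` on read; comparisons are
  case-sensitive afterwards (queries are case-insensitive).
- Newick: trailing semicolon required (appended if missing), quoting with
  `'…'` on write for labels containing structural characters; duplicate
  leaf labels are a data error naming the label; unbalanced parentheses
  are a parse error carrying a character offset.
- Lineage tables: tab-separated with header and columns
  `id`, `species_name`, `lineage` (semicolon-joined Domain..Genus) by
  default; a YAML dialect file remaps names and separators. Empty lineage
  fields become all-`Unclassified` with a warning; short paths are padded
  with `Unclassified`.
- Branch length serialization uses `%.10g` (round-trip stable for the
  generator's 4-decimal lengths).
- If the whole tree is collapsible to one key, the root is the single
  fragment; a 1-leaf tree displays as one plain leaf.
- All traversals are iterative; trees of tens of thousands of leaves never
  touch the recursion limit (the renderer raises it locally for its
  nested-structure walk).

## Performance

One post-order pass builds all per-node summaries; full assessment of all
~17,000 taxa on a 12,000-leaf fixture, including generation and maximal
collapse, runs in ≈1–2 s on one CPU (the acceptance suite enforces < 60 s).

## Known limitations

- Monophyly is binary; no paraphyly/polyphyly distinction is made.
- Modification rules are keyed to a species; rank-level mass rewrites are
  not supported.
- No nomenclature validation and no NEXUS/phyloXML/FASTA support.
- The greedy maximal collapse is provably minimal for this collapsibility
  relation (verified exhaustively on small trees), but display order
  follows source Newick child order only.
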