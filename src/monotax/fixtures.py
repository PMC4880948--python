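"""Deterministic synthetic (taxonomy, tree) fixtures.

The generator emulates the input pair the package consumes: a reference
taxonomy with configurable fan-out at every rank, and a rooted tree that is
*concordant* with it by construction (every taxon is a clade, with random
binary resolution inside each taxon).  Two kinds of controlled noise can
then be layered on top:

* ``planted_moves``: k leaves are pruned and regrafted onto random edges
  outside their source genus, creating known monophyly violations; each
  move is recorded together with the lineage rewrite that would "repair"
  it (re-classify the moved sequence to the taxon of its landing
  neighborhood, with deeper ranks Unclassified).
* ``unclassified_rate``: after tree construction, each supra-specific rank
  slot of each lineage entry is independently blanked to ``Unclassified``
  with this probability, so structure is unchanged but lineages become
  incomplete.

All randomness flows from a single seeded generator: the same spec yields
byte-identical Newick and table outputs.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Optional

from .errors import ArgumentError
from .formats import (
    UNCLASSIFIED,
    LineageModification,
    LineageTable,
    RankedLineage,
    write_modifications,
)
from .monophyly import annotate, brute_force_monophyly, full_assessment
from .taxonomy import build_taxon_table, key_str
from .tree import Node, PhyloTree

#: Above this leaf count the ground-truth assessment falls back from the
#: brute-force oracle to the fast implementation (documented trade-off).
ORACLE_LEAF_LIMIT = 1500


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    ``fanout`` gives the branching count at each supra-specific rank:
    (domains, phyla per domain, classes per phylum, orders per class,
    families per order, genera per family).  The default spec yields
    2*3*2*2*2*3 = 144 genera and, with ``species_per_genus=2`` and one
    strain per species, 288 leaves — a convenient desk-scale world.
    """

    seed: int = 0
    fanout: tuple[int, int, int, int, int, int] = (2, 3, 2, 2, 2, 3)
    species_per_genus: int = 2
    strains_per_species: int = 1
    unclassified_rate: float = 0.0
    planted_moves: int = 0

    def __post_init__(self):
        if len(self.fanout) != 6 or any(f < 1 for f in self.fanout):
            raise ArgumentError("fanout must be six positive counts")
        if not (0.0 <= self.unclassified_rate <= 1.0):
            raise ArgumentError("unclassified_rate must lie in [0, 1]")
        if self.planted_moves < 0:
            raise ArgumentError("planted_moves must be >= 0")
        if self.species_per_genus < 1 or self.strains_per_species < 1:
            raise ArgumentError("species_per_genus and strains_per_species must be >= 1")

    @property
    def n_leaves(self) -> int:
        n = 1
        for f in self.fanout:
            n *= f
        return n * self.species_per_genus * self.strains_per_species


@dataclass
class PlantedMove:
    """Record of one prune-regraft move and its repairing rewrite."""

    leaf_label: str
    old_lineage: RankedLineage  # as it appears in the emitted table
    repair_lineage: RankedLineage  # lineage of the landing neighborhood
    target_taxon: str  # '/'-joined common taxon of the landing subtree


@dataclass
class GroundTruth:
    """What the generator planted, plus the oracle's verdicts."""

    seed: int
    moves: list[PlantedMove] = field(default_factory=list)
    non_monophyletic: list[str] = field(default_factory=list)  # '/'-joined keys
    oracle: str = "brute_force"  # or "fast" above ORACLE_LEAF_LIMIT leaves

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "oracle": self.oracle,
            "moves": [
                {
                    "leaf": mv.leaf_label,
                    "old": key_str(mv.old_lineage.path),
                    "repair": key_str(mv.repair_lineage.path),
                    "target_taxon": mv.target_taxon,
                }
                for mv in self.moves
            ],
            "non_monophyletic": self.non_monophyletic,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


_RANK_PREFIX = ("Dom", "Phy", "Cla", "Ord", "Fam", "Gen")


def _make_names(spec: FixtureSpec) -> list[dict]:
    """Enumerate all lineages of the concordant taxonomy, in DFS order."""
    out: list[dict] = []
    counters = [0] * 6
    acc_counter = [0]

    def descend(depth: int, path: tuple[str, ...]):
        if depth == 6:
            genus = path[-1]
            for s in range(spec.species_per_genus):
                species = f"{genus}_sp{s + 1}"
                for _ in range(spec.strains_per_species):
                    acc_counter[0] += 1
                    acc = f"A{acc_counter[0]:05d}"
                    out.append({
                        "ranks": path,
                        "species": species,
                        "strain_tag": f"{species}__{acc}",
                    })
            return
        for _ in range(spec.fanout[depth]):
            counters[depth] += 1
            name = f"{_RANK_PREFIX[depth]}{counters[depth]:03d}"
            descend(depth + 1, path + (name,))

    descend(0, ())
    return out


def _random_join(subtrees: list[Node], rng: random.Random) -> Node:
    """Combine subtrees into a random binary topology (concordance keeper)."""
    nodes = list(subtrees)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return nodes[0]


def _build_concordant_tree(records: list[dict], rng: random.Random) -> PhyloTree:
    def build_level(recs: list[dict], depth: int) -> Node:
        if depth == 7:
            # species level: strains of one species
            leaves = []
            for rec in recs:
                leaf = Node(label=rec["strain_tag"],
                            length=round(rng.uniform(0.01, 0.2), 4))
                leaves.append(leaf)
            if len(leaves) == 1:
                return leaves[0]
            joined = _random_join(leaves, rng)
            joined.length = round(rng.uniform(0.01, 0.2), 4)
            return joined
        groups: dict[str, list[dict]] = {}
        for rec in recs:
            name = rec["ranks"][depth] if depth < 6 else rec["species"]
            groups.setdefault(name, []).append(rec)
        subtrees = [build_level(g, depth + 1) for g in groups.values()]
        if len(subtrees) == 1:
            return subtrees[0]
        joined = _random_join(subtrees, rng)
        joined.length = round(rng.uniform(0.01, 0.2), 4)
        return joined

    # group by species at depth 6 via rec["species"]; ranks cover depths 0..5
    root = build_level(records, 0)
    root.length = None
    return PhyloTree(root)


def _common_prefix(lineages: list[RankedLineage]) -> tuple[str, ...]:
    """Longest common supra-specific prefix, padded with Unclassified."""
    prefix: list[str] = []
    for r in range(6):
        names = {ln.ranks[r] for ln in lineages}
        if len(names) == 1:
            prefix.append(names.pop())
        else:
            break
    return tuple(prefix + [UNCLASSIFIED] * (6 - len(prefix)))


def generate(spec: FixtureSpec) -> tuple[LineageTable, PhyloTree, GroundTruth]:
    """Generate a (lineage table, tree, ground truth) fixture."""
    rng = random.Random(spec.seed)
    records = _make_names(spec)
    if spec.planted_moves >= len(records):
        raise ArgumentError(
            f"planted_moves={spec.planted_moves} must be smaller than the "
            f"leaf count {len(records)}"
        )
    true_lineage: dict[str, RankedLineage] = {
        rec["strain_tag"]: RankedLineage(
            ranks=rec["ranks"], species=rec["species"], strain_tag=rec["strain_tag"]
        )
        for rec in records
    }
    tree = _build_concordant_tree(records, rng)

    truth = GroundTruth(seed=spec.seed)
    moved: set[str] = set()
    for _ in range(spec.planted_moves):
        move = _plant_one_move(tree, true_lineage, moved, rng)
        truth.moves.append(move)
        moved.add(move.leaf_label)

    # blank rank slots AFTER tree construction (structure unchanged)
    entries: dict[str, RankedLineage] = {}
    for rec in records:
        tag = rec["strain_tag"]
        lineage = true_lineage[tag]
        if spec.unclassified_rate > 0.0:
            # unassignment is contiguous rank-downward: once a rank lacks an
            # assignment, all deeper supra-specific ranks do too (the pattern
            # of real incomplete lineages; scattered interior blanks would
            # manufacture spurious non-monophyletic taxa in a tree that is
            # concordant by construction)
            cut = 6
            for r in range(6):
                if rng.random() < spec.unclassified_rate:
                    cut = r
                    break
            if cut < 6:
                ranks = lineage.ranks[:cut] + (UNCLASSIFIED,) * (6 - cut)
                lineage = lineage.with_ranks(ranks)
        entries[tag] = lineage
    table = LineageTable(entries=entries,
                         provenance=f"monotax fixture seed={spec.seed}")

    # record the emitted (possibly blanked) old lineage for each move
    for mv in truth.moves:
        mv.old_lineage = entries[mv.leaf_label]

    # oracle verdicts
    at, _ = annotate(tree, table)
    if tree.n_leaves <= ORACLE_LEAF_LIMIT:
        non_mono = []
        for rec in at.taxon_table.named_records():
            key = tuple(rec.key)
            if key not in at.member_leaves:
                continue
            status = brute_force_monophyly(key, at)
            if not status.is_monophyletic:
                non_mono.append(key_str(key))
        truth.oracle = "brute_force"
    else:
        statuses = full_assessment(at)
        non_mono = [key_str(k) for k, s in statuses.items()
                    if not s.is_monophyletic]
        truth.oracle = "fast"
    truth.non_monophyletic = sorted(non_mono)
    return table, tree, truth


def _plant_one_move(
    tree: PhyloTree,
    true_lineage: dict[str, RankedLineage],
    moved: set[str],
    rng: random.Random,
) -> PlantedMove:
    """Prune one leaf and regraft it on an admissible random edge.

    Admissible target edges: above a node that is not the root, whose
    subtree lies entirely outside the source genus, contains no previously
    moved leaf, and shares at least the domain with nothing required —
    any such edge; the repair lineage is the longest common supra-specific
    prefix of the target subtree's true lineages, padded Unclassified.
    """
    tree.reindex()
    leaves = tree.leaves()

    def genus_path(label: str) -> tuple[str, ...]:
        return true_lineage[label].ranks

    # candidate leaves: unmoved, with >= 2 unmoved leaves in their genus
    genus_sizes: dict[tuple[str, ...], int] = {}
    for leaf in leaves:
        if leaf.label in moved:
            continue
        genus_sizes[genus_path(leaf.label)] = genus_sizes.get(
            genus_path(leaf.label), 0) + 1
    candidates = [
        leaf for leaf in leaves
        if leaf.label not in moved and genus_sizes[genus_path(leaf.label)] >= 2
    ]
    if not candidates:
        raise ArgumentError("no admissible leaf left to move")
    leaf = rng.choice(candidates)
    source_genus = genus_path(leaf.label)

    # leaf sets per node to test admissibility of targets
    subtree_labels: dict[int, list[str]] = {}
    for node in reversed(tree._preorder_reversed_children()):
        if node.is_leaf:
            subtree_labels[node._id] = [node.label]
        else:
            acc: list[str] = []
            for child in node.children:
                acc.extend(subtree_labels[child._id])
            subtree_labels[node._id] = acc

    def admissible(node: Node) -> bool:
        if node.parent is None or node is leaf:
            return False
        labels = subtree_labels[node._id]
        if any(lb in moved or lb == leaf.label for lb in labels):
            return False
        if any(genus_path(lb) == source_genus for lb in labels):
            return False
        return True

    targets = [node for node in tree.preorder() if admissible(node)]
    target = rng.choice(targets)
    target_lineages = [true_lineage[lb] for lb in subtree_labels[target._id]]
    repair_ranks = _common_prefix(target_lineages)

    tree.prune_leaf(leaf)
    tree.graft_on_edge(target, leaf)
    tree.reindex()

    old = true_lineage[leaf.label]
    repair = RankedLineage(ranks=repair_ranks, species=old.species,
                           strain_tag=old.strain_tag)
    named_depth = sum(1 for r in repair_ranks if r != UNCLASSIFIED)
    return PlantedMove(
        leaf_label=leaf.label,
        old_lineage=old,
        repair_lineage=repair,
        target_taxon=key_str(repair_ranks[:named_depth]) if named_depth else "",
    )


def repair_file(truth: GroundTruth) -> str:
    """Modification file text that undoes the planted moves' damage.

    One rule per moved leaf, rewriting its (emitted) lineage to the taxon
    of its landing neighborhood; applying the file and re-assessing yields
    all named taxa monophyletic.  Returns an empty string for k = 0.
    """
    mods = [
        LineageModification(old=mv.old_lineage, new=mv.repair_lineage)
        for mv in truth.moves
    ]
    return write_modifications(mods)
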