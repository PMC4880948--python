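"""File formats: Newick trees, rank-tagged lineage strings, lineage tables,
and lineage-modification files.

The lineage markup is the eight-rank tagged string used throughout the
package, e.g.::

    <D>Bacteria<P>Actinobacteria<C>Actinobacteria<O>Streptomycetales
    <F>Streptomycetaceae<G>Streptomyces<S>Streptomyces_longisporoflavus
    <T>Streptomyces_longisporoflavus__DQ442520

where D, P, C, O, F, G, S, T stand for Domain, Phylum, Class, Order,
Family, Genus, Species and sTrain.  The literal specifier ``Unclassified``
marks a rank lacking a taxonomic assignment; species and strain names are
never Unclassified.

Newick parsing is delegated to dendropy; the resulting tree is converted to
the package's own :class:`~monotax.tree.PhyloTree`, preserving child order
and branch lengths.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, TextIO, Union

import dendropy

from .errors import ConstraintError, DataError, FormatError, NewickParseError
from .tree import Node, PhyloTree

#: Fixed order of the six supra-specific ranks.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")
#: One-letter markers for all eight ranks, in hierarchy order.
RANK_MARKERS = ("D", "P", "C", "O", "F", "G", "S", "T")
#: Marker for a rank with no taxonomic assignment.
UNCLASSIFIED = "Unclassified"


def _norm(name: str) -> str:
    """Normalize a taxon name: strip and replace whitespace runs with '_'."""
    return re.sub(r"\s+", "_", name.strip())


@dataclass(frozen=True)
class RankedLineage:
    """One sequence's eight-rank taxonomy.

    ``ranks`` holds the six supra-specific names (Domain..Genus, in that
    order), each either a proper name or ``Unclassified``.  ``species`` and
    ``strain_tag`` are always proper names; the strain tag is conventionally
    ``species__accession``.
    """

    ranks: tuple[str, str, str, str, str, str]
    species: str
    strain_tag: str

    def __post_init__(self):
        if len(self.ranks) != 6:
            raise DataError(f"expected 6 supra-specific ranks, got {len(self.ranks)}")
        norm = tuple(_norm(r) for r in self.ranks)
        if any(not r for r in norm):
            raise DataError("empty rank name in lineage")
        object.__setattr__(self, "ranks", norm)
        sp = _norm(self.species)
        st = _norm(self.strain_tag) if self.strain_tag else sp
        if not sp or sp == UNCLASSIFIED:
            raise DataError(f"species name may not be empty or {UNCLASSIFIED!r}")
        if not st or st == UNCLASSIFIED:
            raise DataError(f"strain tag may not be empty or {UNCLASSIFIED!r}")
        object.__setattr__(self, "species", sp)
        object.__setattr__(self, "strain_tag", st)

    # convenience accessors -------------------------------------------------
    @property
    def domain(self) -> str:
        return self.ranks[0]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def path(self) -> tuple[str, ...]:
        """The seven-component taxon path Domain..Genus + species."""
        return self.ranks + (self.species,)

    def with_ranks(self, ranks: Iterable[str]) -> "RankedLineage":
        return replace(self, ranks=tuple(ranks))


@dataclass
class LineageTable:
    """Mapping from strain tag to :class:`RankedLineage`."""

    entries: dict[str, RankedLineage]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __contains__(self, strain_tag: str) -> bool:
        return strain_tag in self.entries


@dataclass(frozen=True)
class LineageModification:
    """A rewrite rule ``old lineage -> new lineage`` for one species.

    Species and strain names are always preserved by a modification; only
    the supra-specific ranks change.  ``has_domain`` records whether the
    rule text spelled out the Domain: rules written without ``<D>`` (the
    common shorthand) match entries of any domain and leave the domain
    untouched.
    """

    old: RankedLineage
    new: RankedLineage
    has_domain: bool = True

    def __post_init__(self):
        if self.old.species != self.new.species:
            raise ConstraintError(
                f"modification may not rename a species: "
                f"{self.old.species!r} -> {self.new.species!r} "
                "(names under <S> and <T> are always kept unchanged)"
            )

    def matches(self, lineage: RankedLineage) -> bool:
        if lineage.species != self.old.species:
            return False
        start = 0 if self.has_domain else 1
        return lineage.ranks[start:] == self.old.ranks[start:]

    def rewrite(self, lineage: RankedLineage) -> RankedLineage:
        ranks = list(self.new.ranks)
        if not self.has_domain:
            ranks[0] = lineage.ranks[0]
        return replace(lineage, ranks=tuple(ranks))


# ---------------------------------------------------------------------------
# lineage markup
# ---------------------------------------------------------------------------

_MARKUP_RE = re.compile(r"<([A-Za-z])>")


def parse_lineage_markup(s: str, *, require_domain: bool = True) -> RankedLineage:
    """Parse a rank-tagged lineage string into a :class:`RankedLineage`.

    Markers must appear in hierarchy order D,P,C,O,F,G,S with <T> optional.
    With ``require_domain=False`` the leading <D> (and only it) may be
    omitted, as is customary in modification rules; the domain slot is then
    filled with ``Unclassified`` and flagged by the caller.
    """
    s = s.strip()
    tokens: dict[str, str] = {}
    found: list[str] = []
    matches = list(_MARKUP_RE.finditer(s))
    if not matches:
        raise FormatError(f"no rank markers found in {s!r}")
    if matches[0].start() != 0:
        raise FormatError(f"unexpected text before first marker in {s!r}")
    for i, m in enumerate(matches):
        marker = m.group(1).upper()
        end = matches[i + 1].start() if i + 1 < len(matches) else len(s)
        value = s[m.end():end]
        if marker not in RANK_MARKERS:
            raise FormatError(f"unknown rank marker <{marker}> in {s!r}")
        if marker in tokens:
            raise FormatError(f"duplicate rank marker <{marker}> in {s!r}")
        if not value.strip():
            raise FormatError(f"empty value after <{marker}> in {s!r}")
        tokens[marker] = _norm(value)
        found.append(marker)

    expected = list(RANK_MARKERS[:7])  # D..S mandatory, T optional
    if not require_domain and found and found[0] != "D":
        expected = expected[1:]
    for marker in expected:
        if marker not in tokens:
            raise FormatError(f"missing rank marker <{marker}> in {s!r}")
    # order check: found markers must follow hierarchy order
    order = {m: i for i, m in enumerate(RANK_MARKERS)}
    for a, b in zip(found, found[1:]):
        if order[a] >= order[b]:
            raise FormatError(f"rank marker <{b}> out of order in {s!r}")

    ranks = tuple(tokens.get(m, UNCLASSIFIED) for m in RANK_MARKERS[:6])
    species = tokens["S"]
    if species == UNCLASSIFIED:
        raise DataError(f"species may not be {UNCLASSIFIED!r}: {s!r}")
    strain = tokens.get("T", species)
    return RankedLineage(ranks=ranks, species=species, strain_tag=strain)


def format_lineage_markup(
    lineage: RankedLineage, include_strain: bool = True, *, include_domain: bool = True
) -> str:
    """Inverse of :func:`parse_lineage_markup`."""
    parts = []
    markers = RANK_MARKERS[:6]
    values = lineage.ranks
    if not include_domain:
        markers, values = markers[1:], values[1:]
    for marker, value in zip(markers, values):
        parts.append(f"<{marker}>{value}")
    parts.append(f"<S>{lineage.species}")
    if include_strain:
        parts.append(f"<T>{lineage.strain_tag}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _duplicate_leaf_label(text: str) -> Optional[str]:
    """First leaf label occurring twice in raw Newick text (best effort)."""
    seen: set[str] = set()
    for token in re.findall(r"[(,]\s*('(?:[^']|'')*'|[^(),:;\[\]]+)", text):
        label = token.strip().strip("'")
        if label in seen:
            return label
        seen.add(label)
    return None


def _as_text(source: Union[str, TextIO]) -> str:
    if hasattr(source, "read"):
        return source.read()
    return source


def read_newick(source: Union[str, TextIO]) -> PhyloTree:
    """Read a rooted tree from Newick text (string or open text stream).

    Child order and branch lengths are preserved; underscores in labels are
    kept verbatim (no underscore-to-space conversion).  A trailing semicolon
    is required by the grammar but surrounding whitespace is tolerated.
    """
    text = _as_text(source).strip()
    if not text:
        raise NewickParseError("empty Newick input")
    if not text.endswith(";"):
        text += ";"
    # cheap structural pre-check so the error can carry a character offset
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError("unbalanced ')'", offset=i)
    if depth != 0:
        raise NewickParseError("unbalanced '(': missing closing parenthesis",
                               offset=len(text) - 1)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy's error zoo -> package errors
        if "Multiple occurrences" in str(exc) or "Duplicate" in type(exc).__name__:
            label = _duplicate_leaf_label(text)
            raise DataError(f"duplicate leaf label {label!r} in Newick input") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    root = Node()
    stack = [(dtree.seed_node, root)]
    while stack:
        dnode, node = stack.pop()
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node.label = label
        node.length = dnode.edge.length
        for child in dnode.child_nodes():
            cnode = Node()
            node.add_child(cnode)
            stack.append((child, cnode))
    # dendropy iterates children in order; our stack visit preserves the
    # insertion order of node.children because we append before descending.
    tree = PhyloTree(root)
    seen: set[str] = set()
    for label in tree.leaf_labels():
        if label in seen:
            raise DataError(f"duplicate leaf label {label!r} in Newick input")
        seen.add(label)
    return tree


_QUOTE_NEEDED = re.compile(r"[\s(){}\[\]:;,']")


def _newick_label(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_suffix(node: Node, with_label: bool) -> str:
    s = ""
    if with_label and node.label:
        s += _newick_label(node.label)
    if node.length is not None:
        s += f":{node.length:.10g}"
    return s


def write_newick(tree: PhyloTree, dest: Optional[TextIO] = None) -> str:
    """Serialize a :class:`PhyloTree` to Newick, inverse of :func:`read_newick`."""
    out: list[str] = []
    # iterative pre/post emission: stack holds nodes and literal text pieces
    stack: list[tuple[str, object]] = [("node", tree.root)]
    while stack:
        kind, item = stack.pop()
        if kind == "text":
            out.append(item)  # type: ignore[arg-type]
            continue
        node: Node = item  # type: ignore[assignment]
        if node.is_leaf:
            out.append(_newick_label(node.label or "") + _node_suffix(node, False))
        else:
            out.append("(")
            stack.append(("text", ")" + _node_suffix(node, True)))
            n = len(node.children)
            for i, child in enumerate(reversed(node.children)):
                stack.append(("node", child))
                if i < n - 1:
                    stack.append(("text", ","))
    text = "".join(out) + ";"
    if dest is not None:
        dest.write(text)
    return text


# ---------------------------------------------------------------------------
# lineage tables
# ---------------------------------------------------------------------------

@dataclass
class TableDialect:
    """Column layout of a lineage table.

    The default layout is tab-separated with a header row and columns
    ``id`` (sequence accession), ``species_name`` and ``lineage``, where
    the lineage field is a semicolon-separated Domain;Phylum;Class;Order;
    Family;Genus path.  Real-world exports can be adapted by remapping the
    column names and separators here (or in a YAML file via the CLI).
    """

    delimiter: str = "\t"
    id_col: str = "id"
    species_col: str = "species_name"
    lineage_col: str = "lineage"
    lineage_sep: str = ";"

    @classmethod
    def from_dict(cls, d: dict) -> "TableDialect":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        bad = set(d) - known
        if bad:
            raise FormatError(f"unknown dialect keys: {sorted(bad)}")
        return cls(**d)


def read_lineage_table(
    source: Union[str, TextIO],
    dialect: Optional[TableDialect] = None,
    provenance: str = "",
) -> tuple[LineageTable, list[str]]:
    """Read a delimiter-separated lineage table.

    Rows with an empty lineage field become all-``Unclassified``
    supra-specific ranks (with a warning).  Lineage paths shorter than six
    ranks are padded with ``Unclassified`` on the right.  The strain tag is
    built as ``species__id``.
    """
    import csv

    dialect = dialect or TableDialect()
    text = _as_text(source)
    reader = csv.reader(io.StringIO(text), delimiter=dialect.delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("lineage table is empty (no header row)")
    header = [h.strip() for h in header]
    cols = {}
    for name in (dialect.id_col, dialect.species_col, dialect.lineage_col):
        if name not in header:
            raise FormatError(f"missing mandatory column {name!r} in lineage table header")
        cols[name] = header.index(name)

    entries: dict[str, RankedLineage] = {}
    warnings: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            seq_id = _norm(row[cols[dialect.id_col]])
            species = _norm(row[cols[dialect.species_col]])
            lineage_field = row[cols[dialect.lineage_col]].strip()
        except IndexError:
            raise FormatError(f"line {lineno}: too few columns")
        if not seq_id or not species:
            raise FormatError(f"line {lineno}: empty id or species name")
        if not lineage_field:
            ranks = (UNCLASSIFIED,) * 6
            warnings.append(
                f"line {lineno}: empty lineage for {species!r}; "
                f"all supra-specific ranks set to {UNCLASSIFIED!r}"
            )
        else:
            parts = [_norm(p) for p in lineage_field.split(dialect.lineage_sep)]
            parts = [p if p else UNCLASSIFIED for p in parts]
            if len(parts) > 6:
                raise FormatError(
                    f"line {lineno}: lineage path has {len(parts)} ranks (max 6)"
                )
            ranks = tuple(parts + [UNCLASSIFIED] * (6 - len(parts)))
        strain_tag = f"{species}__{seq_id}"
        if strain_tag in entries:
            raise DataError(f"line {lineno}: duplicate strain tag {strain_tag!r}")
        entries[strain_tag] = RankedLineage(ranks=ranks, species=species,
                                            strain_tag=strain_tag)
    return LineageTable(entries=entries, provenance=provenance), warnings


def write_lineage_table(
    table: LineageTable,
    dest: Optional[TextIO] = None,
    dialect: Optional[TableDialect] = None,
) -> str:
    """Serialize a :class:`LineageTable` in the given dialect (inverse of read)."""
    dialect = dialect or TableDialect()
    lines = [dialect.delimiter.join(
        (dialect.id_col, dialect.species_col, dialect.lineage_col))]
    for lineage in table:
        tag = lineage.strain_tag
        seq_id = tag.rsplit("__", 1)[-1] if "__" in tag else tag
        lines.append(dialect.delimiter.join(
            (seq_id, lineage.species, dialect.lineage_sep.join(lineage.ranks))))
    text = "\n".join(lines) + "\n"
    if dest is not None:
        dest.write(text)
    return text


# ---------------------------------------------------------------------------
# modification files
# ---------------------------------------------------------------------------

def read_modifications(
    source: Union[str, TextIO],
) -> tuple[list[LineageModification], list[str]]:
    """Read a lineage-modification file.

    Each non-blank, non-comment line holds exactly two whitespace-separated
    lineage-markup tokens: ``old_lineage new_lineage``.  The species (and
    strain) names of old and new must agree; the leading ``<D>`` marker may
    be omitted from both tokens.
    """
    text = _as_text(source)
    mods: list[LineageModification] = []
    warnings: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise FormatError(
                f"line {lineno}: expected exactly 2 lineage tokens "
                f"separated by a space, got {len(tokens)}"
            )
        try:
            old = parse_lineage_markup(tokens[0], require_domain=False)
            new = parse_lineage_markup(tokens[1], require_domain=False)
        except (FormatError, DataError) as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        has_domain = tokens[0].startswith("<D>") and tokens[1].startswith("<D>")
        if tokens[0].startswith("<D>") != tokens[1].startswith("<D>"):
            raise FormatError(
                f"line {lineno}: old and new lineages must both include or "
                "both omit the <D> marker"
            )
        try:
            mods.append(LineageModification(old=old, new=new, has_domain=has_domain))
        except ConstraintError as exc:
            raise ConstraintError(f"line {lineno}: {exc}") from exc
    return mods, warnings


def write_modifications(
    mods: list[LineageModification], dest: Optional[TextIO] = None
) -> str:
    """Serialize modification rules, one ``old new`` pair per line."""
    lines = []
    for mod in mods:
        old = format_lineage_markup(mod.old, include_strain=False,
                                    include_domain=mod.has_domain)
        new = format_lineage_markup(mod.new, include_strain=False,
                                    include_domain=mod.has_domain)
        lines.append(f"{old} {new}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if dest is not None:
        dest.write(text)
    return text
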