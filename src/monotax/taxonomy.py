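"""Taxon hierarchy built from a lineage table.

A *taxon key* is the full path of names from Domain down to some rank —
``("Bacteria",)`` for a domain, a 7-tuple ending in the species name for a
species.  Identity is the whole path, never the terminal name alone, so an
``Unclassified`` family under two different orders yields two distinct
records.

The ``{n+m}`` bookkeeping follows the display convention: for a given
taxon, *n* counts member sequences whose full six-rank lineage is complete
(no ``Unclassified`` specifier) and *m* counts the rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import DataError
from .formats import (
    UNCLASSIFIED,
    LineageModification,
    LineageTable,
    RankedLineage,
)

#: Rank codes by key depth (1-based): depth 1 = Domain ... depth 7 = Species.
KEY_RANKS = ("D", "P", "C", "O", "F", "G", "S")

TaxonKey = tuple  # tuple[str, ...] of length 1..7


def key_rank(key: TaxonKey) -> str:
    """One-letter rank code of a taxon key (by its depth)."""
    return KEY_RANKS[len(key) - 1]


def key_str(key: TaxonKey) -> str:
    """Canonical '/'-joined rendering of a taxon key."""
    return "/".join(key)


def is_complete(lineage: RankedLineage) -> bool:
    """True iff none of the six supra-specific ranks is ``Unclassified``.

    Completeness is evaluated over Domain..Genus only: species and strain
    names are present by construction.
    """
    return UNCLASSIFIED not in lineage.ranks


@dataclass
class TaxonRecord:
    """One taxon (at one rank) with its members and {n+m} statistics."""

    key: TaxonKey
    members: set = field(default_factory=set)  # strain tags
    n: int = 0  # members with complete lineage
    m: int = 0  # members with incomplete lineage (+ absorbed leaves on display)

    @property
    def is_named(self) -> bool:
        return self.key[-1] != UNCLASSIFIED

    @property
    def rank(self) -> str:
        return key_rank(self.key)

    @property
    def size(self) -> int:
        return self.n + self.m


class TaxonTable:
    """All taxa occurring as path prefixes of a lineage table's entries.

    Iteration yields records depth-first: a parent always precedes its
    children, children follow first-occurrence order in the source table.
    """

    def __init__(self, records: dict[TaxonKey, TaxonRecord]):
        self.records = records
        self._children: dict[TaxonKey, list[TaxonKey]] = {}
        self._roots: list[TaxonKey] = []
        for key in records:
            if len(key) == 1:
                self._roots.append(key)
            else:
                self._children.setdefault(key[:-1], []).append(key)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: TaxonKey) -> bool:
        return tuple(key) in self.records

    def __getitem__(self, key: TaxonKey) -> TaxonRecord:
        return self.records[tuple(key)]

    def get(self, key: TaxonKey) -> Optional[TaxonRecord]:
        return self.records.get(tuple(key))

    def children(self, key: TaxonKey) -> list[TaxonKey]:
        return self._children.get(tuple(key), [])

    def ordered_keys(self) -> list[TaxonKey]:
        """Depth-first key order (parent before children)."""
        out: list[TaxonKey] = []
        stack = list(reversed(self._roots))
        while stack:
            key = stack.pop()
            out.append(key)
            for child in reversed(self.children(key)):
                stack.append(child)
        return out

    def __iter__(self):
        for key in self.ordered_keys():
            yield self.records[key]

    def named_records(self) -> Iterable[TaxonRecord]:
        for rec in self:
            if rec.is_named:
                yield rec

    def to_dict(self) -> dict:
        return {
            key_str(rec.key): {
                "rank": rec.rank,
                "n": rec.n,
                "m": rec.m,
                "members": sorted(rec.members),
                "is_named": rec.is_named,
            }
            for rec in self
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def lineage_keys(lineage: RankedLineage) -> list[TaxonKey]:
    """All taxon keys a lineage contributes to: D..G prefixes + species."""
    path = lineage.path
    return [path[: i + 1] for i in range(7)]


def build_taxon_table(table: LineageTable) -> TaxonTable:
    """Materialize one :class:`TaxonRecord` per distinct path prefix.

    ``Unclassified`` prefixes are materialized too (as pseudo-taxa with
    ``is_named == False``); they carry counts but no monophyly verdict
    downstream.
    """
    if len(table) == 0:
        raise DataError("cannot build a taxon table from an empty lineage table")
    records: dict[TaxonKey, TaxonRecord] = {}
    for lineage in table:
        complete = is_complete(lineage)
        for key in lineage_keys(lineage):
            rec = records.get(key)
            if rec is None:
                rec = records[key] = TaxonRecord(key=key)
            rec.members.add(lineage.strain_tag)
            if complete:
                rec.n += 1
            else:
                rec.m += 1
    return TaxonTable(records)


def apply_modifications(
    table: LineageTable, mods: list[LineageModification]
) -> tuple[LineageTable, list[int], list[str]]:
    """Apply rewrite rules to a lineage table (pure function).

    An entry is rewritten by the first rule whose old lineage (Domain..Genus
    plus species) matches it exactly; each entry is rewritten at most once.
    Returns the new table, per-rule match counts (in file order), and
    warnings for rules that matched nothing.
    """
    counts = [0] * len(mods)
    entries: dict[str, RankedLineage] = {}
    for tag, lineage in table.entries.items():
        out = lineage
        for i, mod in enumerate(mods):
            if mod.matches(lineage):
                out = mod.rewrite(lineage)
                counts[i] += 1
                break
        entries[tag] = out
    warnings = [
        f"rule {i + 1} ({mods[i].old.species}) matched no entry"
        for i in range(len(mods))
        if counts[i] == 0
    ]
    return LineageTable(entries=entries, provenance=table.provenance), counts, warnings
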