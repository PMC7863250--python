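"""Hierarchy-aware retrieval over a thesaurus.

Because the hierarchy is a tree linked by the single is_a relation, a
query with a broader term can be expanded to its reflexive-transitive
closure: a level-2 term finds everything annotated with its level-3/4
narrower terms, which is what makes cross-database joins on element ids
work across annotation granularities.
"""

from __future__ import annotations

from .errors import UnknownNamespaceError
from .model import Thesaurus, normalize_id

XREF_NAMESPACES = ("BCH", "Trait", "Donor")


def descendants(thesaurus: Thesaurus, term_id: str) -> set[str]:
    """All strict descendants of a term via is_a closure."""
    tid = thesaurus[term_id].term_id
    out: set[str] = set()
    stack = list(thesaurus.children_index.get(tid, ()))
    while stack:
        cur = stack.pop()
        if cur in out:
            continue
        out.add(cur)
        stack.extend(thesaurus.children_index.get(cur, ()))
    return out


def expand(thesaurus: Thesaurus, term_id: str) -> set[str]:
    """The term together with all its descendants (query expansion)."""
    tid = thesaurus[term_id].term_id
    return {tid} | descendants(thesaurus, tid)


def find(
    thesaurus: Thesaurus,
    text: str,
    fields: tuple[str, ...] = ("name", "synonym"),
) -> list[str]:
    """Case-insensitive exact match on preferred names and/or synonyms.

    Returns term ids sorted ascending; empty list when nothing matches.
    """
    for f in fields:
        if f not in ("name", "synonym"):
            raise ValueError(f"unknown search field {f!r}")
    key = text.casefold()
    hits: set[str] = set()
    if "name" in fields and key in thesaurus.name_index:
        hits.add(thesaurus.name_index[key])
    if "synonym" in fields:
        hits.update(thesaurus.synonym_index.get(key, ()))
    return sorted(hits)


def find_containing(
    thesaurus: Thesaurus,
    text: str,
    fields: tuple[str, ...] = ("name", "synonym"),
) -> list[str]:
    """Case-insensitive substring search (interactive use, not joins)."""
    key = text.casefold()
    hits: set[str] = set()
    for term in thesaurus:
        if "name" in fields and key in term.name.casefold():
            hits.add(term.term_id)
        if "synonym" in fields and any(
            key in s.casefold() for s in term.synonyms
        ):
            hits.add(term.term_id)
    return sorted(hits)


def resolve_xref(
    thesaurus: Thesaurus, namespace: str, value: str | int
) -> list[str]:
    """Exact cross-reference lookup.

    Namespaces: ``BCH`` (integer record id), ``Trait`` (t:NNNNNNN id) and
    ``Donor`` (registry code).  Returns the sorted list of term ids
    carrying the reference — BCH ids are not assumed unique — and the
    empty list when unmapped.
    """
    if namespace == "BCH":
        try:
            key = int(value)
        except (TypeError, ValueError):
            return []
        return sorted(thesaurus.bch_index.get(key, ()))
    if namespace == "Trait":
        return sorted(thesaurus.trait_index.get(normalize_id(str(value)), ()))
    if namespace == "Donor":
        return sorted(thesaurus.donor_index.get(str(value), ()))
    raise UnknownNamespaceError(
        f"unknown xref namespace {namespace!r}; expected one of "
        f"{XREF_NAMESPACES}"
    )
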