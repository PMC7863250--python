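"""Thesaurus data model: term records, the mono-hierarchy, validation.

The thesaurus is a simple tree (ISO 25964 mono-hierarchy): every term has
exactly one broader term via the sole relation is_a, except the single
root.  Five levels are used: level 0 is the root concept "genetic
element", level 1 the twelve element types, level 2 functional long
names, level 3 concrete elements with XX-YYYY-ZZZZZ designations, level 4
sequence variants of a level-3 element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from . import grammar
from .errors import (
    CycleError,
    DuplicateIdError,
    DuplicateNameError,
    IdSpaceExhaustedError,
    LevelError,
    ThesaurusError,
    UnknownTermError,
    UnknownParentError,
)
from .grammar import Modification
from .registries import (
    LEVEL1_ALLOWED_PREFIXES,
    LEVEL1_TYPES,
    DonorRegistry,
    PrefixRegistry,
    default_donor_registry,
    default_prefix_registry,
)

ROOT_ID = "e:0000000"
ROOT_NAME = "genetic element"
MAX_LEVEL = 4

_ID_RE = re.compile(r"^(e|t):\s*(\d{7})$")
TERM_ID_RE = re.compile(r"^e:\d{7}$")
TRAIT_ID_RE = re.compile(r"^t:\d{7}$")


def normalize_id(raw: str) -> str:
    """Canonicalise an identifier: ``e: 0000415`` -> ``e:0000415``.

    The printed form with a space after the colon is accepted on input;
    anything else is returned unchanged (the validator reports pattern
    violations as data).
    """
    m = _ID_RE.match(raw.strip())
    if m:
        return f"{m.group(1)}:{m.group(2)}"
    return raw.strip()


@dataclass(frozen=True)
class Definition:
    """Definition text plus the literature citations backing it."""

    text: str
    citations: tuple[str, ...] = ()


@dataclass(frozen=True)
class TraitRef:
    """Reference into the trait thesaurus (opaque here), optional label."""

    trait_id: str
    label: str | None = None


@dataclass
class ElementTerm:
    """One thesaurus node with its full attribute set.

    ``donor`` holds the registry mnemonic code (STRHY, CaMV, SYNTH);
    ``donor_text`` preserves the scientific name exactly as annotated in
    the source record, which may be more specific than the registry name
    (e.g. a strain).
    """

    term_id: str
    name: str
    parent_id: str | None = None
    level: int | None = None
    definition: Definition | None = None
    comment: str | None = None
    synonyms: list[str] = field(default_factory=list)
    trait_refs: list[TraitRef] = field(default_factory=list)
    bch_id: int | None = None
    other_xrefs: list[tuple[str, str]] = field(default_factory=list)
    donor: str | None = None
    donor_text: str | None = None
    modification: Modification | None = None

    def __post_init__(self) -> None:
        self.term_id = normalize_id(self.term_id)
        if self.parent_id is not None:
            self.parent_id = normalize_id(self.parent_id)


@dataclass(frozen=True)
class Violation:
    """One structural rule broken by a thesaurus (validator output)."""

    code: str
    term_id: str
    message: str
    severity: str = "error"


class Thesaurus:
    """The mono-hierarchical element tree with lookup indexes."""

    def __init__(self, metadata: dict[str, str] | None = None):
        self.terms: dict[str, ElementTerm] = {}
        self.children_index: dict[str, list[str]] = {}
        self.name_index: dict[str, str] = {}
        self.synonym_index: dict[str, list[str]] = {}
        self.bch_index: dict[int, list[str]] = {}
        self.trait_index: dict[str, list[str]] = {}
        self.donor_index: dict[str, list[str]] = {}
        self.metadata: dict[str, str] = dict(
            metadata if metadata is not None else {"format-version": "1.2"}
        )
        self.extra_stanzas: list[str] = []  # non-Term stanzas, verbatim

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __contains__(self, term_id: str) -> bool:
        return normalize_id(term_id) in self.terms

    def __getitem__(self, term_id: str) -> ElementTerm:
        tid = normalize_id(term_id)
        if tid not in self.terms:
            raise UnknownTermError(f"no term {tid!r} in thesaurus")
        return self.terms[tid]

    def get(self, term_id: str) -> ElementTerm | None:
        return self.terms.get(normalize_id(term_id))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Thesaurus):
            return NotImplemented
        return (
            self.terms == other.terms
            and self.metadata == other.metadata
            and self.extra_stanzas == other.extra_stanzas
        )

    @property
    def root_id(self) -> str | None:
        for term in self.terms.values():
            if term.parent_id is None:
                return term.term_id
        return None

    # -- construction --------------------------------------------------
    def add_term(self, term: ElementTerm) -> "Thesaurus":
        """Insert a term, preserving all invariants or rejecting it.

        The level is computed as parent level + 1 (0 for the root); a
        level supplied on the term must agree.  Returns self so calls
        chain.
        """
        tid = term.term_id
        if not TERM_ID_RE.match(tid):
            raise ThesaurusError(
                f"term id {tid!r} does not match e: + 7 digits"
            )
        if tid in self.terms:
            raise DuplicateIdError(f"duplicate term id {tid}")
        if term.parent_id is None:
            if self.root_id is not None:
                raise LevelError(
                    f"thesaurus already has root {self.root_id}; "
                    f"{tid} must declare a parent"
                )
            level = 0
        else:
            if term.parent_id == tid:
                raise CycleError(f"term {tid} cannot be its own parent")
            parent = self.terms.get(term.parent_id)
            if parent is None:
                raise UnknownParentError(
                    f"parent {term.parent_id} of {tid} does not exist"
                )
            level = (parent.level or 0) + 1
            if level > MAX_LEVEL:
                raise LevelError(
                    f"{tid} would sit at level {level}; maximum is {MAX_LEVEL}"
                )
        if term.level is not None and term.level != level:
            raise LevelError(
                f"{tid} declares level {term.level} but its position "
                f"implies level {level}"
            )
        key = term.name.casefold()
        if key in self.name_index:
            raise DuplicateNameError(
                f"preferred name {term.name!r} already used by "
                f"{self.name_index[key]}"
            )

        term = replace(term, level=level)
        self.terms[tid] = term
        self.children_index.setdefault(tid, [])
        if term.parent_id is not None:
            self.children_index.setdefault(term.parent_id, []).append(tid)
        self.name_index[key] = tid
        for syn in term.synonyms:
            self.synonym_index.setdefault(syn.casefold(), []).append(tid)
        if term.bch_id is not None:
            self.bch_index.setdefault(term.bch_id, []).append(tid)
        for ref in term.trait_refs:
            self.trait_index.setdefault(ref.trait_id, []).append(tid)
        if term.donor is not None:
            self.donor_index.setdefault(term.donor, []).append(tid)
        return self

    def next_free_id(self) -> str:
        """Smallest unused positive 7-digit id in the ``e:`` namespace."""
        used = {
            int(tid[2:])
            for tid in self.terms
            if TERM_ID_RE.match(tid)
        }
        for n in range(1, 10**7):
            if n not in used:
                return f"e:{n:07d}"
        raise IdSpaceExhaustedError("all 9 999 999 element ids are in use")

    # -- traversal helpers ---------------------------------------------
    def ancestors(self, term_id: str) -> list[str]:
        """Strict ancestors, nearest first; raises on unknown id."""
        term = self[term_id]
        chain = []
        seen = {term.term_id}
        while term.parent_id is not None:
            if term.parent_id in seen or term.parent_id not in self.terms:
                break  # malformed tree; validator reports it
            chain.append(term.parent_id)
            seen.add(term.parent_id)
            term = self.terms[term.parent_id]
        return chain

    def level1_ancestor(self, term_id: str) -> ElementTerm | None:
        term = self[term_id]
        seen: set[str] = set()
        while term.parent_id is not None and term.parent_id in self.terms:
            if term.term_id in seen:
                return None  # cycle; validator reports it separately
            seen.add(term.term_id)
            parent = self.terms[term.parent_id]
            if parent.parent_id is None:
                return term
            term = parent
        return None


def validate_thesaurus(
    thesaurus: Thesaurus,
    donor_registry: DonorRegistry | None = None,
    prefix_registry: PrefixRegistry | None = None,
) -> list[Violation]:
    """Exhaustive structural validation; empty list iff conformant.

    Violations are data, not exceptions: the checks run over any state
    the term table can express, including states add_term would have
    rejected.  Ordered deterministically (term id, then code).
    """
    donor_registry = donor_registry or default_donor_registry()
    prefix_registry = prefix_registry or default_prefix_registry()
    out: list[Violation] = []

    def bad(code: str, tid: str, msg: str, severity: str = "error") -> None:
        out.append(Violation(code, tid, msg, severity))

    roots = [t.term_id for t in thesaurus if t.parent_id is None]
    if not thesaurus.terms:
        return []
    if not roots:
        bad("no-root", "", "no root term (every term declares a parent)")
    for extra in roots[1:]:
        bad("multiple-roots", extra, f"second root {extra} (forest, not tree)")

    # reachability / cycles via parent links
    for term in thesaurus:
        tid = term.term_id
        if not TERM_ID_RE.match(tid):
            bad("id-pattern", tid, f"id {tid!r} is not e: + exactly 7 digits")
        if term.parent_id is not None:
            if term.parent_id not in thesaurus.terms:
                bad(
                    "unknown-parent",
                    tid,
                    f"parent {term.parent_id} does not exist",
                )
            seen = {tid}
            cur = term
            while cur.parent_id is not None and cur.parent_id in thesaurus.terms:
                if cur.parent_id in seen:
                    bad("cycle", tid, f"{tid} is its own ancestor")
                    break
                seen.add(cur.parent_id)
                cur = thesaurus.terms[cur.parent_id]

    # level arithmetic
    for term in thesaurus:
        tid = term.term_id
        if term.parent_id is None:
            if term.level not in (0, None):
                bad("level", tid, f"root level is {term.level}, expected 0")
            continue
        parent = thesaurus.terms.get(term.parent_id)
        if parent is None or parent.level is None or term.level is None:
            continue
        if term.level != parent.level + 1:
            bad(
                "level",
                tid,
                f"level {term.level} under parent at level {parent.level}",
            )
        if term.level > MAX_LEVEL:
            bad("level", tid, f"level {term.level} exceeds {MAX_LEVEL}")

    # duplicate preferred names
    by_name: dict[str, list[str]] = {}
    for term in thesaurus:
        by_name.setdefault(term.name.casefold(), []).append(term.term_id)
    for name_key, tids in by_name.items():
        for tid in tids[1:]:
            bad(
                "duplicate-name",
                tid,
                f"preferred name {thesaurus.terms[tid].name!r} also used "
                f"by {tids[0]}",
            )

    # naming rules by level
    for term in thesaurus:
        tid = term.term_id
        if term.level == 1 and term.name.casefold() not in LEVEL1_TYPES:
            bad(
                "level1-name",
                tid,
                f"{term.name!r} is not one of the 12 element-type names",
            )
        if term.level in (2, 3, 4):
            prefix = term.name.partition("-")[0]
            anchor = thesaurus.level1_ancestor(tid)
            if prefix not in prefix_registry:
                bad(
                    "prefix",
                    tid,
                    f"name {term.name!r} does not start with a registered "
                    "element-type prefix",
                )
            elif anchor is not None:
                allowed = LEVEL1_ALLOWED_PREFIXES.get(
                    anchor.name.casefold(), frozenset(prefix_registry.entries)
                )
                if prefix not in allowed:
                    bad(
                        "prefix-ancestor",
                        tid,
                        f"prefix {prefix} inconsistent with level-1 branch "
                        f"{anchor.name!r}",
                    )
        if term.level in (3, 4):
            diags = grammar.lint_name(
                term.name,
                prefix_registry,
                donor_registry,
                donor=term.donor,
            )
            for diag in diags:
                bad(
                    "name-grammar",
                    tid,
                    f"{term.name!r}: {diag.rule}: {diag.message}",
                )
            try:
                parsed = grammar.parse_name(
                    term.name, prefix_registry, donor_registry
                )
                if parsed.donor is not None and parsed.donor not in donor_registry:
                    bad("donor", tid, f"unknown donor code {parsed.donor!r}")
            except Exception:
                pass  # already reported through lint diagnostics
        if term.donor is not None and term.donor not in donor_registry:
            bad("donor", tid, f"unknown donor code {term.donor!r}")
        if term.trait_refs and (term.level or 0) < 3:
            bad(
                "trait-level",
                tid,
                "trait xrefs are conventionally attached at levels 3-4",
                severity="warning",
            )
        for ref in term.trait_refs:
            if not TRAIT_ID_RE.match(ref.trait_id):
                bad(
                    "id-pattern",
                    tid,
                    f"trait ref {ref.trait_id!r} is not t: + 7 digits",
                )

    out.sort(key=lambda v: (v.term_id, v.code, v.message))
    return out
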