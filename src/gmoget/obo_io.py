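"""Read and write the thesaurus OBO dialect losslessly.

The dialect follows OBO flat-file 1.2 conventions with a few local
habits: trait cross-references escape the colon inside the target id
(``xref: Trait:t\\:0000006``), donor organisms appear as
``xref: Donor:Streptomyces_hygroscopicus`` (underscores for the spaces
that are illegal in xref targets), and ``is_a`` lines carry the parent's
preferred name as a trailing ``!`` comment.  Writes are deterministic:
stanzas sorted by term id, tags in fixed order, so write -> read -> write
is byte-identical.
"""

from __future__ import annotations

import io
import re
from typing import IO

from .errors import OboParseError
from .model import (
    Definition,
    ElementTerm,
    Thesaurus,
    TraitRef,
    normalize_id,
)
from . import grammar
from .registries import DonorRegistry, default_donor_registry

_TAG_RE = re.compile(r"^([A-Za-z_-]+):\s?(.*)$")
_BCH_RE = re.compile(r"^BCH:\s*(\d+)$")
_TRAIT_RE = re.compile(r"^Trait:\s*(t)\\?:\s*(\d{7})\s*(?:\"(.*)\")?$")
_DONOR_RE = re.compile(r"^Donor:\s*(.+)$")
_SYNONYM_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"(?:\s+(\w+))?(?:\s+\[.*\])?$')
_DEF_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(?:\[(.*)\])?$')

#: tag emission order inside a [Term] stanza
_TAG_ORDER = ("id", "name", "def", "comment", "synonym", "is_a", "xref")


def _escape_quoted(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _unescape(text: str) -> str:
    return re.sub(r"\\(.)", r"\1", text)


def _strip_bang_comment(value: str) -> tuple[str, str | None]:
    """Split an unquoted trailing ``! comment`` off a tag value."""
    in_quotes = False
    i = 0
    while i < len(value):
        ch = value[i]
        if ch == "\\":
            i += 2
            continue
        if ch == '"':
            in_quotes = not in_quotes
        elif ch == "!" and not in_quotes:
            return value[:i].rstrip(), value[i + 1:].strip()
        i += 1
    return value.rstrip(), None


def read_obo(
    source: IO[str] | str,
    donor_registry: DonorRegistry | None = None,
) -> Thesaurus:
    """Parse an OBO document into a Thesaurus.

    Donor xrefs are mapped back to registry codes via the scientific name
    (spaces and underscores interchangeable); when the annotated name is
    more specific than any registry entry the code is recovered from the
    term's own designation and the verbatim name is kept on the term.
    """
    donor_registry = donor_registry or default_donor_registry()
    text = source if isinstance(source, str) else source.read()
    lines = text.splitlines()

    metadata: dict[str, str] = {}
    stanzas: list[tuple[int, dict]] = []  # (line, collected fields)
    extra_stanzas: list[str] = []
    current: dict | None = None
    extra: list[str] | None = None

    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip()
        if extra is not None:
            if line.startswith("["):
                extra_stanzas.append("\n".join(extra))
                extra = None
            else:
                extra.append(line)
                continue
        if not line:
            continue
        if line == "[Term]":
            current = {
                "line": lineno,
                "id": None,
                "name": None,
                "definition": None,
                "comment": None,
                "synonyms": [],
                "parent": None,
                "traits": [],
                "bch": None,
                "donor": None,
                "other": [],
            }
            stanzas.append((lineno, current))
            continue
        if line.startswith("["):  # e.g. [Typedef]: preserved verbatim
            current = None
            extra = [line]
            continue
        m = _TAG_RE.match(line)
        if m is None:
            raise OboParseError(f"malformed tag line {line!r}", lineno)
        tag, value = m.group(1), m.group(2)
        if current is None:
            metadata[tag] = value
            continue
        _apply_tag(current, tag, value, lineno, donor_registry)
    if extra is not None:
        extra_stanzas.append("\n".join(extra))

    thesaurus = Thesaurus(metadata=metadata or None)
    thesaurus.extra_stanzas = extra_stanzas

    terms: dict[str, ElementTerm] = {}
    order: list[str] = []
    for lineno, st in stanzas:
        if st["id"] is None:
            raise OboParseError("[Term] stanza has no id", lineno)
        tid = st["id"]
        if tid in terms:
            raise OboParseError(f"duplicate term id {tid}", lineno)
        donor_code, donor_text = _resolve_donor(
            st["donor"], st["name"], donor_registry
        )
        modification = None
        if st["name"]:
            try:
                parsed = grammar.parse_name(
                    st["name"], donor_registry=donor_registry
                )
                modification = parsed.modifier
            except Exception:
                modification = None
        terms[tid] = ElementTerm(
            term_id=tid,
            name=st["name"] or "",
            parent_id=st["parent"],
            definition=st["definition"],
            comment=st["comment"],
            synonyms=st["synonyms"],
            trait_refs=st["traits"],
            bch_id=st["bch"],
            other_xrefs=st["other"],
            donor=donor_code,
            donor_text=donor_text,
            modification=modification,
        )
        order.append(tid)

    # insert root-first so levels are computable
    remaining = dict(terms)
    inserted: set[str] = set()
    progress = True
    while remaining and progress:
        progress = False
        for tid in list(order):
            if tid not in remaining:
                continue
            term = remaining[tid]
            if term.parent_id is None or term.parent_id in inserted:
                thesaurus.add_term(term)
                inserted.add(tid)
                del remaining[tid]
                progress = True
    if remaining:
        tid = next(iter(remaining))
        raise OboParseError(
            f"is_a target {remaining[tid].parent_id!r} of {tid} cannot be "
            "resolved"
        )
    return thesaurus


def _apply_tag(
    st: dict,
    tag: str,
    value: str,
    lineno: int,
    donor_registry: DonorRegistry,
) -> None:
    if tag == "id":
        st["id"] = normalize_id(value)
        return
    if tag == "name":
        st["name"] = value.strip()
        return
    if tag == "def":
        m = _DEF_RE.match(value.strip())
        if m is None:
            raise OboParseError(f"malformed def line {value!r}", lineno)
        citations = tuple(
            _unescape(c.strip())
            for c in re.split(r"(?<!\\),", m.group(2) or "")
            if c.strip()
        )
        st["definition"] = Definition(_unescape(m.group(1)), citations)
        return
    if tag == "comment":
        st["comment"] = value.strip()
        return
    if tag == "synonym":
        m = _SYNONYM_RE.match(value.strip())
        if m is None:
            raise OboParseError(f"malformed synonym line {value!r}", lineno)
        st["synonyms"].append(_unescape(m.group(1)))
        return
    if tag == "is_a":
        target, _comment = _strip_bang_comment(value)
        if st["parent"] is not None:
            raise OboParseError(
                "second is_a line (the thesaurus is mono-hierarchical)",
                lineno,
            )
        st["parent"] = normalize_id(target)
        return
    if tag == "xref":
        value, _comment = _strip_bang_comment(value)
        value = value.strip()
        m = _BCH_RE.match(value)
        if m:
            st["bch"] = int(m.group(1))
            return
        m = _TRAIT_RE.match(value)
        if m:
            st["traits"].append(
                TraitRef(f"t:{m.group(2)}", m.group(3) or None)
            )
            return
        m = _DONOR_RE.match(value)
        if m:
            st["donor"] = m.group(1).strip()
            return
        ns, sep, val = value.partition(":")
        if not sep:
            ns, val = "xref", value
        st["other"].append((ns, val))
        return
    # unknown tag: preserved as a tagged pair
    st["other"].append((f"tag:{tag}", value))


def _resolve_donor(
    donor_value: str | None,
    name: str | None,
    donor_registry: DonorRegistry,
) -> tuple[str | None, str | None]:
    if donor_value is None:
        return None, None
    text = donor_value.replace("_", " ").strip()
    code = donor_registry.code_for_name(text)
    if code is None and donor_value in donor_registry:
        return donor_value, None
    if code is None and name:
        try:
            parsed = grammar.parse_name(name, donor_registry=donor_registry)
            code = parsed.donor
        except Exception:
            code = None
    # donor_text is only kept when it adds information beyond the
    # registry's scientific name for the code (e.g. a strain)
    if code is not None:
        entry = donor_registry.get(code)
        if entry is not None and entry.scientific_name.strip() == text:
            return code, None
    return code, text


def write_obo(
    thesaurus: Thesaurus,
    stream: IO[str] | None = None,
    donor_registry: DonorRegistry | None = None,
) -> str:
    """Serialise a thesaurus deterministically; returns the text.

    Stanzas are sorted by term id and tags emitted in fixed order, so
    two writes of equal thesauri are byte-identical.
    """
    donor_registry = donor_registry or default_donor_registry()
    out = io.StringIO()
    for key, value in thesaurus.metadata.items():
        out.write(f"{key}: {value}\n")

    for tid in sorted(thesaurus.terms):
        term = thesaurus.terms[tid]
        out.write("\n[Term]\n")
        out.write(f"id: {term.term_id}\n")
        out.write(f"name: {term.name}\n")
        if term.definition is not None:
            cites = ", ".join(
                c.replace(",", "\\,") for c in term.definition.citations
            )
            out.write(
                f'def: "{_escape_quoted(term.definition.text)}" [{cites}]\n'
            )
        if term.comment is not None:
            out.write(f"comment: {term.comment}\n")
        for syn in term.synonyms:
            out.write(f'synonym: "{_escape_quoted(syn)}" EXACT []\n')
        if term.parent_id is not None:
            parent = thesaurus.terms.get(term.parent_id)
            suffix = f" ! {parent.name}" if parent is not None else ""
            out.write(f"is_a: {term.parent_id}{suffix}\n")
        for ref in term.trait_refs:
            line = f"xref: Trait:t\\:{ref.trait_id[2:]}"
            if ref.label:
                line += f' "{_escape_quoted(ref.label)}"'
            out.write(line + "\n")
        if term.bch_id is not None:
            out.write(f"xref: BCH:{term.bch_id}\n")
        donor_name = term.donor_text
        if donor_name is None and term.donor is not None:
            entry = donor_registry.get(term.donor)
            donor_name = entry.scientific_name if entry else term.donor
        if donor_name is not None:
            out.write(f"xref: Donor:{donor_name.replace(' ', '_')}\n")
        for ns, val in term.other_xrefs:
            if ns.startswith("tag:"):
                out.write(f"{ns[4:]}: {val}\n")
            else:
                out.write(f"xref: {ns}:{val}\n")

    for stanza in thesaurus.extra_stanzas:
        out.write("\n" + stanza.rstrip("\n") + "\n")

    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def to_tsv(thesaurus: Thesaurus) -> str:
    """Spreadsheet export: one row per term, sorted by id."""
    rows = [
        "term_id\tlevel\tname\tparent_id\tdonor\tbch_id\ttraits\tsynonyms"
    ]
    for tid in sorted(thesaurus.terms):
        t = thesaurus.terms[tid]
        rows.append(
            "\t".join(
                [
                    t.term_id,
                    "" if t.level is None else str(t.level),
                    t.name,
                    t.parent_id or "",
                    t.donor or "",
                    "" if t.bch_id is None else str(t.bch_id),
                    "|".join(r.trait_id for r in t.trait_refs),
                    "|".join(t.synonyms),
                ]
            )
        )
    return "\n".join(rows) + "\n"
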