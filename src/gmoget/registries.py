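"""Prefix, donor and species-abbreviation registries.

The prefix registry maps the one/two-letter element-type codes used at the
head of a designation (CS-, P-, T-, ...) to the element type they denote.
The donor registry maps organism mnemonic codes (UniProt-style species
codes, virus acronyms, or SYNTH for synthetic/hybrid elements) to their
scientific names.  Both ship with packaged defaults and can be replaced by
local files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import IO, Iterable

from .errors import RegistryError

# ---------------------------------------------------------------------------
# Element-type prefixes

#: Default prefix -> element-type table.
DEFAULT_PREFIXES: dict[str, str] = {
    "CS": "Coding sequence",
    "E": "Enhancer",
    "I": "Intron",
    "L": "Leader",
    "O": "Other sequence",
    "P": "Promoter",
    "R": "Regulatory element other than P, T, I, L or TP",
    "T": "Terminator",
    "TP": "Transit peptide",
    "V": "Vector fragment",
}

#: The controlled list of level-1 element-type names (lowercase).
LEVEL1_TYPES: tuple[str, ...] = (
    "coding sequence",
    "enhancer",
    "gene silencing elements",
    "genomic sequence",
    "intron",
    "leader",
    "promoter",
    "other regulatory elements",
    "terminator",
    "transit peptide",
    "unknown origin",
    "vector fragment",
)

#: level-1 type name -> prefixes allowed below that branch.  The three
#: catch-all types share the O prefix; gene-silencing elements carry the
#: prefix of the silenced element type (any registered prefix) together
#: with an siRNA modifier suffix.
LEVEL1_ALLOWED_PREFIXES: dict[str, frozenset[str]] = {
    "coding sequence": frozenset({"CS"}),
    "enhancer": frozenset({"E"}),
    "gene silencing elements": frozenset(DEFAULT_PREFIXES),
    "genomic sequence": frozenset({"O"}),
    "intron": frozenset({"I"}),
    "leader": frozenset({"L"}),
    "promoter": frozenset({"P"}),
    "other regulatory elements": frozenset({"R"}),
    "terminator": frozenset({"T"}),
    "transit peptide": frozenset({"TP"}),
    "unknown origin": frozenset({"O"}),
    "vector fragment": frozenset({"V"}),
}


class PrefixRegistry:
    """Maps element-type codes (1-2 uppercase characters) to descriptions."""

    def __init__(self, entries: dict[str, str] | None = None):
        entries = dict(DEFAULT_PREFIXES if entries is None else entries)
        for code in entries:
            if not re.fullmatch(r"[A-Z]{1,2}", code):
                raise RegistryError(
                    f"prefix code {code!r} is not 1-2 uppercase characters"
                )
        self.entries = entries

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> str:
        return self.entries[code]

    def codes(self) -> list[str]:
        return sorted(self.entries)


@dataclass(frozen=True)
class DonorEntry:
    code: str
    category: str  # species | virus | synthetic
    scientific_name: str


_SPECLIST_RE = re.compile(
    r"^([A-Z0-9]{2,6})\s+([ABEVO])\s+(-?\d+):\s+N=(.+?)\s*$"
)


class DonorRegistry:
    """Mnemonic donor-code registry (species codes, virus acronyms, SYNTH).

    Species codes are uppercase 2-5 characters following UniProt speclist
    conventions; virus acronyms may be mixed case (CaMV, FMV); hybrid or
    fully synthetic elements use the fixed code SYNTH.  Matching is
    case-sensitive: the registry is authoritative for casing.
    """

    def __init__(self, entries: Iterable[DonorEntry] = ()):
        self.entries: dict[str, DonorEntry] = {}
        self._by_name: dict[str, str] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: DonorEntry) -> None:
        if entry.category not in ("species", "virus", "synthetic"):
            raise RegistryError(f"unknown donor category {entry.category!r}")
        if entry.category == "synthetic" and entry.code != "SYNTH":
            raise RegistryError("the synthetic donor code must be SYNTH")
        if entry.category == "species" and not re.fullmatch(
            r"[A-Z0-9]{2,5}", entry.code
        ):
            raise RegistryError(
                f"species code {entry.code!r} is not 2-5 uppercase characters"
            )
        if entry.code in self.entries:
            raise RegistryError(f"duplicate donor code {entry.code!r}")
        self.entries[entry.code] = entry
        self._by_name[_name_key(entry.scientific_name)] = entry.code

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> DonorEntry:
        return self.entries[code]

    def get(self, code: str) -> DonorEntry | None:
        return self.entries.get(code)

    def code_for_name(self, scientific_name: str) -> str | None:
        """Reverse lookup: scientific name (spaces or underscores) -> code."""
        return self._by_name.get(_name_key(scientific_name))

    def codes(self, category: str | None = None) -> list[str]:
        return sorted(
            c
            for c, e in self.entries.items()
            if category is None or e.category == category
        )

    @classmethod
    def from_stream(cls, stream: IO[str]) -> "DonorRegistry":
        """Load a registry from text.

        Accepts two layouts, decided per line: the native tab-separated
        layout ``CODE<TAB>category<TAB>scientific name`` and the UniProt
        speclist layout ``CODE KINGDOM TAXID: N=Name`` (kingdom V maps to
        the virus category, everything else to species).  Blank lines and
        ``#`` comments are ignored.
        """
        reg = cls()
        for lineno, raw in enumerate(stream, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                parts = line.split("\t")
                if len(parts) != 3:
                    raise RegistryError(
                        f"line {lineno}: expected 3 tab-separated fields"
                    )
                code, category, name = (p.strip() for p in parts)
                reg.add(DonorEntry(code, category, name))
                continue
            m = _SPECLIST_RE.match(line)
            if m is None:
                raise RegistryError(
                    f"line {lineno}: not a registry or speclist entry: "
                    f"{line!r}"
                )
            code, kingdom, _taxid, name = m.groups()
            category = "virus" if kingdom == "V" else "species"
            if code == "SYNTH":
                category = "synthetic"
            reg.add(DonorEntry(code, category, name))
        return reg

    @classmethod
    def from_file(cls, path) -> "DonorRegistry":
        with open(path, encoding="utf-8") as fh:
            return cls.from_stream(fh)


def _name_key(name: str) -> str:
    return " ".join(name.replace("_", " ").split()).casefold()


@lru_cache(maxsize=1)
def default_donor_registry() -> DonorRegistry:
    """The packaged donor registry (data/donors.tsv), loaded once."""
    text = (
        resources.files("gmoget").joinpath("data/donors.tsv").read_text("utf-8")
    )
    import io

    return DonorRegistry.from_stream(io.StringIO(text))


@lru_cache(maxsize=1)
def default_prefix_registry() -> PrefixRegistry:
    return PrefixRegistry()


#: Conventional genus-species abbreviations embedded in common gene
#: abbreviations (AtAHAS, ZmUbi1, ...), mapped to the donor code they
#: imply.  Stripping is applied only when the abbreviation is consistent
#: with the declared (or inferred) donor and is followed by an uppercase
#: letter or digit — never inferred from capitalisation alone.
SPECIES_ABBREVIATIONS: dict[str, str] = {
    "At": "ARATH",
    "Bn": "BRANA",
    "Gm": "SOYBN",
    "Hv": "HORVU",
    "Nt": "TOBAC",
    "Os": "ORYSA",
    "Ps": "PEA",
    "Sl": "SOLLC",
    "St": "SOLTU",
    "Ta": "WHEAT",
    "Zm": "MAIZE",
}

#: Letter-runs that keep a commonly used non-lowercase casing when a stem
#: is normalised.  Keys are the lowercase form; values the canonical
#: casing.  Applied longest key first.  CP4 is the strain-name exception:
#: it is always retained verbatim in stems.
DEFAULT_CASE_OVERRIDES: dict[str, str] = {
    "rbcs_e9": "rbcS_E9",
    "cry1ab": "cry1Ab",
    "cry1ac": "cry1Ac",
    "vip3h": "vip3H",
    "rbcs": "rbcS",
    "cp4": "CP4",
    "34s": "34S",
    "35s": "35S",
}
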