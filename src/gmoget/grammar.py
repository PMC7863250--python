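"""Element-designation grammar: parse, compose, normalise, lint.

A concrete genetic element (hierarchy level 3) is designated
``XX-YYYY-ZZZZZ``: an element-type prefix ``XX`` (CS, P, T, ...), an
abbreviated element name ``YYYY`` and a donor-organism code ``ZZZZZ``
(UniProt-style species mnemonic, virus acronym, or SYNTH for hybrid
elements).  Gene-silencing and genome-edited elements carry a modifier
suffix inside the name part (``ppo5_genome_edited``, ``xyz_siRNAas``).

Stems may legally contain hyphens (``CS-beta-gal``), so parsing anchors on
the first hyphen for the prefix and accepts the segment after the last
hyphen as donor only when it is a registry key; otherwise that segment is
part of the stem.

The normalisation rules for the name part, applied in order:

1. strip 3'/5' UTR designators (redundant with the T-/P- prefix);
2. strip a leading genus-species abbreviation (At, Zm, ...) that denotes
   the donor — the strain token CP4 is always retained;
3. write out Greek letters (β → beta);
4. replace the special characters ``.`` ``/`` ``´`` and whitespace with
   ``_``;
5. lowercase, except letter-runs with a commonly used non-lowercase
   casing (CP4epsps, cry1Ab, rbcS_E9, ...).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from enum import Enum

from .errors import (
    MissingDonorError,
    NameSyntaxError,
    UnknownPrefixError,
)
from .registries import (
    DEFAULT_CASE_OVERRIDES,
    SPECIES_ABBREVIATIONS,
    DonorRegistry,
    PrefixRegistry,
    default_donor_registry,
    default_prefix_registry,
)


class Modification(str, Enum):
    """Modifier suffixes carried inside the name part of a designation."""

    GENOME_EDITED = "genome_edited"
    SIRNA_SENSE = "siRNA_sense"
    SIRNA_ANTISENSE = "siRNA_antisense"
    SIRNA_UNDEFINED = "siRNA_undefined"

    @property
    def token(self) -> str:
        return _MODIFIER_TOKENS[self]


_MODIFIER_TOKENS: dict[Modification, str] = {
    Modification.GENOME_EDITED: "_genome_edited",
    Modification.SIRNA_SENSE: "_siRNAs",
    Modification.SIRNA_ANTISENSE: "_siRNAas",
    Modification.SIRNA_UNDEFINED: "_siRNAu",
}

# longest token first so _siRNAas is not read as _siRNAs + "a"
_TOKEN_TO_MODIFIER: list[tuple[str, Modification]] = sorted(
    ((tok, mod) for mod, tok in _MODIFIER_TOKENS.items()),
    key=lambda it: -len(it[0]),
)

#: The closed set of special characters replaced by underscores.
SPECIAL_CHARS = ".", "/", "´"

_GREEK_NAMES = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}
GREEK_TRANSLITERATION: dict[str, str] = dict(_GREEK_NAMES)
GREEK_TRANSLITERATION.update(
    {ch.upper(): name for ch, name in _GREEK_NAMES.items() if ch != "ς"}
)

_UTR_RE = re.compile(r"[\s_]*[35]\s*[′'´]?\s*UTR", re.IGNORECASE)
_DONOR_SEGMENT_RE = re.compile(r"[A-Z][A-Za-z0-9]{1,5}")


@dataclass(frozen=True)
class ParsedElementName:
    """Decomposition of a designation into prefix, stem, modifier, donor."""

    prefix: str
    stem: str
    modifier: Modification | None = None
    donor: str | None = None

    def __str__(self) -> str:
        return compose_name(self)


def parse_name(
    text: str,
    prefix_registry: PrefixRegistry | None = None,
    donor_registry: DonorRegistry | None = None,
    donor_required: bool = False,
) -> ParsedElementName:
    """Parse a designation into its parts.

    The prefix is everything before the first hyphen; the segment after
    the last hyphen is taken as donor only when it is a donor-registry
    key (case-sensitively), otherwise it stays part of the stem.  A
    recognised trailing modifier token is stripped from the stem.
    """
    prefix_registry = prefix_registry or default_prefix_registry()
    donor_registry = donor_registry or default_donor_registry()
    parsed = _split_name(text, prefix_registry, donor_registry)
    if donor_required and parsed.donor is None:
        raise MissingDonorError(
            f"{text!r} carries no registry-matching donor code"
        )
    bad = sorted(set(parsed.stem) & set(SPECIAL_CHARS))
    if bad:
        raise NameSyntaxError(
            f"name part of {text!r} contains forbidden characters {bad}"
        )
    return parsed


def _split_name(
    text: str,
    prefix_registry: PrefixRegistry,
    donor_registry: DonorRegistry,
) -> ParsedElementName:
    """Lenient three-way split: checks structure, not stem content."""
    text = text.strip()
    if not text:
        raise NameSyntaxError("empty designation")
    prefix, sep, rest = text.partition("-")
    if not sep:
        raise UnknownPrefixError(
            f"{text!r} has no prefix separator (expected XX-YYYY[-ZZZZZ])"
        )
    if prefix not in prefix_registry:
        raise UnknownPrefixError(f"unknown element-type prefix {prefix!r}")

    donor: str | None = None
    stem = rest
    head, sep, tail = rest.rpartition("-")
    if sep and tail in donor_registry:
        donor, stem = tail, head
    stem, modifier = split_modifier(stem)
    if not stem:
        raise NameSyntaxError(f"{text!r} has an empty name part")
    return ParsedElementName(prefix, stem, modifier, donor)


def split_modifier(stem: str) -> tuple[str, Modification | None]:
    """Strip a trailing modifier token (``_genome_edited``, ``_siRNA*``)."""
    for token, mod in _TOKEN_TO_MODIFIER:
        if stem.endswith(token):
            return stem[: -len(token)], mod
    return stem, None


def compose_name(parts: ParsedElementName) -> str:
    """Emit the canonical ``XX-stem[modifier][-ZZZZZ]`` designation."""
    if not parts.prefix or not parts.stem:
        raise NameSyntaxError("prefix and stem must be non-empty")
    bad = sorted(set(parts.stem) & set(SPECIAL_CHARS))
    if bad:
        raise NameSyntaxError(f"stem contains forbidden characters {bad}")
    name = f"{parts.prefix}-{parts.stem}"
    if parts.modifier is not None:
        name += parts.modifier.token
    if parts.donor:
        name += f"-{parts.donor}"
    return name


def infer_donor(
    stem: str,
    species_abbreviations: dict[str, str] | None = None,
) -> str | None:
    """Donor code implied by a leading genus-species abbreviation, if any.

    Requires a camel-case boundary (abbreviation followed by an uppercase
    letter or digit) so stems like ``bar`` are never touched.
    """
    table = (
        SPECIES_ABBREVIATIONS
        if species_abbreviations is None
        else species_abbreviations
    )
    if stem.startswith("CP4"):
        return None
    for abbrev in sorted(table, key=len, reverse=True):
        if (
            stem.startswith(abbrev)
            and len(stem) > len(abbrev)
            and (stem[len(abbrev)].isupper() or stem[len(abbrev)].isdigit())
        ):
            return table[abbrev]
    return None


def _strip_species_abbrev(
    stem: str,
    donor: str | None,
    species_abbreviations: dict[str, str],
) -> str:
    if donor is None or stem.startswith("CP4"):
        return stem
    for abbrev, code in species_abbreviations.items():
        if (
            code == donor
            and stem.startswith(abbrev)
            and len(stem) > len(abbrev)
            and (stem[len(abbrev)].isupper() or stem[len(abbrev)].isdigit())
        ):
            return stem[len(abbrev):]
    return stem


def _strip_utr(stem: str) -> str:
    new = _UTR_RE.sub("", stem)
    if new != stem:
        new = new.strip(" _")
    return new


def _transliterate_greek(stem: str) -> str:
    return "".join(GREEK_TRANSLITERATION.get(ch, ch) for ch in stem)


def _replace_special(stem: str) -> str:
    for ch in SPECIAL_CHARS:
        stem = stem.replace(ch, "_")
    stem = re.sub(r"\s+", "_", stem.strip())
    return stem


def _apply_case(stem: str, case_overrides: dict[str, str]) -> str:
    lowered = stem.lower()
    for key in sorted(case_overrides, key=len, reverse=True):
        lowered = lowered.replace(key, case_overrides[key])
    return lowered


def normalize_stem(
    raw: str,
    donor: str | None = None,
    case_overrides: dict[str, str] | None = None,
    species_abbreviations: dict[str, str] | None = None,
) -> str:
    """Canonical form of a name part under the five normalisation rules."""
    overrides = (
        DEFAULT_CASE_OVERRIDES if case_overrides is None else case_overrides
    )
    species = (
        SPECIES_ABBREVIATIONS
        if species_abbreviations is None
        else species_abbreviations
    )
    if not raw:
        raise NameSyntaxError("empty name part")
    stem = _strip_utr(raw)
    stem = _strip_species_abbrev(stem, donor, species)
    stem = _transliterate_greek(stem)
    stem = _replace_special(stem)
    stem = _apply_case(stem, overrides)
    if not stem:
        raise NameSyntaxError(
            f"name part {raw!r} is empty after normalisation"
        )
    return stem


@dataclass(frozen=True)
class Diagnostic:
    """One violated naming rule, with the offending span and a fix."""

    rule: str
    span: str
    message: str
    suggestion: str | None = None


def _unsupported_chars(stem: str) -> list[str]:
    out = []
    for ch in stem:
        if ch.isalnum() or ch in "_-" or ch in SPECIAL_CHARS:
            continue
        if ch in GREEK_TRANSLITERATION or ch.isspace():
            continue
        if ch in "′'´":  # consumed by the UTR rule when applicable
            out.append(ch)
            continue
        if unicodedata.category(ch).startswith(("P", "S")) or not ch.isascii():
            out.append(ch)
    return sorted(set(out))


def canonical_name(
    text: str,
    donor: str | None = None,
    prefix_registry: PrefixRegistry | None = None,
    donor_registry: DonorRegistry | None = None,
    case_overrides: dict[str, str] | None = None,
    species_abbreviations: dict[str, str] | None = None,
) -> str:
    """Fully canonical designation for *text*.

    A donor absent from the designation may be supplied explicitly or is
    inferred from a leading species abbreviation (CS-AtAHAS → donor ARATH
    → CS-ahas-ARATH).
    """
    parsed = parse_name(text, prefix_registry, donor_registry)
    species = (
        SPECIES_ABBREVIATIONS
        if species_abbreviations is None
        else species_abbreviations
    )
    effective_donor = parsed.donor or donor or infer_donor(parsed.stem, species)
    stem = normalize_stem(
        parsed.stem, effective_donor, case_overrides, species
    )
    return compose_name(
        ParsedElementName(parsed.prefix, stem, parsed.modifier, effective_donor)
    )


def lint_name(
    text: str,
    prefix_registry: PrefixRegistry | None = None,
    donor_registry: DonorRegistry | None = None,
    donor: str | None = None,
    donor_required: bool = False,
    case_overrides: dict[str, str] | None = None,
    species_abbreviations: dict[str, str] | None = None,
) -> list[Diagnostic]:
    """Machine-readable diagnostics for a designation.

    One diagnostic per violated naming rule, each carrying the rule id,
    the offending span and (where determinable) the fully canonical
    replacement.  Empty list iff *text* is already canonical.  The
    lowercase rule and the species-abbreviation rule are one rule in the
    naming convention, so re-casing implied by a stripped abbreviation is
    folded into the species diagnostic.
    """
    prefix_registry = prefix_registry or default_prefix_registry()
    donor_registry = donor_registry or default_donor_registry()
    overrides = (
        DEFAULT_CASE_OVERRIDES if case_overrides is None else case_overrides
    )
    species = (
        SPECIES_ABBREVIATIONS
        if species_abbreviations is None
        else species_abbreviations
    )

    try:
        parsed = _split_name(text, prefix_registry, donor_registry)
    except UnknownPrefixError as exc:
        return [Diagnostic("unknown-prefix", text.partition("-")[0], str(exc))]
    except NameSyntaxError as exc:
        return [Diagnostic("name-syntax", text, str(exc))]

    diagnostics: list[Diagnostic] = []
    effective_donor = parsed.donor or donor or infer_donor(parsed.stem, species)

    def suggest(stem: str) -> str:
        return compose_name(
            ParsedElementName(
                parsed.prefix, stem, parsed.modifier, effective_donor
            )
        )

    try:
        canonical_stem = normalize_stem(
            parsed.stem, effective_donor, overrides, species
        )
    except NameSyntaxError as exc:
        return [Diagnostic("name-syntax", text, str(exc))]
    suggestion = suggest(canonical_stem)

    stem = parsed.stem
    # unrecognised donor-like trailing segment: report it once instead of
    # cascading into a spurious letter-case diagnostic
    unknown_donor_segment = None
    head, sep, tail = stem.rpartition("-")
    if (
        sep
        and parsed.donor is None
        and _DONOR_SEGMENT_RE.fullmatch(tail)
        and tail.isupper()
    ):
        unknown_donor_segment = tail
        diagnostics.append(
            Diagnostic(
                "unknown-donor",
                tail,
                f"trailing segment {tail!r} looks like a donor code but is "
                "not in the donor registry",
            )
        )
        stem = head

    after_utr = _strip_utr(stem)
    if after_utr != stem:
        diagnostics.append(
            Diagnostic(
                "utr-designator",
                stem,
                "3'/5' UTR designators are implied by the element-type "
                "prefix and must be removed",
                suggestion,
            )
        )
    stem = after_utr

    after_species = _strip_species_abbrev(stem, effective_donor, species)
    species_fired = after_species != stem
    if species_fired:
        diagnostics.append(
            Diagnostic(
                "species-abbreviation",
                stem[: len(stem) - len(after_species)],
                "embedded species abbreviation belongs in the donor part",
                suggestion,
            )
        )
    stem = after_species

    after_greek = _transliterate_greek(stem)
    if after_greek != stem:
        offending = "".join(
            sorted({c for c in stem if c in GREEK_TRANSLITERATION})
        )
        diagnostics.append(
            Diagnostic(
                "greek-letter",
                offending,
                "Greek symbols are written out",
                suggestion,
            )
        )
    stem = after_greek

    unsupported = _unsupported_chars(stem)
    if unsupported:
        diagnostics.append(
            Diagnostic(
                "unsupported-character",
                "".join(unsupported),
                "characters outside the documented special set are not "
                "replaced automatically; rename the element",
            )
        )

    specials = sorted(
        {c for c in stem if c in SPECIAL_CHARS or c.isspace()}
    )
    if specials:
        diagnostics.append(
            Diagnostic(
                "special-character",
                "".join(specials),
                "special characters are exchanged by an underline",
                suggestion,
            )
        )
    stem = _replace_special(stem)

    if not species_fired and _apply_case(stem, overrides) != stem:
        diagnostics.append(
            Diagnostic(
                "letter-case",
                stem,
                "the name part is written in lowercase letters unless the "
                "commonly used abbreviation uses uppercase",
                suggestion,
            )
        )

    if parsed.donor is None and effective_donor is not None:
        if not species_fired and unknown_donor_segment is None:
            diagnostics.append(
                Diagnostic(
                    "missing-donor",
                    text,
                    f"designation lacks its donor part -{effective_donor}",
                    suggestion,
                )
            )
    elif parsed.donor is None and donor_required:
        diagnostics.append(
            Diagnostic(
                "missing-donor",
                text,
                "designation carries no registry-matching donor code",
            )
        )

    if not diagnostics and suggestion != text:
        # canonicalisation changed something not covered above (e.g. a
        # stray space around hyphens)
        diagnostics.append(
            Diagnostic("name-syntax", text, "not in canonical form", suggestion)
        )
    return diagnostics
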