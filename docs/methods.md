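# Methods

## The vocabulary model

The thesaurus follows the ISO 25964 notion of a mono-hierarchy rather
than a full ontology: one preferred term per concept, any number of
non-preferred synonyms, and exactly one broader-term relation (`is_a`)
per term.  The result is a rooted tree, which buys two properties a DAG
would not give: query expansions of sibling terms are provably disjoint,
and every term has a unique level.  Levels are not stored independently
but computed as parent level + 1 at insertion, so they can never drift
from the topology.  The five levels carry fixed meanings: 0 the root
concept "genetic element", 1 the twelve element types (closed list), 2
functional long names, 3 concrete elements with full designations, 4
sequence variants.

Term identifiers are `e:` plus exactly seven digits.  The printed
variant with a space after the colon (`e: 0000415`) is accepted on input
and normalised, because whitespace-free identifiers are required inside
OBO xref targets.  Element and trait (`t:`) identifiers are treated as
two independent namespaces; nothing in the data suggests a shared
counter, and independent namespaces let either side grow without
coordination.

The validator reports violations as data rather than raising, and works
directly from the parent links rather than the maintained indexes, so it
can diagnose states that the guarded insertion path would have refused
(useful when reading third-party files).  Trait references attached
above level 3 are reported as warnings, not errors: the convention puts
them on concrete elements, but breaking a file over it would be
overzealous.

## The designation grammar

A concrete element is designated `XX-YYYY-ZZZZZ`.  Parsing cannot be a
naive three-way split because stems legally contain hyphens
(`CS-beta-gal`): the prefix is everything before the first hyphen, and
the trailing segment is a donor only when it is, case-sensitively, a
donor-registry key.  The registry is authoritative for casing (virus
acronyms are mixed-case: CaMV, FMV); species codes are uppercase 2–5
characters in the UniProt speclist style, and fully synthetic or hybrid
elements use the fixed code SYNTH.

Normalisation applies five rules in a fixed order: strip 3′/5′ UTR
designators (redundant given a T- or P- prefix); strip a leading
genus-species abbreviation (At, Zm, ...) when it is consistent with the
declared or inferred donor — never from capitalisation alone, so stems
like `bar` are safe, and the strain token `CP4` is always retained;
transliterate Greek letters to their spelled-out names; replace the
special characters `.` `/` `´` and whitespace with underscores; and
lowercase, except letter-runs with an established non-lowercase casing
(`CP4`, `cry1Ab`, `vip3H`, `rbcS_E9`, `35S`), shipped as a case-override
table and applied longest-match-first.  The special-character set is
treated as closed: characters outside it raise a diagnostic instead of
being replaced silently, because the convention's own list is
illustrative and silent guessing would corrupt names.  Normalisation is
idempotent (property-tested), which guarantees that linting a canonical
name never suggests further changes.

The linter emits one diagnostic per violated rule.  The lowercase rule
and the species-abbreviation rule are a single rule of the convention,
so the re-casing implied by a stripped abbreviation is folded into the
species diagnostic rather than double-reported.  When a name lacks its
donor part but a species abbreviation implies one, the donor is inferred
from the abbreviation table and included in the suggested replacement.

## The OBO dialect

Reading and writing target OBO flat-file 1.2 conventions with the local
dialect habits: `Trait:t\:0000006` (escaped colon, accepted escaped or
not on read), `Donor:` xrefs carrying the organism's scientific name
with underscores for spaces, and `is_a` lines with the parent's name as
a trailing `!` comment.  Donor xrefs are mapped back to registry codes
by reverse name lookup; when the annotated name is more specific than
the registry entry (a strain such as "Agrobacterium tumefaciens ssp.
CP4"), the code is recovered from the term's own designation and the
verbatim name is kept on the term, so round trips lose nothing.  Writes
are deterministic — stanzas sorted by term id, tags in fixed order,
synonyms in stored order — giving the byte-stability that version
control of vocabulary releases needs.  Synonym scope is always written
EXACT; the source material does not distinguish scopes.  Non-Term
stanzas (e.g. `[Typedef]`) are preserved verbatim and re-emitted.

## Query expansion and the detection matrix

`expand(t)` is the reflexive-transitive closure of `is_a` below `t`,
computed from the children index; the test suite checks it against an
independent closure computed by repeated edge expansion over the parent
links.  Synonym and name search is exact and case-insensitive because
its purpose is automated cross-database joins; substring search exists
separately for interactive use.  BCH record ids are not assumed unique
across terms, so cross-reference resolution always returns a (sorted)
list.

The detection matrix is three-valued by design.  A method specific for
target element `m` *detects* GMO `g` when some element annotated on `g`
lies in `expand(m)`: annotation with a narrower variant guarantees the
target sequence is present.  When no such element exists but some
annotated element is a strict ancestor of `m` — the GMO is annotated at
level 3 while the assay is specific for one level-4 variant — the
variant's presence is undetermined and the call is *possible*; a binary
matrix would have to choose between overclaiming and discarding the
information.  A `binary` flag collapses *possible* to *not detected*
for consumers that need two values.  A level-4 annotation never
satisfies a method targeting a different level-3 parent, even under a
shared level-2 grandparent: detection is strictly closure-based, since
sharing a functional group does not imply sharing the target sequence.
Method targets at level 2 are permitted — screening assays commonly
target broad elements — with identical closure semantics.

## The packaged fixture and the random generators

The packaged 40-term thesaurus (root, 12 level-1 types, 11 level-2
groups, 15 level-3 elements, 1 level-4 variant) reproduces its source
records verbatim, including definition and function texts with their
literature citations, synonyms, donor organisms, trait references and
BCH record ids.  Two printed cells that look like transcription
artifacts are reproduced as printed and flagged in
`src/gmoget/data/FIXTURE_NOTES.md` rather than corrected; one printed
name that does not conform to the grammar (`P-34S FMV`) is recorded
under its grammar-conformant form `P-34S-FMV` with the printed form as a
synonym.  The fixture ships both as a checked-in OBO file and as the
builder that regenerates it; a test asserts byte-for-byte equality of
the two.

The random thesaurus generator emulates the structural features the
engine cares about — branch shapes across all twelve element types
(including silencing elements with `_siRNA*` modifiers), donors drawn
from the packaged registry, optional synonyms, BCH ids and trait refs —
with grammar-conformant names built from a lowercase syllable alphabet.
It does not emulate realistic biological naming, definition text, or the
skewed branch-size distribution of a production vocabulary; passing
round-trip and closure properties on it therefore demonstrates
correctness of the machinery, not coverage of real-world content
quirks.  Annotation generation gives each GMO up to four elements, each
kept with the annotation-rate probability (rate 1 guarantees at least
one), and methods target uniformly sampled level ≥ 2 terms.  All
generation is driven by `random.Random(seed)`: same seed, same output.

## Problem sizes and numerical choices

The property checks run on 200 random thesauri of up to ~100 terms for
serialisation round-trips and closure agreement, and 100 random
(thesaurus, GMOs, methods) instances for matrix agreement and
monotonicity — sizes at which the brute-force oracles are still exact
and instant while exercising every branch shape the generator can
produce.  There are no tolerances anywhere: every comparison in the
package is exact (string, set or integer equality).  Ties are broken
deterministically throughout — sibling order by insertion, serialised
order by term id, search results sorted by term id.

## Known limitations

- No DAG/multi-parent support, by design; a second `is_a` line is a
  parse error, not a merge.
- The donor registry is a local file; there is no live lookup of
  UniProt or virus-acronym catalogues, and no derivation of new
  mnemonics from scientific names.
- The trait vocabulary is modelled as opaque `t:` references only.
- Sequence data, amplicon verification and PCR method design are out of
  scope: detection prediction is purely annotation- and hierarchy-based.
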