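# gmoget — a controlled-vocabulary toolkit for GMO genetic elements

GMO databases maintained by different organisations (biosafety
registries, enforcement-lab method collections, national reference
databases) describe the same transgenic inserts with different words.
That blocks automated data exchange: the same *bar* gene may appear as
"PAT", "Bialaphos resistance" or "CS-bar-STRHY" depending on the system.
`gmoget` implements the machinery behind a shared controlled vocabulary
for the genetic elements introduced or altered in GMOs — including
genome-edited organisms — aimed at database maintainers, inspection
services and enforcement laboratories.

The toolkit provides four things:

1. **A mono-hierarchical thesaurus engine** (ISO 25964 style): every
   term has one preferred name, synonyms, and exactly one broader term
   via the sole relation `is_a`.  Five levels: the root concept
   (level 0), twelve element types — coding sequence, promoter,
   terminator, intron, ... (level 1), functional groups such as
   *CS-phosphinothricin N-acetyltransferase* (level 2), concrete
   elements (level 3), and sequence variants (level 4).  A structural
   validator reports every violation of the tree, level, naming and
   cross-reference rules as data.

2. **The element-designation grammar** `XX-YYYY-ZZZZZ`: element-type
   prefix `XX` (CS, E, I, L, O, P, R, T, TP, V), lowercase abbreviated
   name `YYYY` (with modifier suffixes `_genome_edited` and `_siRNAs/as/u`
   for edited and silencing elements), and donor-organism code `ZZZZZ`
   (UniProt-style species mnemonic, virus acronym, or SYNTH for hybrid
   constructs).  A parser, composer, normaliser and linter enforce the
   rules: species abbreviations move from the stem into the donor part
   (`CS-AtAHAS` → `CS-ahas-ARATH`), Greek letters are written out
   (`β` → `beta`), special characters become underscores, UTR designators
   are dropped, and the strain token `CP4` is retained verbatim.

3. **A lossless OBO flat-file dialect** with deterministic writes
   (stanzas sorted by id, fixed tag order), escaped trait xrefs
   (`Trait:t\:0000006`), donor xrefs and `is_a` name comments, plus TSV
   export for spreadsheet users.

4. **Hierarchy-aware querying and detection-matrix prediction.**
   `expand(term)` is the reflexive-transitive `is_a` closure, so a
   level-2 query finds GMOs annotated at level 3 or 4.  `predict`
   computes the GMO × method matrix: a method *detects* a GMO when an
   annotated element lies in the closure of the method's target element;
   when the annotation is only a strict ancestor of a variant-specific
   target the call is *possible* (presence of the variant unconfirmed);
   otherwise *not detected*.

## Worked example

```python
from gmoget import (build_paper_fixture, expand, resolve_xref,
                    canonical_name, predict, GMORecord, MethodSpec)

th = build_paper_fixture()          # 40-term packaged thesaurus
for tid in sorted(expand(th, "e:0000188")):
    print(tid, th[tid].name)
```

```
e:0000188 CS-phosphinothricin N-acetyltransferase
e:0000206 CS-pat-STRVR
e:0000415 CS-bar-STRHY
```

One level-2 query returns both glufosinate-tolerance genes (*bar* from
*Streptomyces hygroscopicus*, *pat* from *S. viridochromogenes*).
Cross-database resolution and name canonicalisation:

```python
>>> resolve_xref(th, "BCH", 14972)
['e:0000415']
>>> canonical_name("CS-AtAHAS")
'CS-ahas-ARATH'
```

The BCH registry record 14972 maps straight onto the *bar* element term;
the free-text name with an embedded *Arabidopsis thaliana* abbreviation
is rewritten with the donor in its proper place.  Detection prediction
(`examples/detection_matrix.py`):

```
GMO         cry1Ab-assay   cry1Ab10-assay
GMO-A           detected         detected
GMO-B       not_detected     not_detected
GMO-C           detected         possible
```

GMO-A carries the level-4 variant `CS-cry1Ab10-BACTK`, so the broader
level-3 assay still detects it; GMO-C is annotated only at level 3, so
the variant-specific assay reports *possible* rather than overclaiming.

The `examples/` directory contains one short script per capability, and
the `gmoget` console command exposes `validate`, `lint-names`, `query`,
`convert`, `matrix` and `fixture` subcommands for shell use
(`gmoget fixture | gmoget validate /dev/stdin`).

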