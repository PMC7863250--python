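# Notes on the packaged worked-example thesaurus

The fixture reproduces its source tables verbatim, including two cells
that look like transcription artifacts.  They are flagged here rather
than corrected, because the fixture's job is fidelity to the published
record:

- `CS-ppo_genome_edited-AGABB` (e:0000208) is listed with trait
  t:0000029 "Glufosinate tolerance" although its definition and comment
  describe reduced enzymatic browning of *Agaricus bisporus*.  The
  printed trait is kept.
- `CS-bar-STRHY` (e:0000415) appears with trait t:0000006 "Herbicide
  tolerance > Glufosinate tolerance" in its full attribute record and
  with t:0000029 "Glufosinate tolerance" in the examples table.  Both
  printed refs are kept, t:0000006 first.
- The promoter printed as `P-34S FMV` does not conform to the
  XX-YYYY-ZZZZZ designation grammar (space instead of hyphen before the
  donor acronym).  The fixture records the grammar-conformant
  `P-34S-FMV` as the preferred name and keeps the printed form as a
  synonym.
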