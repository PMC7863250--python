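"""Build the packaged element thesaurus and query it by hierarchy.

The thesaurus is a mono-hierarchy: each genetic element has exactly one
broader term.  Expanding a level-2 functional group therefore finds every
concrete element (level 3) and sequence variant (level 4) below it — the
mechanism that lets a coarse annotation in one database match a finer one
in another.
"""

from gmoget import build_paper_fixture, descendants, expand, find, resolve_xref

th = build_paper_fixture()
print(f"thesaurus: {len(th)} terms, root {th.root_id!r}")

pat_group = "e:0000188"  # CS-phosphinothricin N-acetyltransferase
print(f"\nexpand({pat_group}) — the group plus everything below it:")
for tid in sorted(expand(th, pat_group)):
    term = th[tid]
    print(f"  level {term.level}  {tid}  {term.name}")

print("\nsynonym search 'PAT' (a non-preferred name):")
for tid in find(th, "PAT", fields=("synonym",)):
    print(f"  {tid}  {th[tid].name}")

print("\ncross-database lookup BCH:14972:")
for tid in resolve_xref(th, "BCH", 14972):
    print(f"  {tid}  {th[tid].name}")

leaf = "e:0000415"
print(f"\ndescendants({leaf}) (a leaf): {descendants(th, leaf)!r}")
# The expansion above shows two sibling glufosinate-tolerance genes (bar,
# pat) retrieved from one level-2 query; the BCH lookup maps an external
# database record id straight onto an element term.
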