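"""Canonicalise free-text element names under the designation grammar.

A concrete element is designated XX-YYYY-ZZZZZ: element-type prefix,
lowercase abbreviated name, donor-organism code.  The linter reports each
violated naming rule with a suggested canonical replacement.
"""

from gmoget import canonical_name, lint_name

candidates = [
    "CS-AtAHAS",           # species abbreviation embedded in the stem
    "P-ZmUbi1",            # same, maize polyubiquitin promoter
    "T-nos 3′ UTR-RHIRD",  # redundant UTR designator
    "CS-CP4epsps-RHIRD",   # already canonical (CP4 strain exception)
    "P-ubi1-MAIZE",        # already canonical
]

for name in candidates:
    diags = lint_name(name)
    if not diags:
        print(f"{name:24s} OK (canonical)")
        continue
    fixed = canonical_name(name)
    for d in diags:
        print(f"{name:24s} {d.rule:22s} -> {fixed}")
# Each flagged name is rewritten to its canonical designation; donors
# implied by a species abbreviation (At -> ARATH) move into the -ZZZZZ
# donor part.
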