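"""Predict which GMOs an element-specific detection method identifies.

The prediction uses annotations and the hierarchy alone: a method
detects a GMO when an annotated element lies in the closure of the
method's target; an annotation that is only an ancestor of a
variant-specific target yields the cautious call 'possible'.
"""

from gmoget import (
    GMORecord,
    MethodSpec,
    build_paper_fixture,
    coverage_report,
    predict,
)

th = build_paper_fixture()
name = lambda n: th.name_index[n.casefold()]

gmos = [
    GMORecord("GMO-A", frozenset({name("CS-cry1Ab10-BACTK")})),  # variant
    GMORecord("GMO-B", frozenset({name("CS-cry1Ac-BACTU")})),    # sibling
    GMORecord("GMO-C", frozenset({name("CS-cry1Ab-BACTU")})),    # parent
]
methods = [
    MethodSpec("cry1Ab-assay", name("CS-cry1Ab-BACTU")),
    MethodSpec("cry1Ab10-assay", name("CS-cry1Ab10-BACTK")),
]

matrix = predict(th, gmos, methods)
print("GMO      " + "  ".join(f"{m.method_id:>15s}" for m in methods))
for g in gmos:
    cells = [
        f"{matrix[(g.gmo_id, m.method_id)].value:>15s}" for m in methods
    ]
    print(f"{g.gmo_id:8s} " + "  ".join(cells))

report = coverage_report(matrix)
print("\nper-method detected counts:",
      {m: c["detected"] for m, c in report.per_method.items()})
# GMO-A carries the level-4 variant, so the level-3 assay still detects
# it; GMO-C is annotated only at level 3, so the variant-specific assay
# reports 'possible' — the variant's presence is unconfirmed, and a
# binary matrix would overclaim.
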