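"""Detection-matrix prediction: which GMOs can an element-specific
method identify, from element annotations and the hierarchy alone.

A GMO is annotated with the concrete elements (level >= 3) it carries; a
method is specific for one target element (level 2-4).  The method
*detects* a GMO when some annotated element lies in the target's
reflexive-transitive closure — annotating with a narrower variant (a
"child") still guarantees the target sequence is present.  When a GMO is
annotated only with a strict ancestor of the target (say level 3, while
the assay is specific for one level-4 variant), the variant's presence
is unconfirmed: the call is *possible*, not detected — a binary output
would silently overclaim.  Everything else is *not_detected*.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable

from .errors import UnknownTermError
from .model import Thesaurus
from .query import expand


class Call(str, Enum):
    DETECTED = "detected"
    POSSIBLE = "possible"
    NOT_DETECTED = "not_detected"

    @property
    def cell(self) -> str:
        """Single-letter TSV cell: D / P / N."""
        return {"detected": "D", "possible": "P", "not_detected": "N"}[
            self.value
        ]


@dataclass(frozen=True)
class GMORecord:
    """One GMO with the set of element term ids annotated on it."""

    gmo_id: str
    element_ids: frozenset[str]


@dataclass(frozen=True)
class MethodSpec:
    """An element-specific detection method and the term it targets."""

    method_id: str
    target_id: str


@dataclass
class DetectionMatrix:
    """GMO x method grid of three-valued detectability calls."""

    gmo_ids: list[str]
    method_ids: list[str]
    calls: dict[tuple[str, str], Call] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> Call:
        return self.calls[key]


def _check_records(
    thesaurus: Thesaurus,
    gmos: Iterable[GMORecord],
    methods: Iterable[MethodSpec],
) -> None:
    for gmo in gmos:
        for eid in gmo.element_ids:
            term = thesaurus.get(eid)
            if term is None:
                raise UnknownTermError(
                    f"GMO {gmo.gmo_id}: unknown element {eid}"
                )
            if (term.level or 0) < 3:
                raise UnknownTermError(
                    f"GMO {gmo.gmo_id}: element {eid} is level {term.level}; "
                    "annotations must name concrete elements (level >= 3)"
                )
    for m in methods:
        term = thesaurus.get(m.target_id)
        if term is None:
            raise UnknownTermError(
                f"method {m.method_id}: unknown target {m.target_id}"
            )
        if term.level not in (2, 3, 4):
            raise UnknownTermError(
                f"method {m.method_id}: target {m.target_id} is level "
                f"{term.level}; methods target levels 2-4"
            )


def predict(
    thesaurus: Thesaurus,
    gmos: list[GMORecord],
    methods: list[MethodSpec],
    binary: bool = False,
) -> DetectionMatrix:
    """Compute the full GMO x method detection matrix.

    With ``binary=True`` the cautious *possible* verdict collapses to
    *not_detected*.
    """
    _check_records(thesaurus, gmos, methods)
    matrix = DetectionMatrix(
        gmo_ids=[g.gmo_id for g in gmos],
        method_ids=[m.method_id for m in methods],
    )
    for method in methods:
        closure = expand(thesaurus, method.target_id)
        strict_ancestors = set(thesaurus.ancestors(method.target_id))
        for gmo in gmos:
            elements = {thesaurus[e].term_id for e in gmo.element_ids}
            if elements & closure:
                call = Call.DETECTED
            elif elements & strict_ancestors:
                call = Call.POSSIBLE if not binary else Call.NOT_DETECTED
            else:
                call = Call.NOT_DETECTED
            matrix.calls[(gmo.gmo_id, method.method_id)] = call
    return matrix


@dataclass
class CoverageReport:
    """Per-method call counts and per-GMO detecting methods."""

    per_method: dict[str, dict[str, int]]
    per_gmo: dict[str, list[str]]


def coverage_report(matrix: DetectionMatrix) -> CoverageReport:
    """Summarise a matrix deterministically (input order preserved)."""
    per_method: dict[str, dict[str, int]] = {}
    per_gmo: dict[str, list[str]] = {}
    for mid in matrix.method_ids:
        counts = Counter(
            matrix.calls[(gid, mid)].value for gid in matrix.gmo_ids
        )
        per_method[mid] = {
            "detected": counts.get("detected", 0),
            "possible": counts.get("possible", 0),
            "not_detected": counts.get("not_detected", 0),
        }
    for gid in matrix.gmo_ids:
        per_gmo[gid] = [
            mid
            for mid in matrix.method_ids
            if matrix.calls[(gid, mid)] is Call.DETECTED
        ]
    return CoverageReport(per_method, per_gmo)


# ---------------------------------------------------------------------------
# TSV interfaces

def load_gmo_annotations(stream: IO[str]) -> list[GMORecord]:
    """Read ``gmo_id<TAB>element_id`` pairs, one per line, aggregating."""
    by_gmo: dict[str, set[str]] = {}
    order: list[str] = []
    for row in csv.reader(stream, delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        gmo_id, element_id = row[0].strip(), row[1].strip()
        if gmo_id not in by_gmo:
            by_gmo[gmo_id] = set()
            order.append(gmo_id)
        by_gmo[gmo_id].add(element_id)
    return [GMORecord(g, frozenset(by_gmo[g])) for g in order]


def load_methods(stream: IO[str]) -> list[MethodSpec]:
    """Read ``method_id<TAB>target_element_id`` lines."""
    out = []
    for row in csv.reader(stream, delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        out.append(MethodSpec(row[0].strip(), row[1].strip()))
    return out


def write_matrix_tsv(matrix: DetectionMatrix, stream: IO[str]) -> None:
    """Matrix as TSV: method-id header row, one row per GMO, cells D/P/N."""
    stream.write("gmo_id\t" + "\t".join(matrix.method_ids) + "\n")
    for gid in matrix.gmo_ids:
        cells = [matrix.calls[(gid, mid)].cell for mid in matrix.method_ids]
        stream.write(gid + "\t" + "\t".join(cells) + "\n")
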