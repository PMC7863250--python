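import io

import pytest

from gmoget import (
    Call,
    GMORecord,
    MethodSpec,
    coverage_report,
    generate_random_annotations,
    generate_random_thesaurus,
    predict,
)
from gmoget.errors import UnknownTermError
from gmoget.matrix import load_gmo_annotations, load_methods, write_matrix_tsv
from conftest import brute_force_ancestors, brute_force_expand


def name_id(th, name):
    return th.name_index[name.casefold()]


@pytest.fixture()
def cry_ids(paper):
    return {
        "parent": name_id(paper, "CS-cry1Ab-BACTU"),
        "variant": name_id(paper, "CS-cry1Ab10-BACTK"),
        "sibling": name_id(paper, "CS-cry1Ac-BACTU"),
    }


class TestPredictExamples:
    def test_child_annotation_is_detected_by_parent_targeting_method(
        self, paper, cry_ids
    ):
        # the assay targets the level-3 element; the GMO carries the
        # level-4 variant, which contains the target sequence
        gmos = [GMORecord("G1", frozenset({cry_ids["variant"]}))]
        methods = [MethodSpec("M1", cry_ids["parent"])]
        m = predict(paper, gmos, methods)
        assert m[("G1", "M1")] is Call.DETECTED

    def test_sibling_annotation_is_not_detected(self, paper, cry_ids):
        gmos = [GMORecord("G1", frozenset({cry_ids["sibling"]}))]
        methods = [MethodSpec("M1", cry_ids["variant"])]
        m = predict(paper, gmos, methods)
        assert m[("G1", "M1")] is Call.NOT_DETECTED

    def test_ancestor_annotation_is_possible(self, paper, cry_ids):
        # annotation at level 3 underdetermines a level-4-specific assay
        gmos = [GMORecord("G1", frozenset({cry_ids["parent"]}))]
        methods = [MethodSpec("M1", cry_ids["variant"])]
        m = predict(paper, gmos, methods)
        assert m[("G1", "M1")] is Call.POSSIBLE

    def test_binary_mode_collapses_possible(self, paper, cry_ids):
        gmos = [GMORecord("G1", frozenset({cry_ids["parent"]}))]
        methods = [MethodSpec("M1", cry_ids["variant"])]
        m = predict(paper, gmos, methods, binary=True)
        assert m[("G1", "M1")] is Call.NOT_DETECTED

    def test_empty_annotation_never_detected(self, paper, cry_ids):
        gmos = [GMORecord("G1", frozenset())]
        methods = [
            MethodSpec("M1", cry_ids["parent"]),
            MethodSpec("M2", cry_ids["variant"]),
        ]
        m = predict(paper, gmos, methods)
        assert all(c is Call.NOT_DETECTED for c in m.calls.values())

    def test_level2_screening_target_allowed(self, paper):
        # screening assays commonly target broad elements such as P-35S
        gmos = [GMORecord("G1", frozenset({name_id(paper, "P-35S-CaMV")}))]
        methods = [MethodSpec("M1", name_id(paper, "P-Cauliflower mosaic virus"))]
        m = predict(paper, gmos, methods)
        assert m[("G1", "M1")] is Call.DETECTED

    def test_unknown_element_rejected(self, paper):
        gmos = [GMORecord("G1", frozenset({"e:0009999"}))]
        with pytest.raises(UnknownTermError):
            predict(paper, gmos, [])

    def test_level1_annotation_rejected(self, paper):
        gmos = [GMORecord("G1", frozenset({"e:0000001"}))]
        with pytest.raises(UnknownTermError):
            predict(paper, gmos, [])


class TestCoverageReport:
    def test_recount_of_example_calls(self, paper, cry_ids):
        gmos = [
            GMORecord("G1", frozenset({cry_ids["variant"]})),
            GMORecord("G2", frozenset({cry_ids["sibling"]})),
            GMORecord("G3", frozenset({cry_ids["parent"]})),
        ]
        methods = [
            MethodSpec("M-parent", cry_ids["parent"]),
            MethodSpec("M-variant", cry_ids["variant"]),
        ]
        report = coverage_report(predict(paper, gmos, methods))
        assert report.per_method["M-parent"] == {
            "detected": 2, "possible": 0, "not_detected": 1
        }
        assert report.per_method["M-variant"] == {
            "detected": 1, "possible": 1, "not_detected": 1
        }
        assert report.per_gmo["G1"] == ["M-parent", "M-variant"]

    def test_empty_inputs(self, paper):
        report = coverage_report(predict(paper, [], []))
        assert report.per_method == {}
        assert report.per_gmo == {}

    def test_all_gmos_annotated_with_target_itself(self, paper, cry_ids):
        gmos = [
            GMORecord(f"G{i}", frozenset({cry_ids["parent"]}))
            for i in range(5)
        ]
        methods = [MethodSpec("M1", cry_ids["parent"])]
        report = coverage_report(predict(paper, gmos, methods))
        assert report.per_method["M1"]["detected"] == len(gmos)


def oracle_call(th, elements, target):
    """Per-pair brute force: explicit closure enumeration."""
    closure = brute_force_expand(th, target)
    if set(elements) & closure:
        return Call.DETECTED
    if set(elements) & brute_force_ancestors(th, target):
        return Call.POSSIBLE
    return Call.NOT_DETECTED


class TestPredictProperties:
    @pytest.mark.parametrize("seed", range(15))
    def test_agrees_with_brute_force_oracle(self, seed):
        th = generate_random_thesaurus(seed, n_level2=4,
                                       n_level3_per_branch=2)
        gmos, methods = generate_random_annotations(seed, th)
        m = predict(th, gmos, methods)
        for gmo in gmos:
            for method in methods:
                assert m[(gmo.gmo_id, method.method_id)] is oracle_call(
                    th, gmo.element_ids, method.target_id
                )

    @pytest.mark.parametrize("seed", range(10))
    def test_ancestor_target_never_shrinks_detected_set(self, seed):
        th = generate_random_thesaurus(seed, n_level2=4,
                                       n_level3_per_branch=2)
        gmos, methods = generate_random_annotations(seed, th)
        for method in methods:
            base = predict(th, gmos, [method])
            detected = {
                g for (g, _), c in base.calls.items() if c is Call.DETECTED
            }
            for anc in th.ancestors(method.target_id):
                if (th[anc].level or 0) < 2:
                    continue
                lifted = predict(th, gmos, [MethodSpec("anc", anc)])
                lifted_detected = {
                    g for (g, _), c in lifted.calls.items()
                    if c is Call.DETECTED
                }
                assert detected <= lifted_detected

    @pytest.mark.parametrize("seed", range(5))
    def test_three_valued_partition(self, seed):
        th = generate_random_thesaurus(seed)
        gmos, methods = generate_random_annotations(seed, th)
        m = predict(th, gmos, methods)
        assert len(m.calls) == len(gmos) * len(methods)
        assert all(isinstance(c, Call) for c in m.calls.values())


class TestTsvInterfaces:
    def test_load_and_write_round(self, paper, cry_ids):
        gmo_tsv = io.StringIO(
            f"G1\t{cry_ids['variant']}\nG1\t{cry_ids['sibling']}\n"
            f"G2\t{cry_ids['parent']}\n"
        )
        method_tsv = io.StringIO(
            f"M1\t{cry_ids['parent']}\nM2\t{cry_ids['variant']}\n"
        )
        gmos = load_gmo_annotations(gmo_tsv)
        methods = load_methods(method_tsv)
        assert gmos[0].element_ids == frozenset(
            {cry_ids["variant"], cry_ids["sibling"]}
        )
        out = io.StringIO()
        write_matrix_tsv(predict(paper, gmos, methods), out)
        lines = out.getvalue().strip().split("\n")
        assert lines[0] == "gmo_id\tM1\tM2"
        assert lines[1] == "G1\tD\tD"
        assert lines[2] == "G2\tD\tP"
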