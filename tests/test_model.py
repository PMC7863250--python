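import pytest

from gmoget import (
    ElementTerm,
    Thesaurus,
    build_paper_fixture,
    generate_random_thesaurus,
    validate_thesaurus,
)
from gmoget.errors import (
    CycleError,
    DuplicateIdError,
    DuplicateNameError,
    LevelError,
    UnknownParentError,
)
from gmoget.model import ROOT_ID, ROOT_NAME, normalize_id


def make_base():
    th = Thesaurus()
    th.add_term(ElementTerm(ROOT_ID, ROOT_NAME))
    th.add_term(ElementTerm("e:0000001", "coding sequence", parent_id=ROOT_ID))
    th.add_term(
        ElementTerm(
            "e:0000188",
            "CS-phosphinothricin N-acetyltransferase",
            parent_id="e:0000001",
        )
    )
    return th


class TestAddTerm:
    def test_level_is_computed_from_parent(self):
        th = make_base()
        th.add_term(
            ElementTerm(
                "e:0000415", "CS-bar-STRHY", parent_id="e:0000188",
                donor="STRHY",
            )
        )
        assert th["e:0000415"].level == 3
        assert th["e:0000188"].level == 2

    def test_printed_id_form_with_space_is_normalized(self):
        th = make_base()
        th.add_term(
            ElementTerm("e: 0000415", "CS-bar-STRHY", parent_id="e: 0000188")
        )
        assert "e:0000415" in th.terms
        assert th["e:0000415"].parent_id == "e:0000188"

    def test_duplicate_id_rejected(self):
        th = make_base()
        th.add_term(ElementTerm("e:0000415", "CS-bar-STRHY",
                                parent_id="e:0000188"))
        with pytest.raises(DuplicateIdError):
            th.add_term(ElementTerm("e:0000415", "CS-other-STRHY",
                                    parent_id="e:0000188"))

    def test_self_parent_rejected(self):
        th = make_base()
        with pytest.raises(CycleError):
            th.add_term(ElementTerm("e:0000999", "CS-x-STRHY",
                                    parent_id="e:0000999"))

    def test_unknown_parent_rejected(self):
        th = make_base()
        with pytest.raises(UnknownParentError):
            th.add_term(ElementTerm("e:0000999", "CS-x-STRHY",
                                    parent_id="e:0000777"))

    def test_second_root_rejected(self):
        th = make_base()
        with pytest.raises(LevelError):
            th.add_term(ElementTerm("e:0000998", "another root"))

    def test_duplicate_preferred_name_rejected(self):
        th = make_base()
        with pytest.raises(DuplicateNameError):
            th.add_term(
                ElementTerm("e:0000997", "coding sequence",
                            parent_id=ROOT_ID)
            )

    def test_declared_level_must_match_position(self):
        th = make_base()
        with pytest.raises(LevelError):
            th.add_term(
                ElementTerm("e:0000996", "CS-x-STRHY", parent_id="e:0000188",
                            level=2)
            )

    def test_depth_beyond_level_4_rejected(self):
        th = make_base()
        th.add_term(ElementTerm("e:0000300", "CS-aaa-STRHY",
                                parent_id="e:0000188"))
        th.add_term(ElementTerm("e:0000301", "CS-aaa1-STRHY",
                                parent_id="e:0000300"))
        with pytest.raises(LevelError):
            th.add_term(ElementTerm("e:0000302", "CS-aaa2-STRHY",
                                    parent_id="e:0000301"))


class TestNextFreeId:
    def test_empty_thesaurus(self):
        assert Thesaurus().next_free_id() == "e:0000001"

    def test_gap_filling(self):
        th = Thesaurus()
        th.add_term(ElementTerm("e:0000001", "genetic element"))
        th.add_term(ElementTerm("e:0000003", "coding sequence",
                                parent_id="e:0000001"))
        assert th.next_free_id() == "e:0000002"

    def test_matches_brute_force_scan_on_fixture(self, paper):
        used = {int(t[2:]) for t in paper.terms}
        expected = next(n for n in range(1, 10**7) if n not in used)
        assert paper.next_free_id() == f"e:{expected:07d}"


class TestValidate:
    def test_paper_fixture_conforms(self, paper, donors, prefixes):
        assert validate_thesaurus(paper, donors, prefixes) == []

    def test_tree_property_on_fixture(self, paper):
        n_parents = sum(1 for t in paper if t.parent_id is not None)
        assert n_parents == len(paper) - 1
        # DFS visits every term exactly once
        seen = []
        stack = [paper.root_id]
        while stack:
            cur = stack.pop()
            seen.append(cur)
            stack.extend(paper.children_index.get(cur, ()))
        assert sorted(seen) == sorted(paper.terms)

    def test_prefix_ancestor_mismatch(self, donors, prefixes):
        th = Thesaurus()
        th.add_term(ElementTerm(ROOT_ID, ROOT_NAME))
        th.add_term(ElementTerm("e:0000007", "promoter", parent_id=ROOT_ID))
        th.add_term(ElementTerm("e:0000100", "P-nopaline synthase",
                                parent_id="e:0000007"))
        th.add_term(ElementTerm("e:0000101", "T-nos-RHIRD",
                                parent_id="e:0000100", donor="RHIRD"))
        codes = {v.code for v in validate_thesaurus(th, donors, prefixes)}
        assert "prefix-ancestor" in codes

    def test_short_id_pattern_violation(self, donors, prefixes):
        th = make_base()
        # seed a malformed id behind add_term's back
        term = ElementTerm("e:0000002", "enhancer", parent_id=ROOT_ID)
        th.add_term(term)
        bad = th.terms.pop("e:0000002")
        bad.term_id = "e:415"
        th.terms["e:415"] = bad
        codes = {v.code for v in validate_thesaurus(th, donors, prefixes)}
        assert "id-pattern" in codes

    @pytest.mark.parametrize(
        "mutate,expected_code",
        [
            (lambda th: th.terms["e:0000188"].__setattr__(
                "parent_id", "e:0009999"), "unknown-parent"),
            (lambda th: th.terms["e:0000188"].__setattr__(
                "parent_id", "e:0000188"), "cycle"),
            (lambda th: th.terms["e:0000188"].__setattr__("level", 4),
             "level"),
            (lambda th: th.terms["e:0000001"].__setattr__(
                "name", "not a type"), "level1-name"),
            (lambda th: th.terms["e:0000188"].__setattr__(
                "donor", "NOPE1"), "donor"),
        ],
    )
    def test_seeded_violation_is_reported(self, donors, prefixes, mutate,
                                          expected_code):
        th = make_base()
        assert validate_thesaurus(th, donors, prefixes) == []
        mutate(th)
        codes = {v.code for v in validate_thesaurus(th, donors, prefixes)}
        assert expected_code in codes

    @pytest.mark.parametrize("seed", range(10))
    def test_random_add_sequences_stay_valid(self, seed, donors, prefixes):
        th = generate_random_thesaurus(seed)
        errors = [
            v for v in validate_thesaurus(th, donors, prefixes)
            if v.severity == "error"
        ]
        assert errors == []
        n_parents = sum(1 for t in th if t.parent_id is not None)
        assert n_parents == len(th) - 1

    def test_trait_below_level3_is_a_warning(self, donors, prefixes):
        from gmoget.model import TraitRef

        th = make_base()
        th.terms["e:0000188"].trait_refs.append(TraitRef("t:0000006"))
        violations = validate_thesaurus(th, donors, prefixes)
        assert [v.code for v in violations] == ["trait-level"]
        assert violations[0].severity == "warning"


def test_normalize_id_accepts_printed_and_canonical_forms():
    assert normalize_id("e: 0000415") == "e:0000415"
    assert normalize_id("e:0000415") == "e:0000415"
    assert normalize_id("t: 0000006") == "t:0000006"


def test_fixture_build_is_deterministic():
    assert build_paper_fixture() == build_paper_fixture()
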