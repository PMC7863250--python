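import pytest
from hypothesis import given, settings, strategies as st

from gmoget import (
    Modification,
    ParsedElementName,
    canonical_name,
    compose_name,
    lint_name,
    normalize_stem,
    parse_name,
)
from gmoget.errors import (
    MissingDonorError,
    NameSyntaxError,
    UnknownPrefixError,
)


class TestParseName:
    @pytest.mark.parametrize(
        "text,prefix,stem,modifier,donor",
        [
            ("CS-bar-STRHY", "CS", "bar", None, "STRHY"),
            ("CS-ppo5_genome_edited-SOLTU", "CS", "ppo5",
             Modification.GENOME_EDITED, "SOLTU"),
            ("CS-CP4epsps-RHIRD", "CS", "CP4epsps", None, "RHIRD"),
            ("P-35S-CaMV", "P", "35S", None, "CaMV"),
            ("T-rbcS_E9-PEA", "T", "rbcS_E9", None, "PEA"),
            ("TP-xyz-MAIZE", "TP", "xyz", None, "MAIZE"),
            ("CS-abc_siRNAas-MAIZE", "CS", "abc",
             Modification.SIRNA_ANTISENSE, "MAIZE"),
            ("CS-abc_siRNAs-MAIZE", "CS", "abc",
             Modification.SIRNA_SENSE, "MAIZE"),
        ],
    )
    def test_decomposition(self, text, prefix, stem, modifier, donor):
        parsed = parse_name(text)
        assert parsed == ParsedElementName(prefix, stem, modifier, donor)

    def test_hyphenated_stem_without_donor(self):
        # the donor segment is accepted only when it is a registry key
        parsed = parse_name("CS-beta-gal")
        assert parsed.stem == "beta-gal"
        assert parsed.donor is None

    def test_unknown_prefix(self):
        with pytest.raises(UnknownPrefixError):
            parse_name("Q-foo-STRHY")

    def test_donor_required(self):
        with pytest.raises(MissingDonorError):
            parse_name("CS-beta-gal", donor_required=True)

    def test_empty_stem(self):
        with pytest.raises(NameSyntaxError):
            parse_name("CS--STRHY")

    def test_forbidden_characters_in_stem(self):
        with pytest.raises(NameSyntaxError):
            parse_name("CS-a.b-STRHY")

    @given(suffix=st.text(
        alphabet=st.characters(whitelist_categories=("Lu",),
                               max_codepoint=127),
        min_size=2, max_size=5))
    @settings(max_examples=100, derandomize=True)
    def test_never_accepts_unregistered_donor_segment(self, suffix, donors):
        parsed = parse_name(f"CS-stem-{suffix}")
        if parsed.donor is not None:
            assert parsed.donor in donors


class TestComposeName:
    @pytest.mark.parametrize(
        "parts,expected",
        [
            (ParsedElementName("P", "ubi1", None, "MAIZE"), "P-ubi1-MAIZE"),
            (ParsedElementName("CS", "ppo", Modification.GENOME_EDITED,
                               "AGABB"), "CS-ppo_genome_edited-AGABB"),
            (ParsedElementName("T", "nos", None, "RHIRD"), "T-nos-RHIRD"),
            (ParsedElementName("CS", "beta-gal", None, None), "CS-beta-gal"),
        ],
    )
    def test_composition(self, parts, expected):
        assert compose_name(parts) == expected

    def test_invalid_parts_rejected(self):
        with pytest.raises(NameSyntaxError):
            compose_name(ParsedElementName("CS", "", None, None))


class TestNormalizeStem:
    @pytest.mark.parametrize(
        "raw,donor,expected",
        [
            ("AtAHAS", "ARATH", "ahas"),
            ("ZmUbi1", "MAIZE", "ubi1"),
            ("Cry1Ab/Vip3H", "SYNTH", "cry1Ab_vip3H"),
            ("β-gal", None, "beta-gal"),
            ("nos 3′ UTR", "RHIRD", "nos"),
            ("CP4epsps", "RHIRD", "CP4epsps"),
            ("rbcS.E9", "PEA", "rbcS_E9"),
            ("bar", "STRHY", "bar"),  # no false species stripping
            ("StArch", None, "StArch".lower()),  # donor absent: no strip
        ],
    )
    def test_paper_rules(self, raw, donor, expected):
        assert normalize_stem(raw, donor) == expected

    def test_empty_after_stripping(self):
        with pytest.raises(NameSyntaxError):
            normalize_stem("3′ UTR", "RHIRD")

    @given(st.text(
        alphabet="abcxyzABCXYZ0123459 ._/´βδΩ-'",
        min_size=1, max_size=20))
    @settings(max_examples=300, derandomize=True)
    def test_idempotence(self, raw):
        try:
            once = normalize_stem(raw, "MAIZE")
        except NameSyntaxError:
            return
        assert normalize_stem(once, "MAIZE") == once


class TestCanonicalName:
    def test_species_abbreviation_infers_donor(self):
        assert canonical_name("CS-AtAHAS") == "CS-ahas-ARATH"
        assert canonical_name("P-ZmUbi1") == "P-ubi1-MAIZE"

    def test_explicit_donor(self):
        assert canonical_name("CS-AtAHAS", donor="ARATH") == "CS-ahas-ARATH"

    def test_cp4_exception_is_retained(self):
        assert canonical_name("CS-CP4epsps-RHIRD") == "CS-CP4epsps-RHIRD"


class TestLintName:
    def test_embedded_species_abbreviation_single_diagnostic(self):
        diags = lint_name("CS-AtAHAS", donor="ARATH")
        assert len(diags) == 1
        assert diags[0].rule == "species-abbreviation"
        assert diags[0].suggestion == "CS-ahas-ARATH"

    def test_canonical_names_are_clean(self, paper):
        assert lint_name("P-ubi1-MAIZE") == []
        assert lint_name("CS-CP4epsps-RHIRD") == []

    def test_utr_designator(self):
        diags = lint_name("T-nos 3′ UTR-RHIRD")
        assert [d.rule for d in diags] == ["utr-designator"]
        assert diags[0].suggestion == "T-nos-RHIRD"

    def test_greek_letter(self):
        diags = lint_name("CS-βgal", donor="ECOLI")
        rules = [d.rule for d in diags]
        assert "greek-letter" in rules
        assert any(d.suggestion == "CS-betagal-ECOLI" for d in diags)

    def test_special_character(self):
        diags = lint_name("CS-a/b-STRHY")
        assert any(d.rule == "special-character" for d in diags)
        assert any(d.suggestion == "CS-a_b-STRHY" for d in diags)

    def test_unknown_prefix_diagnostic(self):
        diags = lint_name("Q-foo-STRHY")
        assert [d.rule for d in diags] == ["unknown-prefix"]

    def test_uppercase_stem(self):
        diags = lint_name("CS-BAR-STRHY")
        assert [d.rule for d in diags] == ["letter-case"]
        assert diags[0].suggestion == "CS-bar-STRHY"

    def test_unknown_donor_segment(self):
        diags = lint_name("CS-bar-STRHX")
        assert [d.rule for d in diags] == ["unknown-donor"]

    def test_fixture_level34_names_are_canonical(self, paper):
        names = [t.name for t in paper if (t.level or 0) >= 3]
        assert len(names) == 16
        for name in names:
            term = paper[paper.name_index[name.casefold()]]
            assert lint_name(name, donor=term.donor) == [], name


class TestRoundTrip:
    def test_fixture_names_round_trip(self, paper):
        for term in paper:
            if (term.level or 0) >= 3:
                assert compose_name(parse_name(term.name)) == term.name
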