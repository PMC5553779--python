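"""Morbidity code-pattern matching and discharge classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costlab.catalog import (
    CATEGORIES,
    CatalogParseError,
    ClassificationError,
    CodePattern,
    classify,
    match_code,
    normalize_code,
    parse_catalog,
)


def pat(text):
    return CodePattern.parse(text)


class TestMatchCode:
    @pytest.mark.parametrize(
        "pattern, code, expected",
        [
            # wildcard stems and ranges as printed in the shipped catalog
            ("401.x", "401.9", True),
            ("401.x", "402.9", False),
            ("430.x–438.x", "434.11", True),
            ("430.x–438.x", "429.9", False),
            ("430.x–438.x", "438", True),
            ("416.8", "416.8", True),
            ("416.8", "416.9", False),
            ("416.8", "416.80", True),  # deeper subdivision of an exact code
            ("I10.x", "K25.0", False),
            ("I10.x", "I10", True),
            ("250.0–250.3", "250.03", True),
            ("250.0–250.3", "250.31", True),  # truncation at endpoint precision
            ("250.0–250.3", "250.4", False),
            ("E10.0–E10.9", "E10.5", True),
            ("174.x–195.8", "195.81", True),
            ("174.x–195.8", "195.9", False),
            ("C00.x–C26.x", "C15.4", True),
            ("C00.x–C26.x", "D15.4", False),
            ("093.0", "093.0", True),
            # scheme mismatch: numeric code never matches a lettered range
            ("I60.x–I69.x", "431", False),
            ("430.x–438.x", "I61.0", False),
        ],
    )
    def test_examples(self, pattern, code, expected):
        assert match_code(pat(pattern), code) is expected

    def test_normalization_restores_decimal(self):
        assert normalize_code("i610") == "I61.0"
        assert normalize_code(" 2500 ") == "250.0"
        assert normalize_code("I10") == "I10"

    def test_brute_force_oracle_equivalence(self, catalog):
        """Every pattern agrees with naive range enumeration on a small
        ICD-9 code universe (stems 400-440, one decimal digit)."""

        def oracle(pattern_text, code):
            # independent re-implementation: expand the pattern into the
            # explicit set of (stem, decimal-prefix) combinations
            text = pattern_text.replace("–", "-").upper()
            stem, dec = code.split(".")
            if "-" in text:
                lo, hi = text.split("-")
                lo_stem, _, lo_d = lo.partition(".")
                hi_stem, _, hi_d = hi.partition(".")
                if not lo_stem.isdigit():
                    return False
                if not (int(lo_stem) <= int(stem) <= int(hi_stem)):
                    return False
                if int(stem) == int(lo_stem) and lo_d not in ("X", ""):
                    if dec[: len(lo_d)] < lo_d:
                        return False
                if int(stem) == int(hi_stem) and hi_d not in ("X", ""):
                    if dec[: len(hi_d)] > hi_d:
                        return False
                return True
            p_stem, _, p_d = text.partition(".")
            if not p_stem.isdigit() or int(p_stem) != int(stem):
                return False
            return p_d in ("X", "") or dec.startswith(p_d)

        universe = [f"{s}.{d}" for s in range(400, 441) for d in range(10)]
        patterns = [
            p for plist in catalog.categories.values() for p in plist
            if p.scheme == "ICD9"
        ]
        for p in patterns:
            for code in universe:
                assert match_code(p, code) == oracle(p.raw, code), (p.raw, code)

    @pytest.mark.parametrize("bad", ["", "40.x–", "A–B", "401.x–I10.x", "438.x–430.x"])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(CatalogParseError):
            CodePattern.parse(bad)


class TestCatalog:
    def test_thirteen_categories_in_order(self, catalog):
        assert tuple(catalog.categories) == CATEGORIES
        assert len(catalog.categories) == 13

    def test_multi_category_codes_flag_all(self, catalog):
        # hypertensive renal disease sits in both Hypertension and Renal
        cats = catalog.match_categories("403.01")
        assert "Hypertension" in cats and "Renal Disease" in cats

    def test_parse_rejects_duplicate_category(self):
        with pytest.raises(CatalogParseError):
            parse_catalog("[Hypertension]\n401.x\n[Hypertension]\nI10.x\n")

    def test_parse_rejects_orphan_pattern(self):
        with pytest.raises(CatalogParseError):
            parse_catalog("401.x\n")


class TestClassify:
    def test_secondary_hypertension_code(self, catalog):
        profile = classify([("I61.0", True), ("I10", False)], catalog)
        assert profile.flags["Hypertension"] is True
        assert profile.count == 1 and profile.any is True

    def test_mrdx_only_means_no_multimorbidity(self, catalog):
        profile = classify([("431", True)], catalog)
        assert profile.count == 0 and profile.any is False
        assert not any(profile.flags.values())

    def test_second_hemorrhage_counts_as_secondary_cerebrovascular(self, catalog):
        profile = classify([("I61.0", True), ("I61.5", False)], catalog)
        assert profile.flags["Secondary Cerebrovascular Disease"] is True

    @pytest.mark.parametrize(
        "codes",
        [
            [("I61.0", False), ("I10", False)],  # no MRDx
            [("I61.0", True), ("431", True)],  # two MRDx
        ],
    )
    def test_mrdx_flag_validation(self, catalog, codes):
        with pytest.raises(ClassificationError):
            classify(codes, catalog)

    @settings(max_examples=50, deadline=None)
    @given(
        perm=st.permutations(["I10", "E11.9", "N18.9", "K27.9", "J44.9"]),
        extra=st.sampled_from(["F32.9", "C34.1", "I70.9"]),
    )
    def test_order_invariance_and_monotone_count(self, catalog, perm, extra):
        base = [("I61.3", True)] + [(c, False) for c in perm]
        profile = classify(base, catalog)
        reference = classify(
            [("I61.3", True)] + [(c, False) for c in sorted(perm)], catalog
        )
        assert profile.flags == reference.flags
        grown = classify(base + [(extra, False)], catalog)
        assert grown.count >= profile.count
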