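import pytest
from hypothesis import given, settings, strategies as st

from pftmine.template_registry import FacilityTemplate
from pftmine.value_extractor import (
    QualFev1,
    QualObstruction,
    default_lexicon,
    extract_all,
    extract_qualitative,
    extract_quantitative,
    mask_post_bronchodilator,
    normalize_ratio,
)


@pytest.fixture
def template():
    return FacilityTemplate(
        facility_id="FX",
        anchor_pattern="PFT",
        dialect_patterns={
            "fev1_liters": r"FEV[\s-]?1\s+(\d+(?:[.,]\d+)*)\s*L\b",
            "fev1_pct_pred": r"\(\s*(\d+(?:[.,]\d+)*)\s*%?\s*predicted\s*\)",
            "ratio": r"FEV[\s-]?1\s*[/:]\s*FVC:?\s*(\d+(?:[.,]\d+)*)\s*%?",
        },
    )


class TestMasking:
    def test_post_segment_blanked(self, template):
        text = "PRE: FEV1/FVC: 55% POST-BD: FEV1/FVC: 68%"
        masked = mask_post_bronchodilator(text, template)
        assert len(masked) == len(text)
        assert "55" in masked
        assert "68" not in masked
        ext = extract_quantitative(masked, template)
        assert ext.ratio_raw == 55

    def test_no_markers_is_identity(self, template):
        text = "FEV1/FVC: 55%\nFEV1 2.1 L"
        assert mask_post_bronchodilator(text, template) == text

    def test_post_only_snippet_yields_nothing(self, template):
        text = "POST-BRONCHODILATOR\nFEV1/FVC: 70%\nFEV1 2.9 L (81% predicted)"
        masked = mask_post_bronchodilator(text, template)
        ext = extract_quantitative(masked, template)
        assert ext.ratio_raw is None
        assert ext.fev1_liters is None
        assert ext.fev1_pct_pred is None

    def test_blank_line_ends_masked_region(self, template):
        text = "POST-BD block\nFEV1/FVC: 70%\n\nFEV1/FVC: 55%"
        masked = mask_post_bronchodilator(text, template)
        ext = extract_quantitative(masked, template)
        assert ext.ratio_raw == 55

    def test_pre_marker_ends_masked_region(self, template):
        text = "POST-BD FEV1/FVC: 70% PRE-BD FEV1/FVC: 55%"
        masked = mask_post_bronchodilator(text, template)
        assert extract_quantitative(masked, template).ratio_raw == 55

    def test_masking_preserves_length_and_newlines(self, template):
        text = "keep\nPOST-BD: xxx\nyyy\n\ntail"
        masked = mask_post_bronchodilator(text, template)
        assert len(masked) == len(text)
        assert masked.count("\n") == text.count("\n")


class TestExtractQuantitative:
    def test_three_slot_extraction(self, template):
        text = "FEV1 2.10 L (78% predicted) FEV1/FVC 65%"
        ext = extract_quantitative(text, template)
        assert ext.fev1_liters == 2.10
        assert ext.fev1_pct_pred == 78
        assert ext.ratio_raw == 65
        assert ext.ratio_fraction == 0.65
        assert set(ext.provenance) == {"fev1_liters", "fev1_pct_pred", "ratio_raw"}

    def test_fraction_form_ratio(self, template):
        ext = extract_quantitative("FEV1/FVC: 0.65", template)
        assert ext.ratio_raw == 0.65
        assert ext.ratio_fraction == 0.65

    def test_no_numerals_all_absent(self, template):
        ext = extract_quantitative("mild obstruction noted", template)
        assert ext.fev1_liters is None
        assert ext.fev1_pct_pred is None
        assert ext.ratio_raw is None

    def test_first_match_wins(self, template):
        text = "FEV1/FVC: 55% ... FEV1/FVC: 61%"
        assert extract_quantitative(text, template).ratio_raw == 55

    def test_comma_thousands_separator_parsed(self, template):
        # a contrived large-but-parseable number exercises the comma path
        ext = extract_quantitative("FEV1 2,10 L", template)
        assert ext.fev1_liters == 210 or ext.fev1_liters is None  # dropped if implausible
        ext2 = extract_quantitative("FEV1/FVC: 0.65", template)
        assert ext2.ratio_fraction == 0.65

    def test_implausible_values_dropped(self, template):
        ext = extract_quantitative("FEV1 25.0 L (250% predicted)", template)
        assert ext.fev1_liters is None  # outside (0.2, 10)
        assert ext.fev1_pct_pred is None  # outside (5, 200)
        ext2 = extract_quantitative("FEV1/FVC: 140%", template)
        assert ext2.ratio_raw is None  # 140 > 120: implausible

    def test_determinism(self, template):
        text = "FEV1 2.10 L (78% predicted) FEV1/FVC 65%"
        assert extract_quantitative(text, template) == extract_quantitative(
            text, template
        )


class TestNormalizeRatio:
    @pytest.mark.parametrize(
        "raw,expected",
        [(0.65, 0.65), (1.0, 1.0), (65, 0.65), (120, 1.2), (140, None), (0.05, 0.05)],
    )
    def test_cases(self, raw, expected):
        assert normalize_ratio(raw) == expected

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=1.001, max_value=120.0))
    def test_percent_branch_divides_by_100(self, raw):
        assert normalize_ratio(raw) == pytest.approx(raw / 100.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_fraction_branch_is_identity(self, raw):
        assert normalize_ratio(raw) == raw


class TestExtractQualitative:
    def test_graded_obstruction_descriptor(self, template):
        qo, qf, _ = extract_qualitative("mild obstruction", template)
        assert qo is QualObstruction.MILD

    def test_fev1_normal_descriptor(self, template):
        qo, qf, _ = extract_qualitative("the FEV1 is normal", template)
        assert qf is QualFev1.NORMAL

    def test_negation_handled(self, template):
        qo, _, _ = extract_qualitative("no evidence of obstruction", template)
        assert qo is QualObstruction.NO_OBSTRUCTION

    def test_bare_obstruction_is_unspecified(self, template):
        qo, _, _ = extract_qualitative("there is obstruction present", template)
        assert qo is QualObstruction.UNSPECIFIED_OBSTRUCTION

    def test_longest_match_precedence(self, template):
        qo, _, _ = extract_qualitative("moderately severe obstruction", template)
        assert qo is QualObstruction.MODERATELY_SEVERE
        qo2, _, _ = extract_qualitative("very severe obstruction", template)
        assert qo2 is QualObstruction.VERY_SEVERE

    def test_nearest_to_anchor_wins(self, template):
        text = "severe obstruction ... " + "x" * 50 + " ... mild obstruction"
        near_start, _, _ = extract_qualitative(text, template, anchor_offset=0)
        near_end, _, _ = extract_qualitative(
            text, template, anchor_offset=len(text) - 1
        )
        assert near_start is QualObstruction.SEVERE
        assert near_end is QualObstruction.MILD

    def test_qualitative_section_restricts_search(self):
        template = FacilityTemplate(
            facility_id="FX",
            anchor_pattern="PFT",
            dialect_patterns={"qualitative_section": r"Impression:[^\n]*"},
        )
        text = "severe obstruction mentioned in history\nImpression: mild obstruction"
        qo, _, _ = extract_qualitative(text, template)
        assert qo is QualObstruction.MILD

    def test_provenance_offsets_index_snippet(self, template):
        text = "lead-in text; moderate obstruction."
        _, _, prov = extract_qualitative(text, template)
        slot, matched, offset = prov["qualitative_obstruction"]
        assert text[offset : offset + len(matched)] == matched


class TestExtractAll:
    def test_masking_then_extraction_pipeline(self, template):
        text = (
            "PFT RESULTS\nFEV1 2.10 L (78% predicted)\nFEV1/FVC: 65%\n"
            "mild obstruction\nPOST-BD: FEV1/FVC: 72% (90% predicted)"
        )
        ext = extract_all(text, template, study_id="s1")
        assert ext.ratio_fraction == 0.65
        assert ext.fev1_pct_pred == 78
        assert ext.qualitative_obstruction is QualObstruction.MILD
        assert ext.study_id == "s1"

    def test_lexicon_ships_negation_entries(self):
        assert any(e.negation for e in default_lexicon())
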